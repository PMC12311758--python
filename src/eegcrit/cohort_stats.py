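"""Cohort-level statistics: band aggregation, group contrasts, effect sizes,
longitudinal and brain-behavior mixed models, multiple-comparison control.

Conventions follow the emulated study: group contrasts are Gaussian GLMs
(OLS) of the channel-averaged band metric on group with age and sex as
covariates; effect sizes are Cohen's d on the raw (unadjusted) group values
with pooled SD; the Bonferroni family is the five canonical bands per metric
(alpha_corrected = alpha / 5 = 0.01 at alpha = 0.05); brain-behavior models
are linear mixed models with a random subject intercept (REML, Wald
p-values).  Rows with missing values are dropped listwise with counts
reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .criticality import CriticalityProfile
from .spectral import CANONICAL_BANDS

__all__ = ["StatResult", "band_average", "demographics_test", "group_contrast",
           "longitudinal_contrast", "mixed_model", "correlation_summary",
           "cohens_d", "classify_effect_size", "N_BANDS"]

N_BANDS = len(CANONICAL_BANDS)
ALPHA = 0.05


@dataclass
class StatResult:
    """One tested term: coefficient, raw p, and the correction bookkeeping."""

    term: str
    coefficient: float
    p_raw: float
    se: float = np.nan
    n_tests: int = 1
    alpha: float = ALPHA
    cohens_d: float = np.nan
    band: str = ""
    metric: str = ""
    n_obs: int = 0
    n_dropped: int = 0
    flags: dict = field(default_factory=dict)

    @property
    def alpha_corrected(self) -> float:
        return self.alpha / self.n_tests

    @property
    def significant(self) -> bool:
        return bool(self.p_raw < self.alpha_corrected)


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's d with pooled SD: (mean(a) - mean(b)) / s_pooled."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = a.size, b.size
    sp = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
    if sp == 0:
        return 0.0 if a.mean() == b.mean() else np.inf
    return float((a.mean() - b.mean()) / sp)


def classify_effect_size(d: float) -> str:
    """Small / medium / large at the conventional 0.2 / 0.5 / 0.8 thresholds."""
    d = abs(d)
    if d >= 0.8:
        return "large"
    if d >= 0.5:
        return "medium"
    if d >= 0.2:
        return "small"
    return "negligible"


# --------------------------------------------------------------------------
# band aggregation
# --------------------------------------------------------------------------

def band_average(prof: CriticalityProfile, bands=tuple(CANONICAL_BANDS)) -> dict:
    """Average each metric over channels then over in-band frequencies.

    fEI is averaged over valid entries only; the valid fraction is reported
    alongside.  Returns ``{f"{metric}_{band}": value}`` plus
    ``{f"fei_{band}_valid_fraction": frac}``; a band with zero valid fEI
    entries yields NaN.
    """
    out = {}
    for band in bands:
        lo, hi = CANONICAL_BANDS[band] if isinstance(band, str) else band
        sel = (prof.freqs >= lo) & (prof.freqs <= hi)
        if not sel.any():
            raise ValueError(f"band {band} contains no profile frequency")
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells
            out[f"dfa_{band}"] = float(np.nanmean(np.nanmean(prof.dfa_exponent[:, sel], axis=0)))
            out[f"bis_{band}"] = float(np.nanmean(np.nanmean(prof.bis[:, sel], axis=0)))
        fei_vals = prof.fei[:, sel]
        valid = prof.fei_valid[:, sel]
        out[f"fei_{band}_valid_fraction"] = float(valid.mean())
        if valid.any():
            out[f"fei_{band}"] = float(fei_vals[valid].mean())
        else:
            out[f"fei_{band}"] = np.nan
    return out


# --------------------------------------------------------------------------
# group-level tests
# --------------------------------------------------------------------------

def _listwise(table: pd.DataFrame, cols: list[str]) -> tuple[pd.DataFrame, int]:
    sub = table.dropna(subset=cols)
    return sub, len(table) - len(sub)


def demographics_test(table: pd.DataFrame, column: str) -> StatResult:
    """Kruskal-Wallis H across groups (chi-square on counts for sex)."""
    sub, dropped = _listwise(table[table["visit"] == "baseline"], [column, "group"])
    groups = [g for _, g in sub.groupby("group", observed=True)]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    if column == "sex":
        counts = pd.crosstab(sub["group"], sub["sex"])
        stat, p, _, _ = sstats.chi2_contingency(counts)
        return StatResult("sex", float(stat), float(p), band="", metric="sex",
                          n_obs=len(sub), n_dropped=dropped)
    vals = [g[column].to_numpy(float) for g in groups]
    if all(np.ptp(v) == 0 for v in vals) and len({v[0] for v in vals}) == 1:
        return StatResult(column, np.nan, np.nan, n_obs=len(sub), n_dropped=dropped,
                          flags={"constant_column": True})
    stat, p = sstats.kruskal(*vals)
    return StatResult(column, float(stat), float(p), metric=column,
                      n_obs=len(sub), n_dropped=dropped)


def _design_matrix(sub: pd.DataFrame, main: pd.Series, covariates) -> pd.DataFrame:
    X = pd.DataFrame({"Intercept": 1.0, "effect": main.astype(float)}, index=sub.index)
    for cov in covariates:
        if cov == "sex":
            X["sex_M"] = (sub["sex"] == "M").astype(float)
        else:
            X[cov] = sub[cov].astype(float)
    return X


def _ols_term(y: np.ndarray, X: pd.DataFrame) -> tuple[float, float]:
    import statsmodels.api as sm

    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = X.loc[:, X.std() > 0].corr().abs()
        np.fill_diagonal(corr.values, 0)
        pairs = corr.stack()[lambda s: s > 0.999999].index.tolist()
        raise ValueError(f"rank-deficient design; collinear columns: {pairs or list(X.columns)}")
    fit = sm.OLS(y, X).fit()
    return float(fit.params["effect"]), float(fit.pvalues["effect"]), float(fit.bse["effect"])


def group_contrast(table: pd.DataFrame, metric: str, band: str,
                   groups: tuple[str, str] = ("HC", "ncRBD"),
                   covariates=("age", "sex"), n_tests: int = N_BANDS) -> StatResult:
    """GLM of the band metric on group membership with covariate adjustment.

    ``groups`` may name single groups or the pseudo-group "RBD" (all patient
    groups pooled).  The reported coefficient is the effect of the second
    group relative to the first; Cohen's d is computed on the raw values.
    """
    col = f"{metric}_{band}"
    base = table[table["visit"] == "baseline"]

    def in_group(name):
        if name == "RBD":
            return base["group"] != "HC"
        return base["group"] == name

    sel = in_group(groups[0]) | in_group(groups[1])
    sub, dropped = _listwise(base[sel], [col, *[c for c in covariates if c != "sex"]])
    g1 = sub[in_group(groups[1]).reindex(sub.index, fill_value=False)]
    g0 = sub[in_group(groups[0]).reindex(sub.index, fill_value=False)]
    if len(g0) == 0 or len(g1) == 0:
        raise ValueError(f"both groups must be present; got n={len(g0)}, {len(g1)}")
    indicator = in_group(groups[1]).reindex(sub.index, fill_value=False)
    coef, p, se = _ols_term(sub[col].to_numpy(float), _design_matrix(sub, indicator, covariates))
    d = cohens_d(g1[col].to_numpy(float), g0[col].to_numpy(float))
    return StatResult(f"group[{groups[1]} vs {groups[0]}]", coef, p, se=se, n_tests=n_tests,
                      cohens_d=d, band=band, metric=metric, n_obs=len(sub),
                      n_dropped=dropped, flags={"effect_size_class": classify_effect_size(d)})


def longitudinal_contrast(table: pd.DataFrame, metric: str, band: str,
                          covariates=("age", "sex"), n_tests: int = N_BANDS) -> StatResult:
    """Visit (baseline vs follow-up) effect on subjects with both visits."""
    col = f"{metric}_{band}"
    paired_ids = (table.groupby("subject_id")["visit"].nunique()
                  .pipe(lambda s: s[s >= 2]).index)
    if len(paired_ids) == 0:
        raise ValueError("no subjects with both baseline and follow-up visits")
    sub, dropped = _listwise(table[table["subject_id"].isin(paired_ids)], [col])
    indicator = (sub["visit"] == "followup")
    coef, p, se = _ols_term(sub[col].to_numpy(float), _design_matrix(sub, indicator, covariates))
    return StatResult("visit[followup vs baseline]", coef, p, se=se, n_tests=n_tests,
                      band=band, metric=metric, n_obs=len(sub), n_dropped=dropped)


def mixed_model(table: pd.DataFrame, response: str, predictors,
                random: str = "subject_id", covariates=("age", "sex"),
                n_tests: int = N_BANDS) -> list[StatResult]:
    """Linear mixed model with a random subject intercept (REML, Wald p).

    Used for SBR ~ band metric, clinical score ~ band metric, and
    fEI ~ nodal synchrony metric relationships.  A singular random-effects
    fit falls back to the fixed-effects model with a convergence flag.
    """
    import statsmodels.api as sm
    import warnings

    predictors = list(predictors)
    cols = [response, *predictors, *[c for c in covariates if c != "sex"], random]
    sub, dropped = _listwise(table, [c for c in cols if c in table.columns])
    if sub[random].nunique() < 10:
        raise ValueError("need >= 10 subjects for a mixed model")
    X = pd.DataFrame({"Intercept": 1.0}, index=sub.index)
    for pcol in predictors:
        X[pcol] = sub[pcol].astype(float)
    for cov in covariates:
        if cov == "sex":
            X["sex_M"] = (sub["sex"] == "M").astype(float)
        else:
            X[cov] = sub[cov].astype(float)
    y = sub[response].to_numpy(float)
    fallback = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.MixedLM(y, X, groups=sub[random]).fit(reml=True)
        if not np.isfinite(fit.params[predictors]).all() or not np.isfinite(
                np.asarray(fit.bse[predictors])).all():
            fallback = True
    except Exception:
        fallback = True
    if fallback:
        fit = sm.OLS(y, X).fit()
    results = []
    for pcol in predictors:
        results.append(StatResult(
            pcol, float(fit.params[pcol]), float(fit.pvalues[pcol]),
            se=float(fit.bse[pcol]), n_tests=n_tests,
            metric=response, n_obs=len(sub), n_dropped=dropped,
            flags={"fixed_effects_fallback": fallback},
        ))
    return results


def correlation_summary(table: pd.DataFrame, x: str, y: str,
                        method: str = "spearman") -> StatResult:
    """Rank correlation (Spearman or Kendall) between two cohort columns."""
    sub, dropped = _listwise(table, [x, y])
    if len(sub) < 5:
        raise ValueError("need >= 5 paired observations")
    xv = sub[x].to_numpy(float)
    yv = sub[y].to_numpy(float)
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        return StatResult(f"{method}({x},{y})", np.nan, np.nan, n_obs=len(sub),
                          n_dropped=dropped, flags={"constant_input": True})
    if method == "spearman":
        r, p = sstats.spearmanr(xv, yv)
    elif method == "kendall":
        r, p = sstats.kendalltau(xv, yv)
    else:
        raise ValueError("method must be 'spearman' or 'kendall'")
    return StatResult(f"{method}({x},{y})", float(r), float(p),
                      n_obs=len(sub), n_dropped=dropped)
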