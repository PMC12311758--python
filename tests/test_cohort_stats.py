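"""Cohort statistics: aggregation, contrasts, effect sizes, mixed models."""

import warnings

import numpy as np
import pandas as pd
import pytest

from eegcrit.cohort_stats import (
    band_average,
    classify_effect_size,
    cohens_d,
    correlation_summary,
    demographics_test,
    group_contrast,
    longitudinal_contrast,
    mixed_model,
)
from eegcrit.criticality import CriticalityProfile
from eegcrit.spectral import make_bank
from eegcrit.synthetic import CohortSpec, gen_cohort


def _profile(freqs, value=0.7, fei_value=1.0, valid=True):
    n_ch, n_fr = 3, len(freqs)
    shape = (n_ch, n_fr)
    return CriticalityProfile(
        freqs=np.asarray(freqs), channel_labels=[f"c{i}" for i in range(n_ch)],
        dfa_exponent=np.full(shape, value), dfa_r2=np.full(shape, 0.99),
        fei=np.full(shape, fei_value), fei_valid=np.full(shape, valid, dtype=bool),
        bis=np.full(shape, value), dbic=np.zeros(shape), gamma1=np.ones(shape),
        gamma2=np.ones(shape), delta1=np.ones(shape),
    )


class TestBandAverage:
    def test_uniform_profile_passes_through(self):
        freqs = make_bank(512.0).freqs
        out = band_average(_profile(freqs, value=0.66, fei_value=0.9))
        for band in ("delta", "theta", "alpha", "beta", "gamma"):
            assert out[f"dfa_{band}"] == pytest.approx(0.66)
            assert out[f"fei_{band}"] == pytest.approx(0.9)
            assert out[f"fei_{band}_valid_fraction"] == 1.0

    def test_theta_collects_5_to_7_hz(self):
        freqs = make_bank(512.0).freqs
        in_theta = (freqs >= 5) & (freqs <= 7)
        prof = _profile(freqs, value=0.0)
        prof.dfa_exponent[:, in_theta] = 1.0
        out = band_average(prof)
        assert out["dfa_theta"] == pytest.approx(1.0)
        assert out["dfa_alpha"] == pytest.approx(0.0)

    def test_fei_partial_validity(self):
        freqs = make_bank(512.0).freqs
        prof = _profile(freqs, fei_value=0.8)
        prof.fei_valid[1:, :] = False          # 1 of 3 channels valid
        prof.fei[1:, :] = 5.0                  # invalid values must be ignored
        out = band_average(prof)
        assert out["fei_theta"] == pytest.approx(0.8)
        assert out["fei_theta_valid_fraction"] == pytest.approx(1 / 3)

    def test_no_valid_fei_gives_missing(self):
        freqs = make_bank(512.0).freqs
        out = band_average(_profile(freqs, valid=False))
        assert np.isnan(out["fei_delta"])


@pytest.fixture(scope="module")
def cohort_table():
    _, table, _ = gen_cohort(CohortSpec(seed=11), render_signals=False)
    return table


class TestDemographics:
    def test_shifted_groups_detected(self, cohort_table):
        t = cohort_table.copy()
        shift = t.group.map({"HC": 0.0, "ncRBD": 3.0, "lRBD": 3.0, "eRBD": 3.0})
        t["age"] = 70 + np.random.default_rng(0).standard_normal(len(t)) + shift * 7
        res = demographics_test(t, "age")
        assert res.p_raw < 0.001

    def test_identical_distributions_not_significant(self):
        rng = np.random.default_rng(1)
        rows = []
        for g in ("HC", "ncRBD", "lRBD", "eRBD"):
            for i in range(200):
                rows.append({"group": g, "visit": "baseline",
                             "education": rng.normal(10, 3)})
        res = demographics_test(pd.DataFrame(rows), "education")
        assert res.p_raw > 0.01

    def test_sex_uses_chi_square(self, cohort_table):
        res = demographics_test(cohort_table, "sex")
        assert res.term == "sex" and np.isfinite(res.p_raw)

    def test_single_group_error(self):
        t = pd.DataFrame({"group": ["HC"] * 5, "visit": ["baseline"] * 5,
                          "age": range(5)})
        with pytest.raises(ValueError, match="2 groups"):
            demographics_test(t, "age")


class TestGroupContrast:
    def test_equal_means_zero_d(self):
        rng = np.random.default_rng(0)
        rows = []
        for g, n in (("HC", 40), ("ncRBD", 40)):
            for i in range(n):
                rows.append({"group": g, "visit": "baseline", "age": rng.normal(70, 5),
                             "sex": "M" if rng.random() < 0.5 else "F",
                             "dfa_delta": 0.7})
        res = group_contrast(pd.DataFrame(rows), "dfa", "delta")
        assert res.cohens_d == 0.0

    def test_effect_size_thresholds(self):
        assert classify_effect_size(0.1) == "negligible"
        assert classify_effect_size(0.2) == "small"
        assert classify_effect_size(0.5) == "medium"
        assert classify_effect_size(0.8) == "large"
        assert classify_effect_size(-0.9) == "large"

    def test_injected_shift_recovered_at_study_size(self):
        """d-hat within the 95% sampling CI of the injected d ~ 0.6 at n=46/41."""
        ds = []
        for seed in range(12):
            _, t, _ = gen_cohort(CohortSpec(seed=800 + seed), render_signals=False)
            ds.append(group_contrast(t, "dfa", "delta", groups=("HC", "RBD")).cohens_d)
        # sampling SE of d at these n is ~0.22; the mean of 12 has SE ~0.065
        assert np.mean(ds) == pytest.approx(0.6, abs=0.2)

    def test_bonferroni_bookkeeping(self, cohort_table):
        res = group_contrast(cohort_table, "fei", "theta", groups=("HC", "RBD"))
        assert res.n_tests == 5
        assert res.alpha_corrected == pytest.approx(0.01)

    def test_rank_deficient_design_errors(self, cohort_table):
        t = cohort_table.copy()
        t["age"] = 70.0  # constant -> collinear with intercept
        with pytest.raises(ValueError, match="collinear"):
            group_contrast(t, "dfa", "delta", groups=("HC", "RBD"))

    def test_missing_group_errors(self, cohort_table):
        t = cohort_table[cohort_table.group != "eRBD"]
        with pytest.raises(ValueError, match="must be present"):
            group_contrast(t, "dfa", "delta", groups=("HC", "eRBD"))


class TestLongitudinal:
    def test_identical_visits_zero_coefficient(self):
        rng = np.random.default_rng(2)
        rows = []
        for i in range(30):
            v = rng.normal(1.0, 0.1)
            age = rng.normal(70, 5)
            for visit in ("baseline", "followup"):
                rows.append({"subject_id": f"s{i}", "group": "ncRBD", "visit": visit,
                             "age": age, "sex": "M", "bis_alpha": v})
        res = longitudinal_contrast(pd.DataFrame(rows), "bis", "alpha",
                                    covariates=("age",))
        assert res.coefficient == pytest.approx(0.0, abs=1e-10)
        assert res.alpha_corrected == pytest.approx(0.01)

    def test_injected_decline_recovered(self):
        rng = np.random.default_rng(3)
        rows = []
        decline = -0.4
        for i in range(40):
            v = rng.normal(2.0, 0.3)
            for visit in ("baseline", "followup"):
                val = v + (decline if visit == "followup" else 0) + rng.normal(0, 0.1)
                rows.append({"subject_id": f"s{i}", "group": "ncRBD", "visit": visit,
                             "age": rng.normal(70, 5), "sex": "M", "bis_alpha": val})
        res = longitudinal_contrast(pd.DataFrame(rows), "bis", "alpha",
                                    covariates=("age",))
        assert res.coefficient == pytest.approx(decline, abs=0.2)

    def test_no_paired_subjects_error(self, cohort_table):
        base_only = cohort_table[cohort_table.visit == "baseline"]
        with pytest.raises(ValueError, match="both baseline and follow-up"):
            longitudinal_contrast(base_only, "dfa", "delta")


class TestMixedModel:
    def test_sbr_slope_sign_recovered(self, cohort_table):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = mixed_model(cohort_table, "sbr_putamen", ["fei_theta"])[0]
        assert res.coefficient < 0

    def test_duplicated_rows_match_fixed_effects(self):
        """With two identical visits per subject the LMM estimate equals the
        one-visit OLS estimate (degenerate random effect)."""
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        rows = []
        for i in range(30):
            x = rng.normal(1.0, 0.2)
            y = 2.0 - 0.8 * x + rng.normal(0, 0.1)
            age = rng.normal(70, 5)
            for visit in ("baseline", "followup"):
                rows.append({"subject_id": f"s{i}", "visit": visit, "age": age,
                             "sex": "M", "fei_theta": x, "sbr_putamen": y})
        t = pd.DataFrame(rows)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = mixed_model(t, "sbr_putamen", ["fei_theta"], covariates=("age",))[0]
        one = t[t.visit == "baseline"]
        X = pd.DataFrame({"Intercept": 1.0, "fei_theta": one.fei_theta, "age": one.age})
        ols = sm.OLS(one.sbr_putamen.to_numpy(), X).fit()
        assert res.coefficient == pytest.approx(ols.params["fei_theta"], abs=1e-4)

    def test_too_few_subjects_error(self):
        t = pd.DataFrame({"subject_id": [f"s{i}" for i in range(5)],
                          "age": 70.0, "sex": "M",
                          "fei_theta": np.arange(5.0), "sbr_putamen": np.arange(5.0)})
        with pytest.raises(ValueError, match="10 subjects"):
            mixed_model(t, "sbr_putamen", ["fei_theta"])


class TestCorrelation:
    def test_monotone_pair_is_one(self):
        t = pd.DataFrame({"x": np.arange(10.0), "y": np.arange(10.0) ** 3})
        assert correlation_summary(t, "x", "y", "spearman").coefficient == pytest.approx(1.0)
        assert correlation_summary(t, "x", "y", "kendall").coefficient == pytest.approx(1.0)

    def test_sign_and_null(self, rng):
        t = pd.DataFrame({"x": rng.standard_normal(300)})
        t["y_neg"] = -t.x + 0.3 * rng.standard_normal(300)
        t["y_ind"] = rng.standard_normal(300)
        assert correlation_summary(t, "x", "y_neg").coefficient < -0.5
        assert abs(correlation_summary(t, "x", "y_ind").coefficient) < 0.15

    def test_constant_input_missing(self):
        t = pd.DataFrame({"x": np.ones(10), "y": np.arange(10.0)})
        res = correlation_summary(t, "x", "y")
        assert np.isnan(res.coefficient) and res.flags["constant_input"]


class TestInvariances:
    def test_row_order_and_covariate_rescaling(self, cohort_table):
        shuffled = cohort_table.sample(frac=1.0, random_state=5)
        a = group_contrast(cohort_table, "dfa", "delta", groups=("HC", "RBD"))
        b = group_contrast(shuffled, "dfa", "delta", groups=("HC", "RBD"))
        assert a.coefficient == pytest.approx(b.coefficient)
        assert a.p_raw == pytest.approx(b.p_raw)
        rescaled = cohort_table.copy()
        rescaled["age"] = (rescaled.age - 70.0) / 10.0
        c = group_contrast(rescaled, "dfa", "delta", groups=("HC", "RBD"))
        assert a.coefficient == pytest.approx(c.coefficient)
        assert a.p_raw == pytest.approx(c.p_raw, rel=1e-8)
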