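"""Pairwise wPLI phase-synchronization matrices and nodal graph measures.

wPLI (weighted phase lag index) of two narrowband analytic series is
|E[Im X]| / E[|Im X|] with X the cross-spectrum; it lives in [0, 1], ignores
zero-lag (volume-conduction) coupling, and is undefined (missing) when the
imaginary cross-spectrum vanishes identically.  From a symmetric wPLI matrix
we compute three nodal measures: strength (sum of incident weights), the
Onnela weighted local clustering coefficient (geometric-mean triangle
intensity over realized neighbor triplets, weights normalized by the matrix
maximum), and eigenvector centrality (leading eigenvector by power iteration,
scaled to unit maximum).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectral import NarrowbandDecomposition, band_frequency_indices, CANONICAL_BANDS

__all__ = ["SynchronyGraph", "wpli", "wpli_matrix", "nodal_metrics", "band_graphs"]

MIN_VALID_SAMPLES = 100
POWER_ITER_TOL = 1e-10


@dataclass
class SynchronyGraph:
    """Symmetric wPLI matrix (diagonal missing) with nodal measures."""

    wpli: np.ndarray
    channel_labels: list[str]
    band: str = ""
    strength: np.ndarray | None = None
    clustering: np.ndarray | None = None
    eigencentrality: np.ndarray | None = None
    n_missing: int = 0
    meta: dict = field(default_factory=dict)

    def to_edge_dataframe(self, subject_id: str = "", visit: str = ""):
        import pandas as pd
        rows = []
        n = len(self.channel_labels)
        for i in range(n):
            for j in range(i + 1, n):
                rows.append({"subject": subject_id, "visit": visit, "band": self.band,
                             "ch_a": self.channel_labels[i], "ch_b": self.channel_labels[j],
                             "wpli": self.wpli[i, j]})
        return pd.DataFrame(rows)

    def to_nodal_dataframe(self, subject_id: str = "", visit: str = ""):
        import pandas as pd
        return pd.DataFrame({
            "subject": subject_id, "visit": visit, "band": self.band,
            "channel": self.channel_labels, "strength": self.strength,
            "clustering": self.clustering, "eigencentrality": self.eigencentrality,
        })


def _wpli_from_cross(x: np.ndarray) -> float:
    """wPLI from a cross-spectral series; NaN when Im X vanishes (zero lag).

    The denominator is compared against the cross-spectral magnitude with a
    relative tolerance: for identical or exactly zero-lag channels Im X is
    pure rounding noise (~1e-15 of |X|), not signal.
    """
    im = x.imag
    denom = np.abs(im).mean()
    if denom <= 1e-12 * np.abs(x).mean():
        return np.nan
    return float(np.abs(im.mean()) / denom)


def wpli(decomp: NarrowbandDecomposition, ch_a: int, ch_b: int, freq_index: int) -> float:
    """wPLI between two channels at one bank frequency; NaN when undefined."""
    mask = decomp.valid_mask[freq_index]
    if mask.sum() < MIN_VALID_SAMPLES:
        return np.nan
    x = decomp.coeffs[ch_a, freq_index, mask] * np.conj(decomp.coeffs[ch_b, freq_index, mask])
    return _wpli_from_cross(x)


def wpli_matrix(decomp: NarrowbandDecomposition, freq_index: int) -> np.ndarray:
    """Symmetric channel x channel wPLI matrix at one frequency (diagonal NaN)."""
    n = decomp.n_channels
    mask = decomp.valid_mask[freq_index]
    out = np.full((n, n), np.nan)
    if mask.sum() < MIN_VALID_SAMPLES:
        return out
    c = decomp.coeffs[:, freq_index, mask]
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = _wpli_from_cross(c[i] * np.conj(c[j]))
    return out


def nodal_metrics(graph: SynchronyGraph) -> SynchronyGraph:
    """Fill strength, Onnela clustering and eigenvector centrality in place.

    Missing (NaN) off-diagonal entries are treated as weight 0 and counted in
    ``n_missing`` so nodal sums stay defined.
    """
    w = graph.wpli.copy()
    n = w.shape[0]
    np.fill_diagonal(w, 0.0)
    graph.n_missing = int(np.isnan(w).sum() // 2)
    w = np.nan_to_num(w, nan=0.0)

    graph.strength = w.sum(axis=1)

    wmax = w.max()
    clustering = np.zeros(n)
    if wmax > 0:
        wn = (w / wmax) ** (1.0 / 3.0)
        tri = np.diagonal(wn @ wn @ wn)
        k = (w > 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            clustering = np.where(k > 1, tri / (k * (k - 1.0)), 0.0)
    graph.clustering = clustering

    if w.sum() == 0:
        graph.eigencentrality = np.full(n, np.nan)
        return graph
    v = np.ones(n) / np.sqrt(n)
    for _ in range(10000):
        nv = w @ v
        norm = np.linalg.norm(nv)
        if norm == 0:
            break
        nv /= norm
        if np.abs(nv - v).max() < POWER_ITER_TOL:
            v = nv
            break
        v = nv
    v = np.abs(v)
    graph.eigencentrality = v / v.max()
    return graph


def band_graphs(decomp: NarrowbandDecomposition,
                bands=tuple(CANONICAL_BANDS)) -> list[SynchronyGraph]:
    """One graph per band: wPLI matrices averaged over in-band bank frequencies,
    then nodal metrics on the band-average matrix."""
    import warnings

    graphs = []
    for band in bands:
        idx = band_frequency_indices(decomp.freqs, band)
        mats = np.stack([wpli_matrix(decomp, k) for k in idx])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN diagonal
            avg = np.nanmean(mats, axis=0)
        g = SynchronyGraph(wpli=avg, channel_labels=list(decomp.channel_labels),
                           band=band if isinstance(band, str) else f"{band[0]}-{band[1]}")
        graphs.append(nodal_metrics(g))
    return graphs
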