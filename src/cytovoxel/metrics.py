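"""Alignment-quality and signal-preservation metrics.

Per-channel 1-D Wasserstein distance (exact empirical form by default, binned
form on request), Euclidean distance between voxel feature vectors,
symmetrized KL-divergence matrices over per-channel histograms, the
diagonal/off-diagonal (technical/biological) ratio and Spearman correlation
between distance matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr, wasserstein_distance

from .core import ConfigurationError, EmptySampleError, EventMatrix, check_shared_panel

__all__ = [
    "per_channel_wasserstein",
    "voxel_euclidean",
    "kl_matrix",
    "PreservationSummary",
    "preservation_summary",
    "replicate_grouping",
    "spearman_upper",
]


def per_channel_wasserstein(
    a: EventMatrix,
    b: EventMatrix,
    bins: int | None = None,
    histogram_range: tuple[float, float] = (0.0, 1.0),
) -> tuple[pd.Series, float]:
    """Per-channel 1-D Wasserstein distances and their mean.

    With ``bins=None`` the exact empirical distance (integral of the absolute
    CDF difference) is used; passing a bin count switches to the binned
    histogram approximation (cumulative-sum difference x bin width), which is
    the convention the training loss uses.
    """
    if a.n_cells == 0 or b.n_cells == 0:
        raise EmptySampleError("cannot compare empty samples")
    if a.marker_names != b.marker_names:
        raise ConfigurationError("marker panels differ between samples")
    dists = {}
    lo, hi = histogram_range
    for j, marker in enumerate(a.marker_names):
        u, v = a.values[:, j], b.values[:, j]
        if bins is None:
            dists[marker] = float(wasserstein_distance(u, v))
        else:
            edges = np.linspace(lo, hi, bins + 1)
            hu = np.histogram(np.clip(u, lo, hi), bins=edges)[0].astype(float)
            hv = np.histogram(np.clip(v, lo, hi), bins=edges)[0].astype(float)
            hu /= hu.sum()
            hv /= hv.sum()
            dists[marker] = float(np.abs(np.cumsum(hu - hv)).sum() * (edges[1] - edges[0]))
    series = pd.Series(dists, name="wasserstein")
    return series, float(series.mean())


def voxel_euclidean(fa: np.ndarray | pd.Series, fb: np.ndarray | pd.Series) -> float:
    """Euclidean distance between two voxel feature vectors."""
    if isinstance(fa, pd.Series) and isinstance(fb, pd.Series):
        if list(fa.index) != list(fb.index):
            raise ConfigurationError("feature columns differ between vectors")
    fa = np.asarray(fa, dtype=np.float64)
    fb = np.asarray(fb, dtype=np.float64)
    if fa.shape != fb.shape:
        raise ConfigurationError(f"feature vectors differ in length: {fa.shape} vs {fb.shape}")
    return float(np.sqrt(np.sum((fa - fb) ** 2)))


def _channel_histograms(
    em: EventMatrix, edges: np.ndarray, pseudocount: float
) -> np.ndarray:
    lo, hi = edges[0], edges[-1]
    clipped = np.clip(em.values, lo, hi)
    h = np.stack(
        [np.histogram(clipped[:, j], bins=edges)[0] for j in range(em.n_markers)]
    ).astype(np.float64)
    h /= h.sum(axis=1, keepdims=True)
    if pseudocount > 0:
        h += pseudocount
        h /= h.sum(axis=1, keepdims=True)
    return h


def _symmetrized_kl(p: np.ndarray, q: np.ndarray) -> float:
    """0.5 * [KL(P||Q) + KL(Q||P)] per channel row, summed over channels.

    Bins where one side is zero contribute 0 to the p*log(p/q) sum for the
    zero side; with the default pseudocount no zeros remain.
    """

    def kl(x, y):
        mask = x > 0
        with np.errstate(divide="ignore"):
            terms = np.where(mask, x * np.log(np.where(mask, x, 1.0) / y), 0.0)
        return terms.sum(axis=1)

    return float((0.5 * (kl(p, q) + kl(q, p))).sum())


def kl_matrix(
    samples: list[EventMatrix],
    bins: int = 50,
    pseudocount: float = 1e-6,
    histogram_range: tuple[float, float] = (0.0, 1.0),
    average_channels: bool = False,
) -> pd.DataFrame:
    """Pairwise symmetrized KL divergence over per-channel histograms.

    Each sample is summarized by per-channel ``bins``-bin histograms with a
    pseudocount added before renormalization (so disjoint supports never give
    infinities); channel KLs are summed by default (``average_channels`` to
    average). Self-distance is exactly 0.
    """
    if len(samples) < 2:
        raise ConfigurationError("kl_matrix needs at least two samples")
    if bins < 2:
        raise ConfigurationError("bins must be >= 2")
    check_shared_panel(samples)
    edges = np.linspace(*histogram_range, bins + 1)
    hists = [_channel_histograms(s, edges, pseudocount) for s in samples]
    ids = [s.sample_id for s in samples]
    n = len(samples)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = _symmetrized_kl(hists[i], hists[j])
            if average_channels:
                d /= samples[0].n_markers
            out[i, j] = out[j, i] = d
    return pd.DataFrame(out, index=ids, columns=ids)


@dataclass
class PreservationSummary:
    """Technical-vs-biological divergence summary of a distance matrix."""

    diag_mean: float  # mean over technical-replicate pairs
    offdiag_mean: float  # mean over biologically distinct pairs
    ratio: float  # diag_mean / offdiag_mean; low = corrected without collapse
    spearman_rho: float | None = None  # vs a baseline matrix, upper triangles


def replicate_grouping(metadata: pd.DataFrame) -> dict[tuple[str, str], str]:
    """Label each off-diagonal sample pair technical (same biological id) or
    biological (different) from a metadata table."""
    bio = dict(zip(metadata["sample_id"], metadata["biological_id"]))
    ids = list(metadata["sample_id"])
    out = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            out[(a, b)] = "technical" if bio[a] == bio[b] else "biological"
    return out


def preservation_summary(
    dm: pd.DataFrame,
    grouping: dict[tuple[str, str], str],
    baseline: pd.DataFrame | None = None,
) -> PreservationSummary:
    """Mean technical and biological divergences, their ratio, and optionally
    the Spearman correlation of this matrix's upper triangle against a
    baseline matrix (global-topology preservation)."""
    tech, bio = [], []
    ids = list(dm.index)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            kind = grouping.get((a, b)) or grouping.get((b, a))
            if kind == "technical":
                tech.append(dm.loc[a, b])
            elif kind == "biological":
                bio.append(dm.loc[a, b])
            else:
                raise ConfigurationError(f"pair ({a}, {b}) has no technical/biological label")
    if not tech or not bio:
        raise ConfigurationError("need at least one technical and one biological pair")
    diag = float(np.mean(tech))
    off = float(np.mean(bio))
    if off <= 0:
        raise ConfigurationError("off-diagonal mean is zero; ratio undefined")
    rho = None
    if baseline is not None:
        rho = spearman_upper(dm, baseline)
    return PreservationSummary(diag, off, diag / off, rho)


def spearman_upper(a: pd.DataFrame, b: pd.DataFrame) -> float:
    """Spearman rank correlation of the upper triangles of two distance
    matrices sharing an index."""
    if list(a.index) != list(b.index):
        b = b.loc[a.index, a.index]
    iu = np.triu_indices(len(a), k=1)
    return float(spearmanr(a.to_numpy()[iu], b.to_numpy()[iu]).statistic)
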