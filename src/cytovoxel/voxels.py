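"""Hypervoxel occupancy featurization.

Every marker's normalized intensity range is cut into three levels —
LOW ("-", below 0.3), MED ("+", 0.3 to 0.6 inclusive) and HIGH ("++", above
0.6) — and for every two- or three-marker combination the fraction of a
sample's cells in each of the 3^k level tuples becomes one interpretable
feature, named like ``CD8++/CD27-/CCR7-``.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ConfigurationError, EmptySampleError, EventMatrix, check_shared_panel

__all__ = [
    "DiscretizationScheme",
    "VoxelFeature",
    "VoxelFeatureMatrix",
    "discretize",
    "enumerate_combinations",
    "voxel_occupancy",
    "build_feature_matrix",
    "filter_sparse",
]

logger = logging.getLogger(__name__)

LEVELS = ("LOW", "MED", "HIGH")
LEVEL_SUFFIX = {"LOW": "-", "MED": "+", "HIGH": "++"}
SUFFIX_LEVEL = {v: k for k, v in LEVEL_SUFFIX.items()}


@dataclass(frozen=True)
class DiscretizationScheme:
    """Two ordered thresholds splitting [0, 1] into three levels.

    Boundary convention: values exactly at a threshold are MED, i.e. MED is
    the closed interval ``[low, high]``.
    """

    thresholds: tuple[float, float] = (0.3, 0.6)

    def __post_init__(self) -> None:
        lo, hi = self.thresholds
        if not lo < hi:
            raise ConfigurationError(f"thresholds must be strictly increasing, got {self.thresholds}")

    def codes(self, values: np.ndarray) -> np.ndarray:
        """Vectorized level codes: 0 = LOW, 1 = MED, 2 = HIGH."""
        lo, hi = self.thresholds
        values = np.asarray(values, dtype=np.float64)
        return np.where(values < lo, 0, np.where(values > hi, 2, 1))


def discretize(value: float, scheme: DiscretizationScheme | None = None) -> str:
    """Level label for a single finite intensity value."""
    scheme = scheme or DiscretizationScheme()
    if not np.isfinite(value):
        raise ConfigurationError(f"cannot discretize non-finite value {value}")
    return LEVELS[int(scheme.codes(np.array([value]))[0])]


@dataclass(frozen=True)
class VoxelFeature:
    """One voxel: a marker subset with one level per marker."""

    markers: tuple[str, ...]
    levels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.markers) != len(self.levels):
            raise ConfigurationError("markers and levels differ in length")
        if len(set(self.markers)) != len(self.markers):
            raise ConfigurationError("voxel markers must be distinct")
        for lv in self.levels:
            if lv not in LEVELS:
                raise ConfigurationError(f"unknown level {lv!r}")

    @property
    def name(self) -> str:
        return "/".join(f"{m}{LEVEL_SUFFIX[lv]}" for m, lv in zip(self.markers, self.levels))

    @classmethod
    def parse(cls, name: str) -> "VoxelFeature":
        markers, levels = [], []
        for token in name.split("/"):
            for suffix in ("++", "+", "-"):  # longest suffix first
                if token.endswith(suffix):
                    markers.append(token[: -len(suffix)])
                    levels.append(SUFFIX_LEVEL[suffix])
                    break
            else:
                raise ConfigurationError(f"cannot parse voxel token {token!r} in {name!r}")
        return cls(tuple(markers), tuple(levels))


def enumerate_combinations(markers: list[str], sizes=(3,)) -> list[tuple[str, ...]]:
    """All unordered marker subsets of the requested sizes, in lexicographic
    panel order (the panel's own ordering, not alphabetical)."""
    sizes = sorted(set(int(k) for k in sizes))
    if any(k not in (2, 3) for k in sizes):
        raise ConfigurationError(f"combination sizes must be within {{2, 3}}, got {sizes}")
    if max(sizes) > len(markers):
        raise ConfigurationError(
            f"combination size {max(sizes)} exceeds panel size {len(markers)}"
        )
    out: list[tuple[str, ...]] = []
    for k in sizes:
        out.extend(itertools.combinations(markers, k))
    return out


def _voxel_level_tuples(k: int) -> list[tuple[str, ...]]:
    """Canonical voxel order: levels vary fastest on the last marker."""
    return list(itertools.product(LEVELS, repeat=k))


def voxel_occupancy(
    em: EventMatrix,
    subset: tuple[str, ...],
    scheme: DiscretizationScheme | None = None,
) -> np.ndarray:
    """Cell-fraction vector over the subset's 3^k voxels (sums to 1)."""
    scheme = scheme or DiscretizationScheme()
    if em.n_cells == 0:
        raise EmptySampleError(f"sample {em.sample_id} has no cells to summarize")
    k = len(subset)
    codes = np.stack([scheme.codes(em.column(m)) for m in subset], axis=1)
    # mixed-radix index, base 3, last marker fastest
    flat = np.zeros(em.n_cells, dtype=np.int64)
    for j in range(k):
        flat = flat * 3 + codes[:, j]
    counts = np.bincount(flat, minlength=3**k).astype(np.float64)
    return counts / em.n_cells


@dataclass
class VoxelFeatureMatrix:
    """Samples x voxel-features occupancy matrix with provenance."""

    data: pd.DataFrame  # index = sample ids, columns = canonical feature names
    scheme: DiscretizationScheme
    sizes: tuple[int, ...]
    filter_threshold: float | None = None
    dropped: list[str] = field(default_factory=list)

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    def features(self) -> list[VoxelFeature]:
        return [VoxelFeature.parse(c) for c in self.data.columns]

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="sample_id")


def build_feature_matrix(
    samples: list[EventMatrix],
    scheme: DiscretizationScheme | None = None,
    sizes=(3,),
) -> VoxelFeatureMatrix:
    """Concatenate voxel occupancies over all enumerated marker combinations.

    Row order follows the input sample order; per-combination blocks of each
    row sum to 1 before any sparsity filtering.
    """
    scheme = scheme or DiscretizationScheme()
    panel = check_shared_panel(samples)
    subsets = enumerate_combinations(panel, sizes)
    names = [
        VoxelFeature(subset, levels).name
        for subset in subsets
        for levels in _voxel_level_tuples(len(subset))
    ]
    rows = np.stack(
        [
            np.concatenate([voxel_occupancy(s, subset, scheme) for subset in subsets])
            for s in samples
        ]
    )
    df = pd.DataFrame(rows, index=[s.sample_id for s in samples], columns=names)
    return VoxelFeatureMatrix(data=df, scheme=scheme, sizes=tuple(sorted(set(sizes))))


def filter_sparse(vfm: VoxelFeatureMatrix, min_max_occupancy: float = 0.01) -> VoxelFeatureMatrix:
    """Drop features whose maximum occupancy over samples is strictly below
    the threshold ('below 1% across all samples'); values at the threshold
    survive."""
    col_max = vfm.data.max(axis=0)
    keep = col_max >= min_max_occupancy
    if not keep.any():
        raise ConfigurationError(
            f"all {len(keep)} features fall below max occupancy {min_max_occupancy}; "
            "review the threshold"
        )
    dropped = list(vfm.data.columns[~keep])
    if dropped:
        logger.info("sparsity filter dropped %d/%d features", len(dropped), len(keep))
        logger.debug("dropped features: %s", dropped)
    return VoxelFeatureMatrix(
        data=vfm.data.loc[:, keep].copy(),
        scheme=vfm.scheme,
        sizes=vfm.sizes,
        filter_threshold=min_max_occupancy,
        dropped=dropped,
    )
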