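"""Pre-processing chain: compensation, scatter gating, intensity transforms,
and fixed-count subsampling.

The logicle (biexponential) transform follows the Parks-Moore
parameterization: display scale ``y`` relates to data value ``x`` through

    x = a * exp(b*y) - c * exp(-d*y) - f

with the coefficients fixed by the top-of-scale ``T``, linearization width
``W`` (decades), total decades ``M`` and additional negative decades ``A``.
The forward transform inverts this biexponential numerically (vectorized
bisection, interval width < 1e-12) and is normalized so that ``x = T`` maps
to ``y = 1``. Mass-cytometry data use ``arcsinh(x / cofactor) * post_scale``
instead.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.optimize import brentq

from .core import ConfigurationError, EventMatrix, TransformState

__all__ = [
    "TransformParams",
    "GateSpec",
    "LogicleScale",
    "apply_compensation",
    "gate_debris",
    "logicle_transform",
    "arcsinh_transform",
    "transform_sample",
    "subsample",
]

logger = logging.getLogger(__name__)


@dataclass
class TransformParams:
    """Intensity-transform parameters.

    Defaults are the standard flow-cytometry logicle setting
    (T=262144, W=0.5, M=4.5, A=0); for CyTOF use ``kind="arcsinh"`` with
    cofactor 5 and post-scale 1/8.
    """

    kind: str = "logicle"  # "logicle" | "arcsinh"
    T: float = 262144.0
    W: float = 0.5
    M: float = 4.5
    A: float = 0.0
    cofactor: float = 5.0
    post_scale: float = 1.0 / 8.0

    def __post_init__(self) -> None:
        if self.kind not in ("logicle", "arcsinh"):
            raise ConfigurationError(f"unknown transform kind {self.kind!r}")
        if self.T <= 0 or self.M <= 0 or self.W < 0 or self.cofactor <= 0:
            raise ConfigurationError("require T > 0, M > 0, W >= 0, cofactor > 0")


class LogicleScale:
    """Parks-Moore logicle scale for one parameter set.

    ``inverse(y)`` evaluates the biexponential (display -> data);
    ``scale(x)`` numerically inverts it (data -> display in [0, y_max]).
    """

    #: display headroom above top-of-scale; values beyond clamp here
    Y_MAX = 1.5

    def __init__(self, T: float, W: float, M: float, A: float = 0.0):
        total = M + A
        self.w = W / total
        self.x2 = A / total
        self.x1 = self.x2 + self.w
        self.x0 = self.x2 + 2.0 * self.w
        self.b = total * math.log(10.0)
        self.d = self._solve_d(self.b, self.w)
        c_a = math.exp(self.x0 * (self.b + self.d))
        mf_a = math.exp(self.b * self.x1) - c_a * math.exp(-self.d * self.x1)
        self.a = T / (math.exp(self.b) - mf_a - c_a * math.exp(-self.d))
        self.c = c_a * self.a
        self.f = mf_a * self.a
        self.x_min = self.inverse(0.0)
        self.x_max = self.inverse(self.Y_MAX)

    @staticmethod
    def _solve_d(b: float, w: float) -> float:
        # root of 2*(ln d - ln b) + w*(d + b) = 0 on (0, b); w = 0 degenerates
        # to pure log scale where d = b.
        if w == 0.0:
            return b
        func = lambda d: 2.0 * (math.log(d) - math.log(b)) + w * (d + b)
        return brentq(func, 1e-12, b, xtol=1e-14, rtol=8.9e-16)

    def inverse(self, y: float | np.ndarray) -> float | np.ndarray:
        return self.a * np.exp(self.b * np.asarray(y, dtype=np.float64)) - self.c * np.exp(
            -self.d * np.asarray(y, dtype=np.float64)
        ) - self.f

    def scale(self, x: np.ndarray) -> np.ndarray:
        """Vectorized monotone inversion; out-of-domain values clamp."""
        x = np.asarray(x, dtype=np.float64)
        xc = np.clip(x, self.x_min, self.x_max)
        lo = np.zeros_like(xc)
        hi = np.full_like(xc, self.Y_MAX)
        for _ in range(64):  # interval shrinks to 1.5 * 2**-64 < 1e-18
            mid = 0.5 * (lo + hi)
            below = self.inverse(mid) < xc
            lo = np.where(below, mid, lo)
            hi = np.where(below, hi, mid)
        return 0.5 * (lo + hi)


def apply_compensation(
    em: EventMatrix,
    spillover: np.ndarray,
    fluorescence_channels: list[str] | None = None,
) -> EventMatrix:
    """Unmix fluorescence spillover by inverting the mixing matrix.

    ``spillover[i, j]`` is the fraction of channel ``j``'s true signal
    detected in channel ``i`` (``observed = spillover @ true`` per event), so
    compensation solves that linear system per event. Scatter channels (those
    not listed in ``fluorescence_channels``) are untouched.
    """
    channels = fluorescence_channels or list(em.marker_names)
    idx = [em.marker_names.index(c) for c in channels]
    spillover = np.asarray(spillover, dtype=np.float64)
    if spillover.shape != (len(idx), len(idx)):
        raise ConfigurationError(
            f"spillover is {spillover.shape}, expected {(len(idx), len(idx))}"
        )
    if abs(np.linalg.det(spillover)) < 1e-12:
        raise np.linalg.LinAlgError("spillover matrix is singular and cannot be inverted")
    values = em.values.copy()
    # observed.T = S @ true.T  =>  true = solve(S, observed.T).T
    values[:, idx] = np.linalg.solve(spillover, em.values[:, idx].T).T
    return em.with_values(values, TransformState.COMPENSATED)


@dataclass
class GateSpec:
    """Sequential polygonal gates, each in a named channel pair."""

    polygons: list[tuple[tuple[str, str], np.ndarray]] = field(default_factory=list)

    def add(self, channels: tuple[str, str], vertices) -> "GateSpec":
        vertices = np.asarray(vertices, dtype=np.float64)
        if vertices.ndim != 2 or vertices.shape[0] < 3 or vertices.shape[1] != 2:
            raise ConfigurationError("a gate polygon needs >= 3 (x, y) vertices")
        self.polygons.append((channels, vertices))
        return self


def gate_debris(em: EventMatrix, gates: GateSpec) -> EventMatrix:
    """Keep events inside every polygon (boundary counts as inside);
    surviving event order is preserved."""
    keep = np.ones(em.n_cells, dtype=bool)
    for (cx, cy), verts in gates.polygons:
        for c in (cx, cy):
            if c not in em.marker_names:
                raise ConfigurationError(f"gate references unknown channel {c!r}")
        poly = shapely.Polygon(verts)
        pts = shapely.points(em.column(cx), em.column(cy))
        keep &= shapely.covers(poly, pts)  # covers = interior + boundary
    return em.with_values(em.values[keep])


def logicle_transform(values: np.ndarray, p: TransformParams) -> np.ndarray:
    """Logicle display transform, normalized so that ``T`` maps to 1."""
    if p.kind != "logicle":
        raise ConfigurationError("TransformParams.kind must be 'logicle'")
    values = np.asarray(values, dtype=np.float64)
    if not np.isfinite(values).all():
        bad = np.flatnonzero(~np.isfinite(values.ravel()))[:10]
        raise ConfigurationError(f"non-finite input at flat indices {bad.tolist()}")
    return LogicleScale(p.T, p.W, p.M, p.A).scale(values)


def arcsinh_transform(values: np.ndarray, p: TransformParams) -> np.ndarray:
    """``arcsinh(x / cofactor) * post_scale`` elementwise."""
    if p.kind != "arcsinh":
        raise ConfigurationError("TransformParams.kind must be 'arcsinh'")
    values = np.asarray(values, dtype=np.float64)
    if not np.isfinite(values).all():
        bad = np.flatnonzero(~np.isfinite(values.ravel()))[:10]
        raise ConfigurationError(f"non-finite input at flat indices {bad.tolist()}")
    return np.arcsinh(values / p.cofactor) * p.post_scale


def transform_sample(em: EventMatrix, p: TransformParams) -> EventMatrix:
    fn = logicle_transform if p.kind == "logicle" else arcsinh_transform
    return em.with_values(fn(em.values, p), TransformState.TRANSFORMED)


def subsample(em: EventMatrix, n: int, seed: int) -> EventMatrix:
    """Uniform sample of exactly ``n`` events without replacement (seeded).

    Samples with fewer than ``n`` events are returned unchanged with a logged
    warning, matching common practice for small files.
    """
    if n <= 0:
        raise ConfigurationError("subsample size must be >= 1")
    if em.n_cells <= n:
        if em.n_cells < n:
            logger.warning(
                "sample %s has %d events < requested %d; returning all",
                em.sample_id, em.n_cells, n,
            )
        return em
    rng = np.random.default_rng(seed)
    rows = np.sort(rng.choice(em.n_cells, size=n, replace=False))
    logger.debug("subsampled %s to %d events with seed %d", em.sample_id, n, seed)
    return em.with_values(em.values[rows])
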