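"""Compensation, gating, intensity transforms and subsampling."""

import logging

import numpy as np
import pytest
from scipy.optimize import brentq

from cytovoxel.core import ConfigurationError, TransformState
from cytovoxel.preprocess import (
    GateSpec,
    LogicleScale,
    TransformParams,
    apply_compensation,
    arcsinh_transform,
    gate_debris,
    logicle_transform,
    subsample,
)

from conftest import make_sample

# ---------------------------------------------------------------------------
# compensation


def test_identity_spillover_is_noop(rng):
    em = make_sample(rng.uniform(0, 100, (50, 3)), transform_state=TransformState.RAW)
    out = apply_compensation(em, np.eye(3))
    assert np.allclose(out.values, em.values)
    assert out.transform_state is TransformState.COMPENSATED


def test_two_by_two_hand_oracle():
    # 10% of channel 1's true signal bleeds into channel 0:
    # observed (110, 100) must unmix to (100, 100).
    em = make_sample([[110.0, 100.0]], transform_state=TransformState.RAW)
    out = apply_compensation(em, np.array([[1.0, 0.1], [0.0, 1.0]]))
    assert np.allclose(out.values, [[100.0, 100.0]])


def test_compensate_then_remix_roundtrip(rng):
    em = make_sample(rng.uniform(0, 500, (200, 4)), transform_state=TransformState.RAW)
    spill = np.eye(4) + rng.uniform(0, 0.15, (4, 4)) * (1 - np.eye(4))
    comp = apply_compensation(em, spill)
    remixed = (spill @ comp.values.T).T
    assert np.allclose(remixed, em.values, rtol=1e-9, atol=1e-9)


def test_singular_spillover_raises(rng):
    em = make_sample(rng.uniform(0, 1, (5, 2)), transform_state=TransformState.RAW)
    with pytest.raises(np.linalg.LinAlgError, match="spillover"):
        apply_compensation(em, np.ones((2, 2)))


# ---------------------------------------------------------------------------
# gating


def _ray_cast(point, verts):
    """Independent even-odd point-in-polygon oracle (boundary not handled)."""
    x, y = point
    inside = False
    n = len(verts)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            if x < x1 + (y - y1) * (x2 - x1) / (y2 - y1):
                inside = not inside
    return inside


def test_bounding_box_gate_keeps_everything(rng):
    em = make_sample(rng.uniform(0, 1, (100, 2)), ["FSC", "SSC"])
    gate = GateSpec().add(("FSC", "SSC"), [(-1, -1), (2, -1), (2, 2), (-1, 2)])
    assert gate_debris(em, gate).n_cells == 100


def test_unit_square_gate_geometry():
    em = make_sample([[0.5, 0.5], [2.0, 2.0]], ["FSC", "SSC"])
    gate = GateSpec().add(("FSC", "SSC"), [(0, 0), (1, 0), (1, 1), (0, 1)])
    out = gate_debris(em, gate)
    assert out.n_cells == 1
    assert np.allclose(out.values[0], [0.5, 0.5])


def test_boundary_counts_as_inside():
    em = make_sample([[0.0, 0.5], [1.0, 1.0]], ["FSC", "SSC"])
    gate = GateSpec().add(("FSC", "SSC"), [(0, 0), (1, 0), (1, 1), (0, 1)])
    assert gate_debris(em, gate).n_cells == 2


def test_gate_matches_ray_casting_oracle(rng):
    verts = [(0.1, 0.1), (0.9, 0.2), (0.7, 0.9), (0.4, 0.6), (0.15, 0.8)]  # non-convex
    pts = rng.uniform(0, 1, (100, 2))
    em = make_sample(pts, ["FSC", "SSC"])
    kept = gate_debris(em, GateSpec().add(("FSC", "SSC"), verts)).values
    oracle = np.array([_ray_cast(p, verts) for p in pts])
    assert np.array_equal(kept, pts[oracle])


def test_gate_preserves_event_order(rng):
    pts = rng.uniform(0, 1, (50, 2))
    em = make_sample(pts, ["FSC", "SSC"])
    kept = gate_debris(em, GateSpec().add(("FSC", "SSC"), [(0, 0), (0.5, 0), (0.5, 0.5), (0, 0.5)]))
    mask = (pts[:, 0] <= 0.5) & (pts[:, 1] <= 0.5)
    assert np.array_equal(kept.values, pts[mask])


def test_gate_unknown_channel_raises():
    em = make_sample([[0.5, 0.5]], ["FSC", "SSC"])
    gate = GateSpec().add(("FSC", "nope"), [(0, 0), (1, 0), (1, 1)])
    with pytest.raises(ConfigurationError, match="nope"):
        gate_debris(em, gate)


# ---------------------------------------------------------------------------
# transforms

PAPER_LOGICLE = TransformParams(kind="logicle")  # T=262144, W=0.5, M=4.5, A=0


def _logicle_oracle(x: float) -> float:
    """High-precision scalar inversion, independent of the vectorized path."""
    s = LogicleScale(PAPER_LOGICLE.T, PAPER_LOGICLE.W, PAPER_LOGICLE.M, PAPER_LOGICLE.A)
    x = min(max(x, s.x_min), s.x_max)
    return brentq(lambda y: s.inverse(y) - x, 0.0, s.Y_MAX, xtol=1e-14)


def test_logicle_top_of_scale_maps_to_one():
    y = logicle_transform(np.array([PAPER_LOGICLE.T]), PAPER_LOGICLE)
    assert y[0] == pytest.approx(1.0, abs=1e-6)
    assert y[0] == pytest.approx(_logicle_oracle(PAPER_LOGICLE.T), abs=1e-8)


def test_logicle_zero_maps_inside_unit_interval():
    y = float(logicle_transform(np.array([0.0]), PAPER_LOGICLE)[0])
    assert 0.0 < y < 1.0
    assert y == pytest.approx(_logicle_oracle(0.0), abs=1e-6)


@pytest.mark.parametrize("x", [-100.0, 0.0, 3.7, 512.0, 1e4, 262144.0])
def test_logicle_matches_scalar_oracle(x):
    y = float(logicle_transform(np.array([x]), PAPER_LOGICLE)[0])
    assert y == pytest.approx(_logicle_oracle(x), abs=1e-8)


def test_logicle_strictly_monotone(rng):
    x = np.sort(rng.uniform(-1000, 262144, 300))
    y = logicle_transform(x, PAPER_LOGICLE)
    assert np.all(np.diff(y) > 0)


def test_logicle_rejects_non_finite():
    with pytest.raises(ConfigurationError, match="indices"):
        logicle_transform(np.array([1.0, np.nan]), PAPER_LOGICLE)


ARCSINH = TransformParams(kind="arcsinh", cofactor=5.0, post_scale=1.0 / 8.0)


def test_arcsinh_closed_forms():
    assert arcsinh_transform(np.array([0.0]), ARCSINH)[0] == 0.0
    # arcsinh(1) = ln(1 + sqrt(2))
    assert arcsinh_transform(np.array([5.0]), ARCSINH)[0] == pytest.approx(
        np.log(1 + np.sqrt(2)) / 8, abs=1e-6
    )
    assert arcsinh_transform(np.array([5 * np.sinh(8.0)]), ARCSINH)[0] == pytest.approx(
        1.0, abs=1e-9
    )


def test_arcsinh_preserves_rank_order(rng):
    x = rng.normal(0, 100, 500)
    y = arcsinh_transform(x, ARCSINH)
    assert np.array_equal(np.argsort(x), np.argsort(y))


# ---------------------------------------------------------------------------
# subsampling


def test_subsample_exact_count_of_input_rows(rng):
    em = make_sample(rng.uniform(0, 1, (50_000, 3)))
    out = subsample(em, 30_000, seed=11)
    assert out.n_cells == 30_000
    # every output row is an input row
    seen = {tuple(r) for r in em.values[:, :2].round(12)}
    assert all(tuple(r) in seen for r in out.values[:200, :2].round(12))


def test_subsample_small_input_passthrough_with_warning(rng, caplog):
    em = make_sample(rng.uniform(0, 1, (100, 2)))
    with caplog.at_level(logging.WARNING, logger="cytovoxel.preprocess"):
        out = subsample(em, 500, seed=0)
    assert out.n_cells == 100
    assert "returning all" in caplog.text


def test_subsample_deterministic(rng):
    em = make_sample(rng.uniform(0, 1, (1000, 2)))
    a = subsample(em, 300, seed=42)
    b = subsample(em, 300, seed=42)
    assert np.array_equal(a.values, b.values)


def test_subsample_rejects_nonpositive(rng):
    em = make_sample(rng.uniform(0, 1, (10, 2)))
    with pytest.raises(ConfigurationError):
        subsample(em, 0, seed=0)
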