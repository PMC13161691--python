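import numpy as np
import pytest

from cytovoxel.core import EventMatrix, TransformState


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def uniform_sample(rng):
    """200 cells x 3 markers, uniform on [0, 1], already in normalized units."""
    return EventMatrix(
        rng.uniform(0, 1, (200, 3)),
        ["CD3", "CD19", "CD8"],
        sample_id="u1",
        batch_id="b1",
        transform_state=TransformState.TRANSFORMED,
    )


def make_sample(values, markers=None, sample_id="s", batch_id="b", **kw):
    values = np.asarray(values, dtype=float)
    markers = markers or [f"M{i}" for i in range(values.shape[1])]
    kw.setdefault("transform_state", TransformState.TRANSFORMED)
    return EventMatrix(values, markers, sample_id, batch_id, **kw)
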