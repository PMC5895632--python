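import numpy as np
import pytest

from shapegraph.data_model import VolumeSeries
from shapegraph.mapper import ShapeGraph


def graph_from_networkx(g) -> ShapeGraph:
    """One frame per node; edges copied. For metric unit tests."""
    n = g.number_of_nodes()
    return ShapeGraph(
        nodes=[np.asarray([i]) for i in range(n)],
        edges=sorted(tuple(sorted(e)) for e in g.edges),
        frame_count=n,
    )


def single_voxel_series(values, tr: float = 1.0) -> VolumeSeries:
    """Frames x 1 series over a one-voxel mask."""
    data = np.asarray(values, dtype=float).reshape(-1, 1)
    return VolumeSeries(data=data, tr=tr, mask=np.ones((1, 1, 1), dtype=bool))


@pytest.fixture(scope="session")
def small_mask():
    from shapegraph.nulls import synthetic_brain_mask
    return synthetic_brain_mask(shape=(8, 8, 8), radius=3.5)


@pytest.fixture(scope="session")
def clustered_series():
    """60 frames in 3 well-separated clusters of 20, 30 voxels."""
    rng = np.random.default_rng(7)
    centers = rng.normal(size=(3, 30)) * 20.0
    data = np.concatenate([c + rng.normal(size=(20, 30)) for c in centers])
    mask = np.zeros((30, 1, 1), dtype=bool)
    mask[:, 0, 0] = True
    labels = np.repeat(["a", "b", "c"], 20)
    return VolumeSeries(data=data, tr=1.0, mask=mask), labels
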