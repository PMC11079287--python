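import numpy as np
import pytest

from slidegrid import GridLabelMap, mesh_layout
from slidegrid.gridding import level_for_edge


def make_map(labels, mpp=0.25, grid_edge_mm=0.25, source="test",
             scores=None, positive_area_um2=None) -> GridLabelMap:
    """Build a GridLabelMap whose slide exactly tiles the label lattice."""
    labels = np.atleast_2d(np.asarray(labels, dtype=bool))
    n_rows, n_cols = labels.shape
    px_per_grid = grid_edge_mm * 1000.0 / mpp
    layout = mesh_layout(int(round(n_cols * px_per_grid)),
                         int(round(n_rows * px_per_grid)),
                         mpp, grid_edge_mm)
    return GridLabelMap(layout=layout, labels=labels,
                        level=level_for_edge(grid_edge_mm), source=source,
                        scores=scores, positive_area_um2=positive_area_um2)


@pytest.fixture
def map_factory():
    return make_map


@pytest.fixture
def rng():
    return np.random.default_rng(20240425)
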