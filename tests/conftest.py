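import numpy as np
import pytest

from junctionlab import WaypointTrace, build_cell_path, generate_monolayer


@pytest.fixture(scope="session")
def monolayer():
    """One zero-noise synthetic monolayer shared across read-only tests."""
    return generate_monolayer(n_cells=20, image_size=512, seed=0)


@pytest.fixture()
def rect_path():
    """A 30x200 rectangular cell path in a 240x240 field.

    The first rasterized segment runs along row 0 from column 0 to 199, so
    path indices 0..199 are that straight top edge - convenient for
    constructing junction pieces with known covered stretches.
    """
    trace = WaypointTrace("rect", np.array([(0, 0), (0, 200), (30, 200), (30, 0)]))
    return trace, build_cell_path(trace, (240, 240))


def star_vertices(center=(60, 60), r_outer=50, r_inner=20, n_points=5):
    """A 5-point star polygon (simple, strongly concave)."""
    angles = np.linspace(0, 2 * np.pi, 2 * n_points, endpoint=False)
    radii = np.where(np.arange(2 * n_points) % 2 == 0, r_outer, r_inner)
    rows = center[0] + radii * np.cos(angles)
    cols = center[1] + radii * np.sin(angles)
    return np.column_stack([np.rint(rows), np.rint(cols)]).astype(np.int64)


def circle_vertices(center=(64, 64), radius=50, n=64):
    angles = np.linspace(0, 2 * np.pi, n, endpoint=False)
    rows = center[0] + radius * np.cos(angles)
    cols = center[1] + radius * np.sin(angles)
    return np.column_stack([np.rint(rows), np.rint(cols)]).astype(np.int64)
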