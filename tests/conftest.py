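import numpy as np
import pytest

from rcspt.geometry import PolygonRegion, regular_polygon, square
from rcspt.io import CellAnnotation, Trajectory


@pytest.fixture
def unit_square() -> PolygonRegion:
    return square(1.0)


@pytest.fixture
def big_square() -> PolygonRegion:
    return square(10.0)


@pytest.fixture
def nucleus() -> PolygonRegion:
    return regular_polygon(48, 6.0)


@pytest.fixture
def annotation(nucleus) -> CellAnnotation:
    """Static annotation: one compartment disc inside a round nucleus."""
    comp = regular_polygon(32, 1.5, 1.0, 0.0)
    return CellAnnotation.static("cell0", nucleus, compartments=[comp])


def make_trajectory(traj_id, frames, xy, cell_id="cell0", max_gap=1):
    return Trajectory(
        traj_id=traj_id,
        cell_id=cell_id,
        frames=np.asarray(frames, dtype=int),
        xy=np.asarray(xy, dtype=float),
        max_gap=max_gap,
    )


@pytest.fixture
def straight_trajectory():
    """8 gap-free points walking along x in 0.2 µm steps."""
    frames = np.arange(8)
    xy = np.column_stack([0.2 * frames, np.zeros(8)])
    return make_trajectory("t0", frames, xy)
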