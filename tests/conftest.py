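import numpy as np
import pytest

from laa_stasis.meshing import Mesh, segments_from_polygon, triangulate_domain

UNIT_SQUARE = np.array([[0, 0], [1, 0], [1, 1], [0, 1], [0, 0]], float)


@pytest.fixture(scope="session")
def unit_square_mesh() -> Mesh:
    return triangulate_domain(segments_from_polygon(UNIT_SQUARE), 0.08)


@pytest.fixture(scope="session")
def channel_mesh() -> Mesh:
    """[0,3]x[0,1] channel: no-slip top/bottom, open (p=0) left/right."""
    segs = [
        ("wall_bottom", np.array([[0, 0], [3, 0]], float)),
        ("pv_inlet_right", np.array([[3, 0], [3, 1]], float)),
        ("wall_top", np.array([[3, 1], [0, 1]], float)),
        ("pv_inlet_left", np.array([[0, 1], [0, 0]], float)),
    ]
    return triangulate_domain(segs, 0.07)


@pytest.fixture(scope="session")
def two_triangle_mesh() -> Mesh:
    """Unit square split along the diagonal: one LA and one LAA cell."""
    vertices = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
    cells = np.array([[0, 1, 2], [0, 2, 3]])
    boundary = np.array([[0, 1], [1, 2], [2, 3], [3, 0]])
    labels = np.array(["wall"] * 4)
    region = np.array(["LA", "LAA"])
    return Mesh(vertices, cells, boundary, labels, region, h=1.0)
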