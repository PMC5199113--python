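import numpy as np
import pytest

from hnmargin import fem, phantom as ph
from hnmargin.landmarks import LandmarkSet


@pytest.fixture(scope="session")
def tiny_phantom():
    return ph.generate_phantom(ph.PhantomSpec.tiny(), seed=0)


@pytest.fixture(scope="session")
def tiny_locator(tiny_phantom):
    return fem.MeshLocator(tiny_phantom.mesh)


@pytest.fixture(scope="session")
def tiny_ctv_warper(tiny_phantom, tiny_locator):
    """Shared CTV mask warper (its grid embedding is expensive to build)."""
    return fem.MaskWarper(tiny_phantom.ctv, tiny_phantom.mesh, tiny_locator)


@pytest.fixture(scope="session")
def unit_tet_mesh():
    """Single regular tetrahedron, 10 mm scale."""
    nodes = 10.0 * np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
    return fem.TetMesh(nodes, np.array([[0, 1, 2, 3]]))


@pytest.fixture(scope="session")
def two_cube_mesh():
    """Small structured mesh: 2x1x1 cells split into Kuhn tetrahedra."""
    import itertools

    nodes = []
    index = {}
    for i in range(3):
        for j in range(2):
            for k in range(2):
                index[(i, j, k)] = len(nodes)
                nodes.append([10.0 * i, 10.0 * j, 10.0 * k])
    paths = []
    for perm in itertools.permutations(range(3)):
        steps = [np.zeros(3, int)]
        for ax in perm:
            s = steps[-1].copy()
            s[ax] = 1
            steps.append(s)
        paths.append(steps)
    tets = []
    for ci in range(2):
        for p in paths:
            tets.append([index[(ci + int(v[0]), int(v[1]), int(v[2]))] for v in p])
    nodes = np.array(nodes)
    tets = np.array(tets)
    e = np.stack([nodes[tets[:, 1]] - nodes[tets[:, 0]],
                  nodes[tets[:, 2]] - nodes[tets[:, 0]],
                  nodes[tets[:, 3]] - nodes[tets[:, 0]]], axis=2)
    neg = np.linalg.det(e) < 0
    tets[neg] = tets[neg][:, [0, 2, 1, 3]]
    return fem.TetMesh(nodes, tets)


def make_landmark_set(positions, region="skull", fraction_id=0, valid=None):
    positions = np.asarray(positions, dtype=float)
    names = [f"lm{i}" for i in range(len(positions))]
    return LandmarkSet(names, positions, [region] * len(positions),
                       valid=valid, fraction_id=fraction_id)


@pytest.fixture
def skull_landmarks():
    """Six non-collinear skull landmarks."""
    pts = np.array([
        [30, 0, 200], [-30, 0, 200], [0, 30, 205], [0, -30, 205],
        [0, 0, 235], [20, 20, 190],
    ], float)
    return make_landmark_set(pts)


def random_rotation(rng, max_angle_rad):
    axis = rng.standard_normal(3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(-max_angle_rad, max_angle_rad)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)
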