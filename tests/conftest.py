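import numpy as np
import pytest

from femoneck import msk, subject
from femoneck.mesh import TetMesh, extract_surface


@pytest.fixture(scope="session")
def default_spec():
    return subject.SubjectSpec()


@pytest.fixture(scope="session")
def femur(default_spec):
    return subject.generate_femur(default_spec)


@pytest.fixture(scope="session")
def density(default_spec, femur):
    return subject.generate_density(default_spec, femur)


@pytest.fixture(scope="session")
def linkage(default_spec, femur):
    return msk.build_linkage(default_spec, femur)


@pytest.fixture(scope="session")
def gait_trial(default_spec):
    return subject.generate_gait(default_spec)


@pytest.fixture(scope="session")
def body_solution(linkage, gait_trial):
    """(moments, MuscleForceSolution, JointLoads) for the default subject."""
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return msk.solve_gait(linkage, gait_trial)


@pytest.fixture(scope="session")
def sweep(default_spec):
    """Full 100-interval body-organ sweep on the default subject."""
    from femoneck.coupling import run_gait_sweep
    return run_gait_sweep(default_spec)


def make_block_mesh(nx, ny, nz, hx=1.0, hy=1.0, hz=1.0):
    """Structured Kuhn-subdivided block mesh for element-level tests."""
    xs, ys, zs = (np.arange(n + 1) * h for n, h in ((nx, hx), (ny, hy), (nz, hz)))
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    idx = np.arange((nx + 1) * (ny + 1) * (nz + 1)).reshape(nx + 1, ny + 1, nz + 1)
    kuhn = [[0b000, 0b100, 0b110, 0b111], [0b000, 0b100, 0b111, 0b101],
            [0b000, 0b010, 0b111, 0b110], [0b000, 0b010, 0b011, 0b111],
            [0b000, 0b001, 0b101, 0b111], [0b000, 0b001, 0b111, 0b011]]
    tets = []
    for t in kuhn:
        cols = []
        for b in t:
            sl = tuple(slice(1, None) if (b >> s) & 1 else slice(0, -1)
                       for s in (2, 1, 0))
            cols.append(idx[sl].ravel())
        tets.append(np.stack(cols, axis=1))
    tets = np.concatenate(tets)
    return TetMesh(nodes, tets, extract_surface(tets))


@pytest.fixture
def block_mesh():
    return make_block_mesh
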