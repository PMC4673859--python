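import numpy as np
import pytest

from surfdiff.geometry import build_mesh


@pytest.fixture(scope="session")
def square_mesh():
    """Unit square split along its diagonal into two coplanar triangles."""
    tris = [
        [(0, 0, 0), (1, 0, 0), (1, 1, 0)],
        [(0, 0, 0), (1, 1, 0), (0, 1, 0)],
    ]
    return build_mesh(tris, ["fast", "slow"])


@pytest.fixture(scope="session")
def roof_mesh():
    """Two non-coplanar triangles sharing an edge (a folded 'roof')."""
    tris = [
        [(0, 0, 0), (1, 0, 0), (1, 1, 1)],
        [(0, 0, 0), (1, 1, 1), (0, 1, 1)],
    ]
    return build_mesh(tris, ["a", "b"])


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
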