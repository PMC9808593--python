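import numpy as np
import pytest

import helixhand as hh


@pytest.fixture(scope="session")
def spec():
    return hh.default_paper_spec()


@pytest.fixture(scope="session")
def g4(spec):
    return hh.g4_dataset(spec, seed=11)


@pytest.fixture(scope="session")
def dh(spec):
    return hh.duplex_dataset(spec, seed=12)


@pytest.fixture()
def duplex_fixture(tmp_path):
    """A 4-residue idealized duplex strand written to disk."""
    text, truth = hh.make_fixture_structure("idealized-duplex", 4)
    path = tmp_path / "duplex.pdb"
    path.write_text(text)
    return path, truth


def hulls_strictly_separable(a, b):
    """Convex hulls of two 2D point sets are disjoint iff the sets are
    strictly linearly separable (LP feasibility with unit margin)."""
    from scipy.optimize import linprog

    n_a, n_b = len(a), len(b)
    # variables: w1, w2, bias; constraints w.x + b <= -1 (a), >= +1 (b)
    A_ub = np.vstack([
        np.hstack([a, np.ones((n_a, 1))]),
        -np.hstack([b, np.ones((n_b, 1))]),
    ])
    b_ub = -np.ones(n_a + n_b)
    res = linprog(c=[0, 0, 0], A_ub=A_ub, b_ub=b_ub,
                  bounds=[(None, None)] * 3, method="highs")
    return res.status == 0


def rigid_transform(rng):
    """A uniformly random rotation plus translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    shift = rng.normal(scale=10.0, size=3)
    return rot, shift
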