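import numpy as np
import pytest

import complexqa as cq


@pytest.fixture(scope="session")
def toy_native():
    return cq.make_toy_complex(n_res_receptor=16, n_res_ligand=12, seed=3)


@pytest.fixture(scope="session")
def toy_mapping(toy_native):
    return cq.map_residues(toy_native, toy_native)


@pytest.fixture(scope="session")
def ligand_axis(toy_native):
    coords = np.array([a.position for r in toy_native.partner_residues("ligand")
                       for a in r.atoms])
    centered = coords - coords.mean(axis=0)
    return np.linalg.svd(centered, full_matrices=False)[2][0]


@pytest.fixture(scope="session")
def noiseless_benchmark():
    """20 cases x 5 models, noiseless confidence, fixed seed."""
    cases, table = cq.generate_benchmark(n_cases=20, models_per_case=5,
                                         noise_sd=0.0, seed=7)
    return cases, table


def random_rigid_transform(rng):
    """A uniform random proper rotation and a random translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    trans = rng.normal(scale=10.0, size=3)
    return rot, trans


def apply_rigid(structure, rot, trans):
    """Apply a global rigid transform to every atom of a complex."""
    import copy

    out = copy.deepcopy(structure)
    for res in out.residues:
        for a in res.atoms:
            a.position = rot @ a.position + trans
    return out
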