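"""Shared fixtures: direction sets, dense quadrature oracles, tiny cohorts."""

import numpy as np
import pytest

from amura.sh_core import SHBasisSpec, PenaltySpec, eval_basis
from amura.synthetic_cohort import make_directions, make_scheme


def fibonacci_sphere(n: int = 20000) -> np.ndarray:
    """Near-uniform dense point set on S² — the brute-force quadrature grid."""
    i = np.arange(n) + 0.5
    polar = np.arccos(1.0 - 2.0 * i / n)
    azimuth = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack([
        np.cos(azimuth) * np.sin(polar),
        np.sin(azimuth) * np.sin(polar),
        np.cos(polar),
    ])


@pytest.fixture(scope="session")
def dirs61() -> np.ndarray:
    return make_directions(61)


@pytest.fixture(scope="session")
def scheme61():
    return make_scheme()


@pytest.fixture(scope="session")
def sphere_dense() -> np.ndarray:
    return fibonacci_sphere(20000)


@pytest.fixture(scope="session")
def basis_spec() -> SHBasisSpec:
    return SHBasisSpec(order=6)


@pytest.fixture(scope="session")
def B61(dirs61, basis_spec) -> np.ndarray:
    return eval_basis(dirs61, basis_spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Haar-ish random rotation matrix via QR."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
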