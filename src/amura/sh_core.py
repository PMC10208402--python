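"""Real symmetric spherical-harmonic basis and penalized least-squares fitting.

Every apparent q-space metric in this package reduces to an angular average of
some power of the apparent diffusivity profile D(u) on the acquisition shell.
Those averages are computed by expanding the sampled profile in a real,
symmetric (even-order) spherical-harmonic basis, fitted by least squares with a
Laplace-Beltrami roughness penalty, and reading the average off the degree-0
coefficient (or off an equatorial resampling of the expansion).

Basis convention
----------------
Real, orthonormal on the unit sphere, even degrees l = 0, 2, ..., L only
(diffusion signals are antipodally symmetric).  Coefficients are ordered by
increasing l, and within each l by m = -l, ..., 0, ..., l, with

    Y_lm^real = sqrt(2) * (-1)^m * Im(Y_l^|m|)   for m < 0
    Y_l0^real = Y_l^0                            for m = 0
    Y_lm^real = sqrt(2) * (-1)^m * Re(Y_l^m)     for m > 0

where Y_l^m are the complex orthonormal spherical harmonics.  This is the
standard modified-real construction; downstream quantities (spherical means,
anisotropy power ratios) depend only on c_00 and the total power and are
invariant to the ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import sph_harm_y

__all__ = [
    "SHBasisSpec",
    "SHCoeffs",
    "PenaltySpec",
    "eval_basis",
    "fit_sh",
    "spherical_mean",
    "evaluate",
    "eval_on_circle",
]


@dataclass(frozen=True)
class SHBasisSpec:
    """Even-order real symmetric SH basis up to degree ``order``."""

    order: int = 6

    def __post_init__(self) -> None:
        if self.order < 0 or self.order % 2 != 0:
            raise ValueError(f"SH order must be a nonnegative even integer, got {self.order}")

    @property
    def n_coeffs(self) -> int:
        L = self.order
        return (L + 1) * (L + 2) // 2

    def lm_pairs(self) -> list[tuple[int, int]]:
        """(l, m) index pairs in coefficient order."""
        return [(l, m) for l in range(0, self.order + 1, 2) for m in range(-l, l + 1)]


@dataclass(frozen=True)
class PenaltySpec:
    """Laplace-Beltrami penalty: diagonal weight l^2 (l+1)^2 per coefficient.

    ``lambda_lb`` is dimensionless; 0 disables regularization.  The l = 0 term
    carries zero penalty, so constants are never shrunk.
    """

    lambda_lb: float = 0.006

    def __post_init__(self) -> None:
        if self.lambda_lb < 0:
            raise ValueError("lambda_lb must be >= 0")

    def diagonal(self, spec: SHBasisSpec) -> np.ndarray:
        return np.array([l * l * (l + 1) * (l + 1) for l, _ in spec.lm_pairs()], dtype=float)


@dataclass
class SHCoeffs:
    """Coefficient vector(s) of a spherical function, shape (..., n_coeffs)."""

    spec: SHBasisSpec
    c: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=float)
        if self.c.shape[-1] != self.spec.n_coeffs:
            raise ValueError(
                f"coefficient axis has length {self.c.shape[-1]}, "
                f"expected {self.spec.n_coeffs} for order {self.spec.order}"
            )

    @property
    def total_power(self) -> np.ndarray:
        """Sum of squared coefficients (Parseval power of the expansion)."""
        return np.sum(self.c**2, axis=-1)


def _to_polar(directions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = np.asarray(directions, dtype=float)
    z = np.clip(d[..., 2], -1.0, 1.0)
    theta = np.arccos(z)
    phi = np.arctan2(d[..., 1], d[..., 0])
    return theta, phi


def eval_basis(directions: np.ndarray, spec: SHBasisSpec = SHBasisSpec()) -> np.ndarray:
    """Design matrix B of shape (n_dirs, n_coeffs) for unit ``directions``.

    Raises
    ------
    ValueError
        If any direction deviates from unit norm by more than 1e-6.
    """
    d = np.atleast_2d(np.asarray(directions, dtype=float))
    norms = np.linalg.norm(d, axis=-1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        worst = float(np.abs(norms - 1.0).max())
        raise ValueError(f"directions must be unit vectors (max norm deviation {worst:.2e})")
    theta, phi = _to_polar(d)
    cols = []
    for l, m in spec.lm_pairs():
        if m == 0:
            cols.append(np.real(sph_harm_y(l, 0, theta, phi)))
        elif m > 0:
            y = sph_harm_y(l, m, theta, phi)
            cols.append(np.sqrt(2.0) * (-1.0) ** m * np.real(y))
        else:
            y = sph_harm_y(l, -m, theta, phi)
            cols.append(np.sqrt(2.0) * (-1.0) ** m * np.imag(y))
    return np.stack(cols, axis=-1)


def fit_sh(
    values: np.ndarray,
    B: np.ndarray,
    penalty: PenaltySpec = PenaltySpec(),
    spec: SHBasisSpec | None = None,
) -> SHCoeffs:
    """Penalized least-squares SH fit: c = (B'B + λR)^-1 B' y.

    Parameters
    ----------
    values : array, shape (..., n_dirs)
        Per-direction samples; leading axes are independent problems (voxels).
    B : array, shape (n_dirs, n_coeffs)
        Design matrix from :func:`eval_basis` at the sampling directions.
    penalty : PenaltySpec
        Laplace-Beltrami weight; R = diag(l^2 (l+1)^2).
    """
    if spec is None:
        n = B.shape[1]
        L = int(round((-3 + np.sqrt(1 + 8 * n)) / 2))
        spec = SHBasisSpec(order=L)
    y = np.asarray(values, dtype=float)
    if y.shape[-1] != B.shape[0]:
        raise ValueError(f"values last axis ({y.shape[-1]}) must match n_dirs ({B.shape[0]})")
    R = penalty.diagonal(spec)
    M = B.T @ B + penalty.lambda_lb * np.diag(R)
    cond = np.linalg.cond(M)
    if cond > 1e12:
        raise np.linalg.LinAlgError(
            f"ill-conditioned SH normal matrix (condition number {cond:.3e}); "
            "need more / better-spread directions or a larger penalty"
        )
    rhs = np.moveaxis(y @ B, -1, 0)  # (n_coeffs, ...)
    coef = np.moveaxis(np.linalg.solve(M, rhs.reshape(M.shape[0], -1)), 0, -1)
    return SHCoeffs(spec=spec, c=coef.reshape(y.shape[:-1] + (M.shape[0],)))


def spherical_mean(coeffs: SHCoeffs) -> np.ndarray:
    """Mean of the represented function over the sphere: c_00 / (2 sqrt(pi))."""
    return coeffs.c[..., 0] / (2.0 * np.sqrt(np.pi))


def evaluate(coeffs: SHCoeffs, directions: np.ndarray) -> np.ndarray:
    """Evaluate the expansion at unit ``directions``; shape (..., n_dirs)."""
    B = eval_basis(directions, coeffs.spec)
    return coeffs.c @ B.T


def _orthonormal_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors spanning the plane orthogonal to ``axis``.

    Deterministic: the seed vector is the coordinate axis least aligned with
    ``axis``, so nearby axes get nearby frames.
    """
    a = np.asarray(axis, dtype=float)
    seed = np.zeros(3)
    seed[np.argmin(np.abs(a))] = 1.0
    u = seed - np.dot(seed, a) * a
    u /= np.linalg.norm(u)
    v = np.cross(a, u)
    return u, v


def eval_on_circle(coeffs: SHCoeffs, axis: np.ndarray, K: int = 64) -> np.ndarray:
    """Sample the expansion at K equally spaced points on the equator ⊥ axis.

    The trapezoid mean of these samples integrates an order-L expansion
    exactly for K > L (the restriction to a great circle is a trigonometric
    polynomial of degree ≤ L).  K = 64 is far inside the exact regime for the
    default L = 6.
    """
    if K < 16:
        raise ValueError("K must be >= 16")
    a = np.asarray(axis, dtype=float)
    nrm = np.linalg.norm(a)
    if abs(nrm - 1.0) > 1e-6:
        raise ValueError("axis must be unit-norm")
    a = a / nrm
    u, v = _orthonormal_frame(a)
    ang = 2.0 * np.pi * np.arange(K) / K
    pts = np.cos(ang)[:, None] * u[None, :] + np.sin(ang)[:, None] * v[None, :]
    return evaluate(coeffs, pts)
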