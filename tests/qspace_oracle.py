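"""Brute-force q-space integration oracle for the apparent metrics.

Independent of the package's SH machinery: integrates the mono-exponential
attenuation E(q u) = exp(-4 π² τ q² D(u)) numerically on dense radial ×
angular grids for a tensor-model diffusivity profile D(u) = u' T u.
"""

import numpy as np
from scipy.special import gamma as gamma_fn

from conftest import fibonacci_sphere

TAU = 0.070


def tensor_adc(dirs: np.ndarray, T: np.ndarray) -> np.ndarray:
    return np.einsum("nd,de,ne->n", dirs, T, dirs)


def zeppelin_tensor(d_par: float, d_perp: float, mu: np.ndarray) -> np.ndarray:
    mu = np.asarray(mu, float) / np.linalg.norm(mu)
    return d_perp * np.eye(3) + (d_par - d_perp) * np.outer(mu, mu)


def _radial_grid(a_min: float, n: int = 2000) -> np.ndarray:
    """q grid covering the slowest Gaussian decay exp(-a_min q²)."""
    q_max = 6.0 / np.sqrt(a_min)
    return np.linspace(0.0, q_max, n)


def brute_force_moment(T: np.ndarray, gamma: float, tau: float = TAU,
                       n_sphere: int = 5000, n_radial: int = 4000) -> float:
    """∫_{R³} ||q||^γ exp(-4π²τ q² D(u)) dq by trapezoid × sphere sum."""
    dirs = fibonacci_sphere(n_sphere)
    D = tensor_adc(dirs, T)
    a = 4.0 * np.pi**2 * tau * D  # (n_sphere,)
    q = _radial_grid(a.min(), n_radial)
    radial = np.trapezoid(q[None, :]**(gamma + 2) * np.exp(-a[:, None] * q[None, :]**2),
                          q, axis=1)
    return float(4.0 * np.pi * radial.mean())


def brute_force_rtop(T: np.ndarray, tau: float = TAU, **kw) -> float:
    return brute_force_moment(T, 0.0, tau, **kw)


def brute_force_rtpp(T: np.ndarray, e1: np.ndarray, tau: float = TAU,
                     n_radial: int = 20000) -> float:
    """∫_R exp(-4π²τ q² D(e1)) dq along the principal axis."""
    a = 4.0 * np.pi**2 * tau * float(tensor_adc(e1[None, :], T)[0])
    q = _radial_grid(a, n_radial)
    return float(2.0 * np.trapezoid(np.exp(-a * q**2), q))


def brute_force_rtap(T: np.ndarray, e1: np.ndarray, tau: float = TAU,
                     n_azimuth: int = 2048, n_radial: int = 4000) -> float:
    """∫_{R²} exp(-4π²τ q² D(u)) dq over the plane orthogonal to e1."""
    e1 = np.asarray(e1, float) / np.linalg.norm(e1)
    seed = np.zeros(3)
    seed[np.argmin(np.abs(e1))] = 1.0
    u = seed - (seed @ e1) * e1
    u /= np.linalg.norm(u)
    v = np.cross(e1, u)
    ang = 2.0 * np.pi * np.arange(n_azimuth) / n_azimuth
    dirs = np.cos(ang)[:, None] * u + np.sin(ang)[:, None] * v
    a = 4.0 * np.pi**2 * tau * tensor_adc(dirs, T)
    q = _radial_grid(a.min(), n_radial)
    radial = np.trapezoid(q[None, :] * np.exp(-a[:, None] * q[None, :]**2), q, axis=1)
    return float(2.0 * np.pi * radial.mean())


def closed_form_isotropic(D: float, tau: float = TAU) -> dict:
    tau4pi = 4.0 * np.pi * tau

    def moment(g):
        p = (g + 3.0) / 2.0
        return 2.0 * np.pi * gamma_fn(p) * (4.0 * np.pi**2 * tau * D) ** (-p)

    return {"RTOP": tau4pi**-1.5 * D**-1.5, "RTPP": (tau4pi * D)**-0.5,
            "RTAP": 1.0 / (tau4pi * D), "qMSD": moment(2.0), "U12": moment(0.5)}
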