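"""Apparent q-space metrics from a single shell (AMURA).

Under the mono-exponential radial model the normalized attenuation along unit
direction u is E(q u) = exp(-4 π² τ q² D(u)), where D(u) is the apparent
diffusivity sampled at the acquired shell (b = 4 π² τ q²).  The q-space
integrals defining the return-to-origin/plane/axis probabilities and the
generalized moments then collapse to angular averages of powers of D(u):

    RTOP = (4πτ)^{-3/2} ⟨D^{-3/2}⟩_sphere                       (mm⁻³)
    RTPP = (4πτ D(e1))^{-1/2}                                   (mm⁻¹)
    RTAP = (4πτ)^{-1} ⟨D^{-1}⟩_{equator ⊥ e1}                   (mm⁻²)
    Υ^γ  = 2π Γ((γ+3)/2) (4π²τ)^{-(γ+3)/2} ⟨D^{-(γ+3)/2}⟩_sphere

with qMSD = Υ² and Υ^{1/2} the half-order moment; Υ⁰ coincides with RTOP.
Angular averages are computed by fitting a real symmetric SH series to the
required *power* of D (transform-then-fit) and reading the spherical mean off
c_00; the equatorial average uses the Funk-Hecke identity, which is exact for
a band-limited expansion.

The anisotropy indices APA (on the attenuation E(u)) and DiA (on D(u)) measure
the fraction of SH power outside the isotropic l=0 term,
t = sqrt(1 - c_00²/Σ c_lm²) ∈ [0,1], optionally passed through the contrast
rescaling σ_ε(t) = t^{3ε} / (1 - 3 t^ε + 3 t^{2ε}).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gamma as gamma_fn

from .io_gradients import DWIVolume
from . import sh_core
from .sh_core import PenaltySpec, SHBasisSpec, SHCoeffs

__all__ = [
    "QSpaceConfig",
    "AnisotropyScalingSpec",
    "ADCField",
    "adc_from_signal",
    "adc_from_signal_flat",
    "rtop",
    "rtpp",
    "rtap",
    "generalized_moment",
    "apa",
    "dia",
    "compute_amura_flat",
    "AMURA_METRIC_NAMES",
]

AMURA_METRIC_NAMES = ("RTOP", "RTPP", "RTAP", "APA", "DiA", "qMSD", "U12")

#: ADC clipping window, mm²/s; bounds the negative powers the metrics take.
ADC_CLIP = (1e-5, 1e-2)


@dataclass(frozen=True)
class QSpaceConfig:
    """Effective diffusion time τ (s) linking the shell to q-space, q² = b/(4π²τ)."""

    tau: float = 0.070

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")


@dataclass(frozen=True)
class AnisotropyScalingSpec:
    """Contrast rescaling for the anisotropy indices.

    σ_ε maps [0,1] monotonically onto [0,1]; ε < 1 expands contrast near 0,
    which is where white-matter anisotropy indices live.
    """

    enabled: bool = True
    epsilon: float = 0.4

    def apply(self, t: np.ndarray) -> np.ndarray:
        if not self.enabled:
            return t
        s = np.power(np.clip(t, 0.0, 1.0), self.epsilon)
        return s**3 / (1.0 - 3.0 * s + 3.0 * s**2)


@dataclass
class ADCField:
    """Per-voxel, per-direction apparent diffusivity on the shell.

    ``D`` has shape (n_vox, n_dirs) in mm²/s, clipped to ``clip_window``;
    ``n_clipped`` counts samples that hit the window (a QC signal — a high
    rate means the signal model or the mask is off).
    """

    D: np.ndarray
    directions: np.ndarray
    shell_b: float
    valid: np.ndarray
    clip_window: tuple[float, float] = ADC_CLIP
    n_clipped: int = 0

    @property
    def n_vox(self) -> int:
        return self.D.shape[0]


def adc_from_signal_flat(
    signal: np.ndarray,
    s0: np.ndarray,
    directions: np.ndarray,
    shell_b: float,
    clip_window: tuple[float, float] = ADC_CLIP,
) -> ADCField:
    """D(u) = -ln(S/S0)/b per voxel and direction, clipped to the window.

    Voxels with S0 <= 0 are flagged invalid (their D is set to the lower
    clip bound and ignored downstream).
    """
    s0 = np.asarray(s0, dtype=float)
    sig = np.asarray(signal, dtype=float)
    valid = s0 > 0
    s0_safe = np.where(valid, s0, 1.0)
    ratio = np.clip(sig / s0_safe[:, None], 1e-12, None)
    D = -np.log(ratio) / shell_b
    lo, hi = clip_window
    n_clipped = int(np.count_nonzero((D[valid] < lo) | (D[valid] > hi)))
    D = np.clip(D, lo, hi)
    D[~valid] = lo
    return ADCField(D=D, directions=np.asarray(directions, dtype=float),
                    shell_b=float(shell_b), valid=valid,
                    clip_window=clip_window, n_clipped=n_clipped)


def adc_from_signal(dwi: DWIVolume, clip_window: tuple[float, float] = ADC_CLIP) -> ADCField:
    """ADC field over the masked voxels of a 4D dataset (flattened order)."""
    sig = dwi.data[dwi.mask][:, dwi.scheme.dwi_indices]
    s0 = dwi.s0[dwi.mask]
    return adc_from_signal_flat(sig, s0, dwi.scheme.dwi_directions,
                                dwi.scheme.shell_b, clip_window)


def _fit_power(adc: ADCField, power: float, B: np.ndarray, penalty: PenaltySpec,
               spec: SHBasisSpec) -> SHCoeffs:
    return sh_core.fit_sh(adc.D**power, B, penalty, spec)


def _sphere_mean_power(adc: ADCField, power: float, B: np.ndarray,
                       penalty: PenaltySpec, spec: SHBasisSpec) -> np.ndarray:
    return sh_core.spherical_mean(_fit_power(adc, power, B, penalty, spec))


def rtop(adc: ADCField, cfg: QSpaceConfig = QSpaceConfig(),
         spec: SHBasisSpec = SHBasisSpec(), penalty: PenaltySpec = PenaltySpec()) -> np.ndarray:
    """Return-to-origin probability, mm⁻³."""
    B = sh_core.eval_basis(adc.directions, spec)
    mean = _sphere_mean_power(adc, -1.5, B, penalty, spec)
    return (4.0 * np.pi * cfg.tau) ** (-1.5) * mean


def rtpp(adc: ADCField, e1: np.ndarray, cfg: QSpaceConfig = QSpaceConfig(),
         spec: SHBasisSpec = SHBasisSpec(), penalty: PenaltySpec = PenaltySpec()) -> np.ndarray:
    """Return-to-plane probability, mm⁻¹, along the principal direction e1.

    D is represented in SH and evaluated at e1 (per voxel), then
    RTPP = (4πτ D(e1))^{-1/2}.
    """
    B = sh_core.eval_basis(adc.directions, spec)
    coeffs = sh_core.fit_sh(adc.D, B, penalty, spec)
    B_e1 = sh_core.eval_basis(np.atleast_2d(e1), spec)
    d_axial = np.einsum("vc,vc->v", coeffs.c, B_e1)
    d_axial = np.clip(d_axial, adc.clip_window[0], None)
    return (4.0 * np.pi * cfg.tau * d_axial) ** (-0.5)


def _legendre_at_zero(spec: SHBasisSpec) -> np.ndarray:
    """P_l(0) per coefficient — the Funk-Hecke weights of the equatorial mean."""
    vals = {}
    for l in range(0, spec.order + 1, 2):
        k = l // 2
        # P_l(0) = (-1)^{l/2} (l-1)!! / l!!
        num = np.prod(np.arange(1, l, 2, dtype=float)) if l > 0 else 1.0
        den = np.prod(np.arange(2, l + 1, 2, dtype=float)) if l > 0 else 1.0
        vals[l] = (-1.0) ** k * num / den
    return np.array([vals[l] for l, _ in spec.lm_pairs()])


def rtap(adc: ADCField, e1: np.ndarray, cfg: QSpaceConfig = QSpaceConfig(),
         spec: SHBasisSpec = SHBasisSpec(), penalty: PenaltySpec = PenaltySpec(),
         K: int = 64) -> np.ndarray:
    """Return-to-axis probability, mm⁻², about the principal direction e1.

    The equatorial mean of the fitted SH series of D^{-1} about e1 is taken
    with the Funk-Hecke identity ⟨f⟩_eq(e) = Σ c_lm P_l(0) Y_lm(e), which is
    exact for a band-limited series (identical to averaging K ≥ order+1
    equally spaced points on the great circle; ``K`` is kept for the explicit
    quadrature cross-check in :func:`amura.sh_core.eval_on_circle`).
    """
    B = sh_core.eval_basis(adc.directions, spec)
    coeffs = _fit_power(adc, -1.0, B, penalty, spec)
    w = _legendre_at_zero(spec)
    B_e1 = sh_core.eval_basis(np.atleast_2d(e1), spec)
    eq_mean = np.einsum("vc,c,vc->v", coeffs.c, w, B_e1)
    eq_mean = np.clip(eq_mean, 1.0 / adc.clip_window[1], None)
    return eq_mean / (4.0 * np.pi * cfg.tau)


def generalized_moment(adc: ADCField, gamma: float, cfg: QSpaceConfig = QSpaceConfig(),
                       spec: SHBasisSpec = SHBasisSpec(),
                       penalty: PenaltySpec = PenaltySpec()) -> np.ndarray:
    """Full q-space moment Υ^γ = ∫ ||q||^γ E(q) dq of order γ > -3.

    γ = 2 is the q-space mean squared displacement (qMSD); γ = 0 recovers
    RTOP exactly.
    """
    if gamma <= -3:
        raise ValueError("generalized moment requires gamma > -3")
    B = sh_core.eval_basis(adc.directions, spec)
    p = (gamma + 3.0) / 2.0
    mean = _sphere_mean_power(adc, -p, B, penalty, spec)
    const = 2.0 * np.pi * gamma_fn(p) * (4.0 * np.pi**2 * cfg.tau) ** (-p)
    return const * mean


def _power_fraction_index(coeffs: SHCoeffs) -> np.ndarray:
    """Raw anisotropy index t = sqrt(1 - c_00² / Σ c_lm²); 0 for zero power."""
    total = coeffs.total_power
    iso = coeffs.c[..., 0] ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.sqrt(np.clip(1.0 - iso / np.where(total > 0, total, 1.0), 0.0, 1.0))
    return np.where(total > 0, t, 0.0)


def apa(signal: np.ndarray, s0: np.ndarray, directions: np.ndarray,
        spec: SHBasisSpec = SHBasisSpec(), penalty: PenaltySpec = PenaltySpec(),
        scaling: AnisotropyScalingSpec = AnisotropyScalingSpec()) -> np.ndarray:
    """Apparent propagator anisotropy from the shell attenuation E(u) = S/S0."""
    s0 = np.asarray(s0, dtype=float)
    s0_safe = np.where(s0 > 0, s0, 1.0)
    E = np.asarray(signal, dtype=float) / s0_safe[:, None]
    B = sh_core.eval_basis(directions, spec)
    coeffs = sh_core.fit_sh(E, B, penalty, spec)
    return scaling.apply(_power_fraction_index(coeffs))


def dia(adc: ADCField, spec: SHBasisSpec = SHBasisSpec(),
        penalty: PenaltySpec = PenaltySpec(),
        scaling: AnisotropyScalingSpec = AnisotropyScalingSpec()) -> np.ndarray:
    """Diffusion anisotropy: same power-fraction index, taken on D(u)."""
    B = sh_core.eval_basis(adc.directions, spec)
    coeffs = sh_core.fit_sh(adc.D, B, penalty, spec)
    return scaling.apply(_power_fraction_index(coeffs))


def compute_amura_flat(
    signal: np.ndarray,
    s0: np.ndarray,
    directions: np.ndarray,
    shell_b: float,
    e1: np.ndarray,
    cfg: QSpaceConfig = QSpaceConfig(),
    spec: SHBasisSpec = SHBasisSpec(),
    penalty: PenaltySpec = PenaltySpec(),
    scaling: AnisotropyScalingSpec = AnisotropyScalingSpec(),
) -> dict[str, np.ndarray]:
    """All seven metrics on flattened voxels; single basis build, shared fits.

    Returns a dict keyed RTOP/RTPP/RTAP/APA/DiA/qMSD/U12 plus "_qc" with the
    ADC clip count and invalid-voxel count.
    """
    adc = adc_from_signal_flat(signal, s0, directions, shell_b)
    B = sh_core.eval_basis(adc.directions, spec)
    tau4pi = 4.0 * np.pi * cfg.tau

    coeff_D = sh_core.fit_sh(adc.D, B, penalty, spec)
    coeff_Dm1 = sh_core.fit_sh(adc.D**-1.0, B, penalty, spec)
    coeff_Dm32 = sh_core.fit_sh(adc.D**-1.5, B, penalty, spec)
    coeff_Dm52 = sh_core.fit_sh(adc.D**-2.5, B, penalty, spec)
    coeff_Dm74 = sh_core.fit_sh(adc.D**-1.75, B, penalty, spec)

    B_e1 = sh_core.eval_basis(np.atleast_2d(e1), spec)
    d_axial = np.clip(np.einsum("vc,vc->v", coeff_D.c, B_e1), adc.clip_window[0], None)
    w = _legendre_at_zero(spec)
    eq_mean = np.clip(np.einsum("vc,c,vc->v", coeff_Dm1.c, w, B_e1),
                      1.0 / adc.clip_window[1], None)

    def moment_const(p: float) -> float:
        return 2.0 * np.pi * gamma_fn(p) * (4.0 * np.pi**2 * cfg.tau) ** (-p)

    s0_safe = np.where(np.asarray(s0, dtype=float) > 0, s0, 1.0)
    E = np.asarray(signal, dtype=float) / np.asarray(s0_safe)[:, None]
    coeff_E = sh_core.fit_sh(E, B, penalty, spec)

    out = {
        "RTOP": tau4pi**-1.5 * sh_core.spherical_mean(coeff_Dm32),
        "RTPP": (tau4pi * d_axial) ** -0.5,
        "RTAP": eq_mean / tau4pi,
        "qMSD": moment_const(2.5) * sh_core.spherical_mean(coeff_Dm52),
        "U12": moment_const(1.75) * sh_core.spherical_mean(coeff_Dm74),
        "APA": scaling.apply(_power_fraction_index(coeff_E)),
        "DiA": scaling.apply(_power_fraction_index(coeff_D)),
    }
    for k in out:
        out[k] = np.where(adc.valid, out[k], np.nan)
    out["_qc"] = {
        "adc_clipped_samples": adc.n_clipped,
        "invalid_voxels": int(np.count_nonzero(~adc.valid)),
    }
    return out
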