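"""Diffusion-tensor estimation (OLS on log-signal) and the classical scalars.

The tensor D is fitted per voxel from log(S/S0) = -b g' D g by ordinary least
squares over the six unique tensor elements, mirroring the standard dtifit
behavior.  Scalars: FA, MD, AD = λ1, RD = (λ2+λ3)/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_gradients import DWIVolume, GradientScheme

__all__ = ["TensorField", "DTIScalars", "fit_tensor", "tensor_scalars", "fit_tensor_flat"]

#: Eigenvalue floor, mm²/s — keeps downstream negative-power transforms finite.
EIGENVALUE_FLOOR = 1e-7

#: S is clipped to [RELATIVE_SIGNAL_FLOOR*S0, S0] before the log.
RELATIVE_SIGNAL_FLOOR = 1e-6


@dataclass
class TensorField:
    """Per-voxel diffusion tensors with sorted eigensystem.

    ``tensors`` holds the six unique elements (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz)
    in mm²/s; ``evals`` are sorted descending; ``e1`` is the principal unit
    eigenvector.  ``valid`` flags voxels with usable baseline signal.
    """

    tensors: np.ndarray
    evals: np.ndarray
    e1: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.ones(self.evals.shape[:-1], dtype=bool)


@dataclass
class DTIScalars:
    """FA (dimensionless), MD/AD/RD (mm²/s) per voxel; NaN where invalid."""

    FA: np.ndarray
    MD: np.ndarray
    AD: np.ndarray
    RD: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {"FA": self.FA, "MD": self.MD, "AD": self.AD, "RD": self.RD}


def _design_matrix(scheme: GradientScheme) -> np.ndarray:
    """Rows -b*(gx², gy², gz², 2gxgy, 2gxgz, 2gygz) for the DWI volumes."""
    g = scheme.dwi_directions
    b = scheme.bvals[scheme.dwi_indices]
    return -b[:, None] * np.column_stack(
        [g[:, 0] ** 2, g[:, 1] ** 2, g[:, 2] ** 2,
         2 * g[:, 0] * g[:, 1], 2 * g[:, 0] * g[:, 2], 2 * g[:, 1] * g[:, 2]]
    )


def fit_tensor_flat(signal: np.ndarray, s0: np.ndarray, scheme: GradientScheme) -> TensorField:
    """Tensor fit on flattened voxels.

    Parameters
    ----------
    signal : (n_vox, n_dwi) DWI signal at the nonzero-b volumes.
    s0 : (n_vox,) baseline signal.
    scheme : acquisition scheme (provides directions and b-values).
    """
    if scheme.n_directions < 6:
        raise ValueError("tensor fit needs at least 6 distinct gradient directions")
    s0 = np.asarray(s0, dtype=float)
    valid = s0 > 0
    s0_safe = np.where(valid, s0, 1.0)
    sig = np.clip(signal, RELATIVE_SIGNAL_FLOOR * s0_safe[:, None], s0_safe[:, None])
    y = np.log(sig / s0_safe[:, None])
    X = _design_matrix(scheme)
    coef, *_ = np.linalg.lstsq(X, y.T, rcond=None)
    coef = coef.T  # (n_vox, 6)

    n = coef.shape[0]
    T = np.empty((n, 3, 3))
    T[:, 0, 0] = coef[:, 0]
    T[:, 1, 1] = coef[:, 1]
    T[:, 2, 2] = coef[:, 2]
    T[:, 0, 1] = T[:, 1, 0] = coef[:, 3]
    T[:, 0, 2] = T[:, 2, 0] = coef[:, 4]
    T[:, 1, 2] = T[:, 2, 1] = coef[:, 5]

    w, v = np.linalg.eigh(T)  # ascending
    evals = np.maximum(w[:, ::-1], EIGENVALUE_FLOOR)
    e1 = v[:, :, ::-1][:, :, 0]
    return TensorField(tensors=coef, evals=evals, e1=e1, valid=valid)


def fit_tensor(dwi: DWIVolume) -> TensorField:
    """Fit the diffusion tensor in every masked voxel of a 4D dataset.

    Voxels outside the mask (or with non-positive S0) are flagged invalid;
    their scalars come out as NaN from :func:`tensor_scalars`.
    """
    mask = dwi.mask
    flat_sig = dwi.data[mask][:, dwi.scheme.dwi_indices]
    flat_s0 = dwi.s0[mask]
    tf_flat = fit_tensor_flat(flat_sig, flat_s0, dwi.scheme)

    shape = dwi.data.shape[:3]
    tensors = np.zeros(shape + (6,))
    evals = np.full(shape + (3,), np.nan)
    e1 = np.zeros(shape + (3,))
    valid = np.zeros(shape, dtype=bool)
    tensors[mask] = tf_flat.tensors
    evals[mask] = tf_flat.evals
    e1[mask] = tf_flat.e1
    valid[mask] = tf_flat.valid
    return TensorField(tensors=tensors, evals=evals, e1=e1, valid=valid)


def tensor_scalars(tf: TensorField) -> DTIScalars:
    """FA/MD/AD/RD from the eigenvalues; FA of an all-zero tensor is 0."""
    lam = tf.evals
    md = lam.mean(axis=-1)
    norm_sq = np.sum(lam**2, axis=-1)
    dev_sq = np.sum((lam - md[..., None]) ** 2, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * dev_sq / np.where(norm_sq > 0, norm_sq, 1.0))
    fa = np.where(norm_sq > 0, fa, 0.0)
    fa = np.clip(fa, 0.0, 1.0)
    bad = ~tf.valid
    out = DTIScalars(
        FA=np.where(bad, np.nan, fa),
        MD=np.where(bad, np.nan, md),
        AD=np.where(bad, np.nan, lam[..., 0]),
        RD=np.where(bad, np.nan, 0.5 * (lam[..., 1] + lam[..., 2])),
    )
    return out
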