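"""Volume, gradient-table and mask I/O; single-shell acquisition contract.

Gradient tables follow the FSL dialect: the bval file is one whitespace
separated row of b-values (s/mm²), the bvec file three rows holding the x, y
and z components of the gradient directions in the image frame.  Volumes are
NIfTI-1, read and written with nibabel.  Directions are kept in the image
frame; no world-frame reorientation is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "GradientScheme",
    "VolumeGrid",
    "DWIVolume",
    "GradientTableError",
    "MultiShellError",
    "GridMismatchError",
    "read_gradient_table",
    "write_gradient_table",
    "validate_single_shell",
    "read_volume",
    "read_dwi",
    "write_scalar_map",
    "write_volume",
    "read_labels",
    "B0_THRESHOLD",
]

#: b-values below this (s/mm²) are classified as b=0; robust to vendor jitter.
B0_THRESHOLD = 50.0


class GradientTableError(ValueError):
    """Malformed or inconsistent bval/bvec pair."""


class MultiShellError(ValueError):
    """Nonzero b-values are not consistent with a single shell."""


class GridMismatchError(ValueError):
    """Two volumes expected on the same grid do not match."""


@dataclass(frozen=True)
class GradientScheme:
    """Per-volume b-values and unit directions of a single-shell acquisition.

    Attributes
    ----------
    bvals : array (n_volumes,)
        b-value per volume, s/mm².
    bvecs : array (n_volumes, 3)
        Unit direction per volume in the image frame; zero vector at b=0.
    shell_b : float
        Nominal nonzero b-value (median of the nonzero bvals), s/mm².
    """

    bvals: np.ndarray
    bvecs: np.ndarray
    b0_threshold: float = B0_THRESHOLD

    def __post_init__(self) -> None:
        object.__setattr__(self, "bvals", np.asarray(self.bvals, dtype=float).ravel())
        object.__setattr__(self, "bvecs", np.asarray(self.bvecs, dtype=float).reshape(-1, 3))
        if len(self.bvals) != len(self.bvecs):
            raise GradientTableError(
                f"bvals ({len(self.bvals)}) and bvecs ({len(self.bvecs)}) count mismatch"
            )
        if not np.any(self.bvals < self.b0_threshold):
            raise GradientTableError("scheme has no b=0 (baseline) volume")

    @property
    def b0_indices(self) -> np.ndarray:
        return np.flatnonzero(self.bvals < self.b0_threshold)

    @property
    def dwi_indices(self) -> np.ndarray:
        return np.flatnonzero(self.bvals >= self.b0_threshold)

    @property
    def shell_b(self) -> float:
        return float(np.median(self.bvals[self.dwi_indices]))

    @property
    def dwi_directions(self) -> np.ndarray:
        return self.bvecs[self.dwi_indices]

    @property
    def n_directions(self) -> int:
        return len(self.dwi_indices)


@dataclass(frozen=True)
class VolumeGrid:
    """3D sampling grid: dimensions, voxel size (mm) and voxel-to-world affine."""

    dims: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    affine: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "affine", np.asarray(self.affine, dtype=float))
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")
        if any(v <= 0 for v in self.voxel_size) or any(d <= 0 for d in self.dims):
            raise ValueError("dims and voxel_size must be positive")

    @classmethod
    def from_img(cls, img: nib.Nifti1Image) -> "VolumeGrid":
        zooms = img.header.get_zooms()[:3]
        return cls(dims=tuple(img.shape[:3]), voxel_size=tuple(float(z) for z in zooms),
                   affine=np.asarray(img.affine))


@dataclass
class DWIVolume:
    """4D diffusion-weighted dataset: grid + signal + scheme + brain mask."""

    grid: VolumeGrid
    data: np.ndarray
    scheme: GradientScheme
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 4:
            raise ValueError("DWI data must be 4D")
        if self.data.shape[-1] != len(self.scheme.bvals):
            raise GridMismatchError(
                f"data has {self.data.shape[-1]} volumes but the gradient table "
                f"has {len(self.scheme.bvals)} entries"
            )
        if self.mask.shape != self.data.shape[:3]:
            raise GridMismatchError(
                f"mask dims {self.mask.shape} do not match data dims {self.data.shape[:3]}"
            )

    @property
    def s0(self) -> np.ndarray:
        """Mean baseline (b=0) signal per voxel."""
        return self.data[..., self.scheme.b0_indices].mean(axis=-1)


def read_gradient_table(
    bval_path: str | Path, bvec_path: str | Path, b0_threshold: float = B0_THRESHOLD
) -> GradientScheme:
    """Read an FSL-dialect bval/bvec pair and normalize the nonzero directions.

    b-values below ``b0_threshold`` are classified as b=0 and their direction is
    stored as the zero vector.  A zero direction paired with a nonzero b-value
    is a format error.
    """
    try:
        bvals = np.loadtxt(bval_path, dtype=float).ravel()
        bvecs = np.loadtxt(bvec_path, dtype=float)
    except ValueError as exc:
        raise GradientTableError(f"could not parse gradient table: {exc}") from exc
    if bvecs.ndim != 2 or bvecs.shape[0] != 3:
        raise GradientTableError(f"bvec file must have three rows, found shape {bvecs.shape}")
    bvecs = bvecs.T
    if len(bvals) != len(bvecs):
        raise GradientTableError(
            f"bval file has {len(bvals)} entries, bvec file {len(bvecs)} columns"
        )
    norms = np.linalg.norm(bvecs, axis=1)
    nz = bvals >= b0_threshold
    if np.any(norms[nz] < 1e-8):
        bad = np.flatnonzero(nz & (norms < 1e-8))
        raise GradientTableError(f"zero direction at nonzero b for volume(s) {bad.tolist()}")
    out = np.zeros_like(bvecs)
    out[nz] = bvecs[nz] / norms[nz][:, None]
    return GradientScheme(bvals=bvals, bvecs=out, b0_threshold=b0_threshold)


def write_gradient_table(scheme: GradientScheme, bval_path: str | Path, bvec_path: str | Path) -> None:
    np.savetxt(bval_path, scheme.bvals[None, :], fmt="%.6g")
    np.savetxt(bvec_path, scheme.bvecs.T, fmt="%.8f")


def validate_single_shell(scheme: GradientScheme, rel_tol: float = 0.05) -> dict:
    """Check all nonzero b-values sit on one shell; return its summary.

    Passes iff every nonzero b is within ``rel_tol`` (relative) of the median
    nonzero b.  Returns ``{"shell_b", "n_directions", "n_b0"}``.

    Raises
    ------
    MultiShellError
        If any nonzero b-value deviates from the median by more than rel_tol,
        naming the offending values.
    """
    b = scheme.bvals[scheme.dwi_indices]
    med = float(np.median(b))
    off = np.abs(b - med) > rel_tol * med
    if np.any(off):
        raise MultiShellError(
            f"not a single shell: median b = {med:g} but found b-values "
            f"{sorted(set(np.round(b[off], 3).tolist()))}"
        )
    return {"shell_b": med, "n_directions": int(len(b)), "n_b0": int(len(scheme.b0_indices))}


def read_volume(path: str | Path) -> tuple[np.ndarray, VolumeGrid]:
    """Read a 3D or 4D NIfTI volume; returns (data, grid)."""
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=float), VolumeGrid.from_img(img)


def read_dwi(
    dwi_path: str | Path,
    bval_path: str | Path,
    bvec_path: str | Path,
    mask_path: str | Path | None = None,
) -> DWIVolume:
    data, grid = read_volume(dwi_path)
    scheme = read_gradient_table(bval_path, bvec_path)
    if mask_path is None:
        mask = np.ones(data.shape[:3], dtype=bool)
    else:
        mdat, mgrid = read_volume(mask_path)
        if mgrid.dims != grid.dims:
            raise GridMismatchError(f"mask dims {mgrid.dims} != DWI dims {grid.dims}")
        mask = mdat > 0.5
    return DWIVolume(grid=grid, data=data, scheme=scheme, mask=mask)


def write_volume(data: np.ndarray, grid: VolumeGrid, path: str | Path) -> None:
    img = nib.Nifti1Image(np.asarray(data), grid.affine)
    img.header.set_zooms(tuple(grid.voxel_size) + ((1.0,) if np.asarray(data).ndim == 4 else ()))
    nib.save(img, str(path))


# scalar maps are plain 3D volumes; keep the spec-facing alias
write_scalar_map = write_volume


def read_labels(path: str | Path) -> tuple[np.ndarray, VolumeGrid]:
    """Read an integer ROI label volume (0 = background)."""
    data, grid = read_volume(path)
    rounded = np.round(data)
    if not np.allclose(data, rounded, atol=1e-6):
        raise ValueError(f"label volume {path} is not integer-valued")
    return rounded.astype(np.int32), grid
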