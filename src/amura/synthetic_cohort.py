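"""Synthetic single-shell diffusion data: voxel signal model and cohorts.

Two layers:

1. A two-compartment voxel model — an axially symmetric "zeppelin" tensor
   compartment (volume fraction f) plus isotropic free water (fraction 1-f):

       S(b, u) = f · exp(-b (d⊥ + (d∥-d⊥)(u·μ)²)) + (1-f) · exp(-b D0)

   with the constant-FA / constant-MD parameter families in which d⊥ is
   solved per f so that the tensor fitted from S keeps FA (or MD) constant.

2. A cohort generator: three groups (healthy controls HC, episodic migraine
   EM, chronic migraine CM by default) of subjects over a toy block atlas of
   labeled white-matter regions, with per-group per-region parameter offsets
   (the injected effect), subject-level jitter, and Rician magnitude noise at
   a stated b=0 SNR.  This stands in for a clinical dataset: it produces the
   same objects (4D DWI + gradient table + atlas + skeleton + design table)
   the group-statistics pipeline consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .dti_fit import fit_tensor_flat, tensor_scalars, TensorField
from .io_gradients import DWIVolume, GradientScheme, VolumeGrid, write_gradient_table, write_volume

__all__ = [
    "VoxelModelParams",
    "CohortSpec",
    "CohortData",
    "zeppelin_signal",
    "two_compartment_signal",
    "make_directions",
    "make_scheme",
    "constant_fa_family",
    "constant_md_family",
    "generate_cohort",
    "write_cohort",
    "DEFAULT_D_PAR",
    "DEFAULT_D_PERP",
    "DEFAULT_D0",
]

DEFAULT_D_PAR = 1.7e-3   # mm²/s, healthy white matter parallel diffusivity
DEFAULT_D_PERP = 0.3e-3  # mm²/s, perpendicular
DEFAULT_D0 = 3.0e-3      # mm²/s, free water at body temperature


@dataclass(frozen=True)
class VoxelModelParams:
    """Zeppelin + free-water voxel: fraction f, diffusivities, zeppelin axis μ."""

    f: float = 0.8
    d_par: float = DEFAULT_D_PAR
    d_perp: float = DEFAULT_D_PERP
    mu: tuple[float, float, float] = (0.0, 0.0, 1.0)
    D0: float = DEFAULT_D0

    def __post_init__(self) -> None:
        if not (0.0 <= self.f <= 1.0):
            raise ValueError(f"volume fraction f must be in [0,1], got {self.f}")
        if not (0.0 < self.d_perp <= self.d_par):
            raise ValueError("need 0 < d_perp <= d_par")
        object.__setattr__(self, "mu", tuple(np.asarray(self.mu, float) / np.linalg.norm(self.mu)))


def zeppelin_signal(b: float, u: np.ndarray, params: VoxelModelParams) -> np.ndarray:
    """Attenuation of the zeppelin compartment, exp(-b D_zep(u)) ∈ (0, 1]."""
    u = np.asarray(u, dtype=float)
    mu = np.asarray(params.mu)
    proj2 = (u @ mu) ** 2
    return np.exp(-b * (params.d_perp + (params.d_par - params.d_perp) * proj2))


def two_compartment_signal(b: float, directions: np.ndarray, params: VoxelModelParams) -> np.ndarray:
    """S(b, u) per direction; S(0, ·) = 1 by construction."""
    zp = zeppelin_signal(b, directions, params)
    return params.f * zp + (1.0 - params.f) * np.exp(-b * params.D0)


@lru_cache(maxsize=8)
def _make_directions_cached(n: int, seed: int, n_iter: int) -> np.ndarray:
    """Well-spread unit direction set by electrostatic repulsion of antipodal pairs.

    Deterministic for a fixed (n, seed): starts from a seeded random hemisphere
    sample and runs a fixed number of projected-gradient Coulomb-energy steps on
    the 2n charges {±x_i}.
    """
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, 3))
    x /= np.linalg.norm(x, axis=1, keepdims=True)
    step = 0.05
    for _ in range(n_iter):
        pts = np.concatenate([x, -x])        # antipodal charges
        diff = x[:, None, :] - pts[None, :, :]
        d2 = np.sum(diff**2, axis=-1)
        np.fill_diagonal(d2[:, :n], np.inf)  # self terms
        force = np.sum(diff / (d2[..., None] ** 1.5 + 1e-12), axis=1)
        force -= np.sum(force * x, axis=1, keepdims=True) * x  # tangential
        x = x + step * force / n
        x /= np.linalg.norm(x, axis=1, keepdims=True)
    x.setflags(write=False)
    return x


def make_directions(n: int = 61, seed: int = 20230510, n_iter: int = 300) -> np.ndarray:
    return _make_directions_cached(n, seed, n_iter)


def make_scheme(shell_b: float = 1000.0, n_directions: int = 61, n_b0: int = 1,
                seed: int = 20230510) -> GradientScheme:
    """Acquisition scheme: n_b0 baselines followed by the shell directions."""
    dirs = make_directions(n_directions, seed=seed)
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_directions, shell_b)])
    bvecs = np.concatenate([np.zeros((n_b0, 3)), dirs])
    return GradientScheme(bvals=bvals, bvecs=bvecs)


# ---------------------------------------------------------------------------
# constant-FA / constant-MD parameter families


def _fit_scalars_noiseless(params: VoxelModelParams, scheme: GradientScheme):
    sig = two_compartment_signal(scheme.shell_b, scheme.dwi_directions, params)
    full = np.ones(len(scheme.bvals))
    full[scheme.dwi_indices] = sig
    tf = fit_tensor_flat(sig[None, :], np.ones(1), scheme)
    return tensor_scalars(tf)


def _solve_family(f_grid, d_par, D0, mu, scheme, target_fn, target, tol=1e-6):
    params_out, infeasible = [], []
    for f in np.asarray(f_grid, dtype=float):
        def objective(d_perp: float) -> float:
            p = VoxelModelParams(f=f, d_par=d_par, d_perp=d_perp, mu=mu, D0=D0)
            return target_fn(_fit_scalars_noiseless(p, scheme)) - target
        lo, hi = 1.01e-5, d_par * (1 - 1e-9)
        try:
            if objective(lo) * objective(hi) > 0:
                raise ValueError("no sign change")
            d_perp = brentq(objective, lo, hi, xtol=tol * 1e-3, rtol=1e-12)
        except ValueError:
            infeasible.append(float(f))
            continue
        params_out.append(VoxelModelParams(f=f, d_par=d_par, d_perp=d_perp, mu=mu, D0=D0))
    if infeasible:
        raise ValueError(f"no feasible d_perp for f values {infeasible}")
    return params_out


def constant_fa_family(
    f_grid: np.ndarray,
    d_par: float = DEFAULT_D_PAR,
    d_perp_ref: float = DEFAULT_D_PERP,
    D0: float = DEFAULT_D0,
    mu=(0.0, 0.0, 1.0),
    scheme: GradientScheme | None = None,
    target: float | None = None,
) -> list[VoxelModelParams]:
    """Per-f zeppelin parameters keeping the *fitted* FA constant.

    For each f, d⊥ is root-found so that the tensor fitted from the noiseless
    two-compartment signal has the FA of the f=1 reference zeppelin
    (d∥, d⊥_ref) unless an explicit ``target`` is given.
    """
    if scheme is None:
        scheme = make_scheme()
    if target is None:
        ref = VoxelModelParams(f=1.0, d_par=d_par, d_perp=d_perp_ref, mu=mu, D0=D0)
        target = float(_fit_scalars_noiseless(ref, scheme).FA[0])
    return _solve_family(f_grid, d_par, D0, mu, scheme, lambda s: float(s.FA[0]), target)


def constant_md_family(
    f_grid: np.ndarray,
    d_par: float = DEFAULT_D_PAR,
    d_perp_ref: float = DEFAULT_D_PERP,
    D0: float = DEFAULT_D0,
    mu=(0.0, 0.0, 1.0),
    scheme: GradientScheme | None = None,
    target: float | None = None,
) -> list[VoxelModelParams]:
    """Per-f zeppelin parameters keeping the fitted MD constant (mm²/s)."""
    if scheme is None:
        scheme = make_scheme()
    if target is None:
        ref = VoxelModelParams(f=1.0, d_par=d_par, d_perp=d_perp_ref, mu=mu, D0=D0)
        target = float(_fit_scalars_noiseless(ref, scheme).MD[0])
    return _solve_family(f_grid, d_par, D0, mu, scheme, lambda s: float(s.MD[0]), target)


# ---------------------------------------------------------------------------
# cohort generation


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic three-group study.

    ``group_sizes`` maps group name to subject count.  The atlas is a block
    grid of ``n_regions`` cuboid regions tiled over ``grid_dims``; each region
    gets a baseline :class:`VoxelModelParams` (axis drawn per region from the
    seed) and each group an optional per-region offset dict, e.g.
    ``{"EM": {3: {"f": -0.05}}}`` lowers f by 0.05 in region 3 for group EM.

    Between-subject variability has two sources: ``f_sigma``, the SD of a
    per-subject, per-region Gaussian perturbation of the zeppelin fraction f
    (biological variability — hydration, partial-volume and fiber-density
    differences make the effective intra-axonal fraction vary across healthy
    subjects on this order), and ``jitter_frac``, the relative SD of the
    subject-level jitter applied to each injected group offset.  Rician noise
    at ``snr`` (defined on the b=0 signal) is added on top.
    """

    group_sizes: dict[str, int] = field(default_factory=lambda: {"HC": 50, "EM": 51, "CM": 56})
    n_regions: int = 12
    grid_dims: tuple[int, int, int] = (24, 24, 12)
    baseline: VoxelModelParams = VoxelModelParams()
    offsets: dict[str, dict[int, dict[str, float]]] = field(default_factory=dict)
    snr: float = 30.0
    shell_b: float = 1000.0
    n_directions: int = 61
    jitter_frac: float = 0.1
    f_sigma: float = 0.07
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 1 or self.n_regions > 48:
            raise ValueError("n_regions must be in [1, 48]")
        if any(s < 1 for s in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 1")
        for g, regions in self.offsets.items():
            if g not in self.group_sizes:
                raise ValueError(f"offset group {g!r} not in group_sizes")
            for r, delta in regions.items():
                if not (1 <= r <= self.n_regions):
                    raise ValueError(f"offset region {r} outside 1..{self.n_regions}")
                self._apply_offset(self.baseline, delta)  # validates ranges

    @staticmethod
    def _apply_offset(base: VoxelModelParams, delta: dict[str, float]) -> VoxelModelParams:
        kw = {k: getattr(base, k) + v for k, v in delta.items()}
        return replace(base, **kw)


@dataclass
class CohortData:
    """In-memory cohort: per-subject masked signals plus shared geometry.

    ``signals`` has shape (n_subjects, n_vox, n_volumes) over the masked
    (atlas > 0) voxels in flattened order; ``labels_flat`` / ``skeleton_flat``
    give each voxel's region id and skeleton membership.
    """

    spec: CohortSpec
    scheme: GradientScheme
    grid: VolumeGrid
    labels: np.ndarray
    skeleton: np.ndarray
    signals: np.ndarray
    design: pd.DataFrame

    @property
    def labels_flat(self) -> np.ndarray:
        return self.labels[self.labels > 0]

    @property
    def skeleton_flat(self) -> np.ndarray:
        return self.skeleton[self.labels > 0]

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0


def _block_atlas(dims: tuple[int, int, int], n_regions: int) -> tuple[np.ndarray, np.ndarray]:
    """Cuboid-region label volume and its one-voxel-thick core-plane skeleton."""
    nx = int(np.ceil(np.sqrt(n_regions)))
    ny = int(np.ceil(n_regions / nx))
    labels = np.zeros(dims, dtype=np.int32)
    skeleton = np.zeros(dims, dtype=bool)
    bx = np.array_split(np.arange(dims[0]), nx)
    by = np.array_split(np.arange(dims[1]), ny)
    r = 0
    for ix in range(nx):
        for iy in range(ny):
            if r >= n_regions:
                break
            xs, ys = bx[ix], by[iy]
            labels[np.ix_(xs, ys, np.arange(dims[2]))] = r + 1
            # core plane: central x-slice of the block, one voxel thick
            skeleton[xs[len(xs) // 2], ys[0]:ys[-1] + 1, :] = True
            r += 1
    return labels, skeleton


def generate_cohort(spec: CohortSpec) -> CohortData:
    """Deterministically simulate a full cohort from the spec seed.

    Per subject, each voxel's parameters are the region baseline plus the
    group's region offset plus Gaussian subject jitter (SD = jitter_frac ×
    |offset|, shared across the subject's voxels of that region); the signal
    follows the two-compartment model and magnitude Rician noise is added at
    the stated b=0 SNR.
    """
    root = np.random.SeedSequence(spec.seed)
    ss_atlas, ss_params, ss_noise = root.spawn(3)
    rng_atlas = np.random.default_rng(ss_atlas)
    rng_params = np.random.default_rng(ss_params)
    rng_noise = np.random.default_rng(ss_noise)

    labels, skeleton = _block_atlas(spec.grid_dims, spec.n_regions)
    mask = labels > 0
    lab_flat = labels[mask]
    n_vox = lab_flat.size

    # per-region baseline axis: random unit vector, fixed across the cohort
    axes = rng_atlas.standard_normal((spec.n_regions, 3))
    axes /= np.linalg.norm(axes, axis=1, keepdims=True)

    # the direction table plays the role of the scanner's fixed vendor set:
    # identical across subjects and cohorts (and cached), like a real protocol
    scheme = make_scheme(spec.shell_b, spec.n_directions)
    n_volumes = len(scheme.bvals)
    dirs = scheme.dwi_directions
    b = scheme.shell_b

    subjects, groups = [], []
    for g, size in spec.group_sizes.items():
        for i in range(size):
            subjects.append(f"{g}{i+1:03d}")
            groups.append(g)
    design = pd.DataFrame({"subject_id": subjects, "group": groups})
    n_subj = len(subjects)
    group_arr = np.array(groups)

    # per-(subject, region) parameter tables, drawn in a fixed order
    param_names = ("f", "d_par", "d_perp", "D0")
    table = {k: np.full((n_subj, spec.n_regions), getattr(spec.baseline, k))
             for k in param_names}
    for g in spec.group_sizes:
        g_rows = np.flatnonzero(group_arr == g)
        for r in range(1, spec.n_regions + 1):
            for k, v in spec.offsets.get(g, {}).get(r, {}).items():
                jitter = rng_params.normal(0.0, spec.jitter_frac * abs(v), size=len(g_rows))
                table[k][g_rows, r - 1] += v + jitter
    if spec.f_sigma > 0:
        table["f"] = table["f"] + rng_params.normal(0.0, spec.f_sigma,
                                                    size=(n_subj, spec.n_regions))
    table["f"] = np.clip(table["f"], 0.01, 1.0)
    table["d_perp"] = np.clip(table["d_perp"], 1e-5, table["d_par"] - 1e-9)

    clean = np.empty((n_subj, n_vox, n_volumes))
    clean[:, :, scheme.b0_indices] = 1.0
    dwi_block = np.empty((n_subj, n_vox, len(scheme.dwi_indices)))
    for r in range(1, spec.n_regions + 1):
        sel = np.flatnonzero(lab_flat == r)
        proj2 = (dirs @ axes[r - 1]) ** 2
        f = table["f"][:, r - 1][:, None]
        d_par = table["d_par"][:, r - 1][:, None]
        d_perp = table["d_perp"][:, r - 1][:, None]
        D0 = table["D0"][:, r - 1][:, None]
        zp = np.exp(-b * (d_perp + (d_par - d_perp) * proj2[None, :]))
        att = f * zp + (1.0 - f) * np.exp(-b * D0)     # (n_subj, n_dirs)
        dwi_block[:, sel, :] = att[:, None, :]
    clean[:, :, scheme.dwi_indices] = dwi_block

    if spec.snr == np.inf or spec.snr <= 0:
        signals = clean
    else:
        sigma = 1.0 / spec.snr  # S0 = 1 by construction
        n1 = rng_noise.standard_normal(clean.shape)
        n2 = rng_noise.standard_normal(clean.shape)
        signals = np.sqrt((clean + sigma * n1) ** 2 + (sigma * n2) ** 2)

    grid = VolumeGrid(dims=spec.grid_dims, voxel_size=(2.0, 2.0, 2.0), affine=np.eye(4))
    return CohortData(spec=spec, scheme=scheme, grid=grid, labels=labels,
                      skeleton=skeleton, signals=signals, design=design)


def write_cohort(cohort: CohortData, out_dir: str | Path) -> None:
    """Persist a cohort: per-subject NIfTI + bval/bvec, atlas, skeleton, design TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = cohort.grid
    write_volume(cohort.labels.astype(np.int16), grid, out / "atlas_labels.nii.gz")
    write_volume(cohort.skeleton.astype(np.uint8), grid, out / "skeleton_mask.nii.gz")
    cohort.design.to_csv(out / "design.tsv", sep="\t", index=False)
    mask = cohort.mask
    for i, sid in enumerate(cohort.design["subject_id"]):
        vol = np.zeros(grid.dims + (cohort.signals.shape[-1],))
        vol[mask] = cohort.signals[i]
        write_volume(vol, grid, out / f"{sid}_dwi.nii.gz")
        write_gradient_table(cohort.scheme, out / f"{sid}.bval", out / f"{sid}.bvec")


def cohort_subject_dwi(cohort: CohortData, index: int) -> DWIVolume:
    """Materialize one subject as a DWIVolume (mask = atlas > 0)."""
    mask = cohort.mask
    vol = np.zeros(cohort.grid.dims + (cohort.signals.shape[-1],))
    vol[mask] = cohort.signals[index]
    return DWIVolume(grid=cohort.grid, data=vol, scheme=cohort.scheme, mask=mask)
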