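"""Study orchestration: simulate → fit → ROI stats → resampling → report.

The in-memory entry points here are what the CLI wraps; they are equally
usable from a script or notebook.  All stages are deterministic given the
study config and base seed, and every on-disk stage output carries a manifest
(config hash, seed, package versions).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .amura_metrics import (AMURA_METRIC_NAMES, AnisotropyScalingSpec, QSpaceConfig,
                            compute_amura_flat)
from .dti_fit import fit_tensor_flat, tensor_scalars
from .io_gradients import write_volume
from .resampling_stability import (ResamplingPlan, ResamplingResult,
                                   significance_vs_size_curve, subsample_experiment)
from .roi_stats import ROIExtractionSpec, extract_roi_table, roi_comparison_table
from .sh_core import PenaltySpec, SHBasisSpec
from .synthetic_cohort import CohortData, CohortSpec, generate_cohort, write_cohort

__all__ = [
    "StudyConfig",
    "METRIC_ORDER",
    "compute_subject_metrics_flat",
    "compute_cohort_metrics",
    "run_roi_stats",
    "run_resampling",
    "run_signal_experiment",
    "run_study",
]

#: fixed presentation order for all report tables
METRIC_ORDER = ("FA", "MD", "AD", "RD") + AMURA_METRIC_NAMES


@dataclass
class StudyConfig:
    """Single config for a full synthetic study."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    tau: float = 0.070
    sh_order: int = 6
    lambda_lb: float = 0.006
    anisotropy_scaling: bool = True
    trim_low: float = 2.0
    trim_high: float = 98.0
    resample_B: int = 5001
    alpha: float = 0.05
    base_seed: int = 0
    out_dir: str = "study_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort_raw = raw.pop("cohort", {})
        offsets = {g: {int(r): dict(d) for r, d in regs.items()}
                   for g, regs in cohort_raw.pop("offsets", {}).items()}
        bad = set(raw) - {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        if bad:
            raise ValueError(f"unknown config fields: {sorted(bad)}")
        from .synthetic_cohort import VoxelModelParams
        baseline_raw = cohort_raw.pop("baseline", None)
        if baseline_raw is not None:
            baseline_raw["mu"] = tuple(baseline_raw.get("mu", (0.0, 0.0, 1.0)))
            cohort_raw["baseline"] = VoxelModelParams(**baseline_raw)
        if "grid_dims" in cohort_raw:
            cohort_raw["grid_dims"] = tuple(cohort_raw["grid_dims"])
        cohort = CohortSpec(offsets=offsets, **cohort_raw)
        return cls(cohort=cohort, **raw)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["cohort"]["baseline"] = asdict(self.cohort.baseline)
        d = json.loads(json.dumps(d, default=float))  # drop numpy scalar types
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True, default=str)
                              .encode()).hexdigest()[:16]


def compute_subject_metrics_flat(signal_volumes: np.ndarray, scheme, tau: float = 0.070,
                                 sh_order: int = 6, lambda_lb: float = 0.006,
                                 scaling_enabled: bool = True) -> dict[str, np.ndarray]:
    """All 11 scalar metrics for one batch of voxels, shape (n_vox, n_volumes).

    Returns {metric: (n_vox,)} for FA/MD/AD/RD + the seven apparent q-space
    metrics, in a single pass (one tensor fit, shared SH design matrix).
    """
    s0 = signal_volumes[:, scheme.b0_indices].mean(axis=1)
    dwi = signal_volumes[:, scheme.dwi_indices]
    tf = fit_tensor_flat(dwi, s0, scheme)
    scalars = tensor_scalars(tf)
    out = dict(scalars.as_dict())
    amura = compute_amura_flat(
        dwi, s0, scheme.dwi_directions, scheme.shell_b, tf.e1,
        cfg=QSpaceConfig(tau=tau), spec=SHBasisSpec(order=sh_order),
        penalty=PenaltySpec(lambda_lb=lambda_lb),
        scaling=AnisotropyScalingSpec(enabled=scaling_enabled))
    qc = amura.pop("_qc")
    out.update(amura)
    out["_qc"] = qc
    return out


def compute_cohort_metrics(cohort: CohortData, tau: float = 0.070, sh_order: int = 6,
                           lambda_lb: float = 0.006, scaling_enabled: bool = True,
                           max_chunk_rows: int = 200_000) -> dict[str, np.ndarray]:
    """Metric maps for every subject: {metric: (n_subjects, n_vox)}.

    Subjects are processed in chunks so that the flattened voxel batch stays
    below ``max_chunk_rows`` rows.
    """
    n_subj, n_vox, n_volumes = cohort.signals.shape
    per_chunk = max(1, max_chunk_rows // n_vox)
    out = {m: np.empty((n_subj, n_vox)) for m in METRIC_ORDER}
    qc = {"adc_clipped_samples": 0, "invalid_voxels": 0}
    for start in range(0, n_subj, per_chunk):
        stop = min(start + per_chunk, n_subj)
        block = cohort.signals[start:stop].reshape(-1, n_volumes)
        res = compute_subject_metrics_flat(block, cohort.scheme, tau=tau,
                                           sh_order=sh_order, lambda_lb=lambda_lb,
                                           scaling_enabled=scaling_enabled)
        for k, v in qc.items():
            qc[k] = v + res["_qc"][k]
        for m in METRIC_ORDER:
            out[m][start:stop] = res[m].reshape(stop - start, n_vox)
    out["_qc"] = qc
    return out


#: two-compartment signal-experiment defaults.  d∥ is fixed for both families;
#: the reference d⊥ (at f=1) is the largest-margin feasible choice — with 30-70%
#: free water at D0 = 3.0e-3 mm²/s the fitted FA cannot exceed ~0.49, and the
#: fitted MD cannot fall below ~1.6e-3 mm²/s at f = 0.3.
SIGNAL_EXPERIMENT = {
    "d_par": 2.0e-3,            # mm²/s
    "d_perp_ref_fa": 0.9e-3,    # constant-FA family reference (FA ≈ 0.46)
    "d_perp_ref_md": 1.5e-3,    # constant-MD family reference (MD ≈ 1.67e-3)
}


def run_signal_experiment(f_grid: np.ndarray | None = None,
                          tau: float = 0.070) -> dict[str, dict[str, np.ndarray]]:
    """Constant-FA and constant-MD two-compartment families with all metrics.

    Returns {"constant_fa": {metric: curve over f}, "constant_md": ...,
    "f_grid": grid}; each curve has one value per f.  This is the synthetic
    signal experiment behind the qualitative metric-vs-f comparisons.
    """
    from .synthetic_cohort import (constant_fa_family, constant_md_family,
                                   make_scheme, two_compartment_signal)
    if f_grid is None:
        f_grid = np.linspace(0.3, 1.0, 15)
    scheme = make_scheme()
    p = SIGNAL_EXPERIMENT
    out: dict = {"f_grid": np.asarray(f_grid, dtype=float)}
    for name, family in (
        ("constant_fa", constant_fa_family(f_grid, d_par=p["d_par"],
                                           d_perp_ref=p["d_perp_ref_fa"], scheme=scheme)),
        ("constant_md", constant_md_family(f_grid, d_par=p["d_par"],
                                           d_perp_ref=p["d_perp_ref_md"], scheme=scheme)),
    ):
        sig = np.stack([np.concatenate([
            [1.0], two_compartment_signal(scheme.shell_b, scheme.dwi_directions, q)])
            for q in family])
        res = compute_subject_metrics_flat(sig, scheme, tau=tau)
        res.pop("_qc")
        res["d_perp"] = np.array([q.d_perp for q in family])
        out[name] = res
    return out


def run_roi_stats(cohort: CohortData, metrics: dict[str, np.ndarray],
                  config: StudyConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ROI table + full-sample comparison table for a fitted cohort."""
    spec = ROIExtractionSpec(trim_low=config.trim_low, trim_high=config.trim_high)
    metric_values = {m: metrics[m] for m in METRIC_ORDER}
    roi_table = extract_roi_table(metric_values, cohort.labels_flat,
                                  cohort.skeleton_flat, cohort.design, spec)
    comparisons = roi_comparison_table(roi_table, alpha=config.alpha)
    return roi_table, comparisons


def run_resampling(roi_table: pd.DataFrame, comparisons: pd.DataFrame,
                   config: StudyConfig) -> ResamplingResult:
    plan = ResamplingPlan(full_sizes=dict(config.cohort.group_sizes),
                          B=config.resample_B, alpha=config.alpha,
                          base_seed=config.base_seed)
    return subsample_experiment(roi_table, plan, restrict_to=comparisons)


#: compact atlases for the replicated validation experiments — small regions
#: keep hundreds of full-pipeline replicates tractable; region size does not
#: enter the subject-level test statistics.
CALIBRATION_ATLAS = {"n_regions": 12, "grid_dims": (8, 6, 2)}    # 2×2×2 regions
RECOVERY_ATLAS = {"n_regions": 12, "grid_dims": (12, 9, 3)}      # 3×3×3 regions


def _comparison_matrices(cohort: CohortData, metrics: dict[str, np.ndarray],
                         config: StudyConfig):
    """ROI table pivot + per-group value matrices (subjects × series)."""
    spec = ROIExtractionSpec(trim_low=config.trim_low, trim_high=config.trim_high)
    roi_table = extract_roi_table({m: metrics[m] for m in METRIC_ORDER},
                                  cohort.labels_flat, cohort.skeleton_flat,
                                  cohort.design, spec)
    pivot = roi_table.pivot_table(index="subject_id", columns=["roi", "metric"],
                                  values="value", sort=False)
    grp = roi_table.drop_duplicates("subject_id").set_index("subject_id")["group"]
    grp = grp.loc[pivot.index]
    groups = list(dict.fromkeys(cohort.design["group"]))
    return roi_table, pivot, {g: pivot[grp == g].to_numpy() for g in groups}


def run_null_calibration(n_replicates: int = 500, alpha: float = 0.05,
                         snr: float = 30.0, n_per_group: int = 50,
                         base_seed: int = 0) -> dict:
    """Empirical type-I error of the full pipeline on null cohorts.

    Generates ``n_replicates`` three-group cohorts with no injected effects
    (biological f variability and Rician noise only), runs simulate → fit →
    trimmed ROI means → pooled t-tests for all three group pairs, and pools
    the per-test rejection rate at ``alpha`` across replicates.
    """
    from .roi_stats import pooled_t_test_vectorized

    ss = np.random.SeedSequence(base_seed, spawn_key=(101,))
    seeds = ss.generate_state(n_replicates) % (2**31)
    hits = 0
    total = 0
    for seed in seeds:
        spec = CohortSpec(group_sizes={"HC": n_per_group, "EM": n_per_group,
                                       "CM": n_per_group},
                          snr=snr, seed=int(seed), **CALIBRATION_ATLAS)
        cohort = generate_cohort(spec)
        metrics = compute_cohort_metrics(cohort)
        cfg = StudyConfig(cohort=spec, alpha=alpha)
        _, _, mats = _comparison_matrices(cohort, metrics, cfg)
        for a, b in (("EM", "HC"), ("CM", "HC"), ("CM", "EM")):
            _, p = pooled_t_test_vectorized(mats[a], mats[b])
            hits += int((p < alpha).sum())
            total += p.size
    return {"rejection_rate": hits / total, "n_tests": total,
            "n_replicates": n_replicates}


def run_null_majority_check(B: int = 501, n_planner_seeds: int = 5,
                            snr: float = 30.0, n_per_group: int = 50,
                            base_seed: int = 0, size: int = 10) -> dict:
    """Majority-vote robustness of a null cohort at a strongly reduced size.

    At subsample sizes close to the full N, a chance-significant full-sample
    test is reproduced by construction; the informative check is at a strongly
    reduced size, where the selection effect decays (expected |t| shrinks by
    sqrt(n/N)).  Counts, over planner seeds, how many (ROI, metric, pair)
    tests reach the >= ceil(B/2) criterion at ``size`` subjects per group.
    """
    spec = CohortSpec(group_sizes={"HC": n_per_group, "EM": n_per_group,
                                   "CM": n_per_group},
                      snr=snr, seed=base_seed + 17, **RECOVERY_ATLAS)
    cohort = generate_cohort(spec)
    metrics = compute_cohort_metrics(cohort)
    cfg = StudyConfig(cohort=spec)
    roi_table, _ = run_roi_stats(cohort, metrics, cfg)
    n_majority = []
    for k in range(n_planner_seeds):
        plan = ResamplingPlan(full_sizes=dict(spec.group_sizes), B=B,
                              base_seed=base_seed + 1000 * k,
                              sizes_override=(size,))
        res = subsample_experiment(roi_table, plan, compute_cqv=False)
        n_majority.append(int(res.counts["significant"].sum()))
    return {"n_majority_per_planner_seed": n_majority, "size": size, "B": B,
            "threshold": int(np.ceil(B / 2))}


def run_effect_recovery(n_seeds: int = 20, B: int = 501, snr: float = 30.0,
                        f_offset: float = -0.05, n_injected: int = 6,
                        group_sizes: dict[str, int] | None = None,
                        base_seed: int = 0, metric: str = "RTOP") -> dict:
    """Injected-effect recovery and significance-vs-sample-size behavior.

    Per cohort seed: inject ``f_offset`` on the zeppelin fraction in
    ``n_injected`` of 12 regions for the EM group, run the full pipeline, and
    (a) count injected regions with a significant EM-HC difference for
    ``metric`` at full N, (b) run the subsample experiment restricted to the
    reference-significant tests and count robustly significant ROIs for
    ``metric`` at every size.  Returns per-seed recovered counts and the
    median significance-vs-size curve.
    """
    if group_sizes is None:
        group_sizes = {"HC": 50, "EM": 51}
    offsets = {"EM": {r: {"f": f_offset} for r in range(1, n_injected + 1)}}
    ss = np.random.SeedSequence(base_seed, spawn_key=(202,))
    seeds = ss.generate_state(n_seeds) % (2**31)

    recovered = []
    curves = []
    sizes = None
    for seed in seeds:
        spec = CohortSpec(group_sizes=dict(group_sizes), offsets=offsets,
                          snr=snr, seed=int(seed), **RECOVERY_ATLAS)
        cohort = generate_cohort(spec)
        metrics = compute_cohort_metrics(cohort)
        cfg = StudyConfig(cohort=spec)
        roi_table, comparisons = run_roi_stats(cohort, metrics, cfg)
        ref = comparisons[(comparisons["metric"] == metric)
                          & (comparisons["group_a"] == "EM")
                          & (comparisons["group_b"] == "HC")
                          & (comparisons["roi"].between(1, n_injected))]
        recovered.append(int(ref["significant"].sum()))

        plan = ResamplingPlan(full_sizes=dict(group_sizes), B=B, base_seed=int(seed))
        res = subsample_experiment(roi_table, plan, restrict_to=comparisons,
                                   compute_cqv=False)
        sizes = plan.sizes
        c = res.counts
        sel = c[(c["metric"] == metric) & (c["group_a"] == "EM")
                & (c["group_b"] == "HC") & (c["roi"] != 0)]
        curve = sel.groupby("size")["significant"].sum()
        curves.append([int(curve.get(s, 0)) for s in sizes])

    curves = np.array(curves)  # (n_seeds, n_sizes)
    return {"sizes": list(sizes), "recovered_full_n": recovered,
            "median_recovered": float(np.median(recovered)),
            "median_curve": np.median(curves, axis=0).tolist(),
            "metric": metric, "n_injected": n_injected}


def _manifest(config: StudyConfig, stage: str) -> dict:
    return {"stage": stage, "config_digest": config.digest(),
            "base_seed": config.base_seed, "amura_version": __version__,
            "numpy_version": np.__version__}


def _write_manifest(config: StudyConfig, stage: str, out: Path) -> None:
    (out / f"manifest_{stage}.json").write_text(json.dumps(_manifest(config, stage), indent=2))


def run_study(config: StudyConfig, write_volumes: bool = False) -> dict:
    """End-to-end in-memory study; optionally persists everything under out_dir.

    Returns a dict with the cohort, metrics, roi_table, comparisons,
    resampling result and significance-vs-size curves.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cohort = generate_cohort(config.cohort)
    if write_volumes:
        write_cohort(cohort, out / "cohort")
    _write_manifest(config, "simulate", out)

    metrics = compute_cohort_metrics(cohort, tau=config.tau, sh_order=config.sh_order,
                                     lambda_lb=config.lambda_lb,
                                     scaling_enabled=config.anisotropy_scaling)
    if write_volumes:
        maps_dir = out / "maps"
        maps_dir.mkdir(exist_ok=True)
        mask = cohort.mask
        for i, sid in enumerate(cohort.design["subject_id"]):
            for m in METRIC_ORDER:
                vol = np.zeros(cohort.grid.dims)
                vol[mask] = metrics[m][i]
                write_volume(vol, cohort.grid, maps_dir / f"{sid}_{m}.nii.gz")
    (out / "qc.json").write_text(json.dumps(metrics["_qc"], indent=2))
    _write_manifest(config, "fit", out)

    roi_table, comparisons = run_roi_stats(cohort, metrics, config)
    roi_table.to_csv(out / "roi_table.tsv", sep="\t", index=False)
    comparisons.to_csv(out / "comparisons.tsv", sep="\t", index=False)
    _write_manifest(config, "roistats", out)

    result = run_resampling(roi_table, comparisons, config)
    result.counts.to_csv(out / "resampling_counts.tsv", sep="\t", index=False)
    result.cqv_summary.to_csv(out / "cqv_summary.tsv", sep="\t", index=False)
    curves = significance_vs_size_curve(result)
    curves.to_csv(out / "significance_vs_size.tsv", sep="\t", index=False)
    _write_manifest(config, "resample", out)

    return {"cohort": cohort, "metrics": metrics, "roi_table": roi_table,
            "comparisons": comparisons, "resampling": result, "curves": curves}
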