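"""Skeleton-restricted trimmed ROI summaries and two-group statistics.

Per subject and region, the metric is summarized as the mean over the voxels
of the ROI ∩ skeleton whose values lie strictly inside the [2, 98] percentile
bounds of those same voxels (linear-interpolation quantiles).  Group
comparisons are classical pooled-variance two-tailed t-tests with Cohen's D
effect sizes; no multiple-comparison correction is applied by default (an FDR
switch exists but is off, matching the exploratory region-wise design).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ROIExtractionSpec",
    "ComparisonRecord",
    "trimmed_roi_mean",
    "trimmed_mean_values",
    "extract_roi_table",
    "pooled_t_test",
    "pooled_t_test_vectorized",
    "cohens_d",
    "chi_square_contingency",
    "roi_comparison_table",
    "FULL_WM_ROI",
]

#: pseudo-ROI id for the whole skeleton ("full white matter") row
FULL_WM_ROI = 0


@dataclass(frozen=True)
class ROIExtractionSpec:
    """Trim percentiles and skeleton restriction for ROI summaries."""

    trim_low: float = 2.0
    trim_high: float = 98.0
    restrict_to_skeleton: bool = True
    per_roi_bounds: bool = True  # bounds from ROI∩skeleton values (vs global skeleton)

    def __post_init__(self) -> None:
        if not (0.0 <= self.trim_low < self.trim_high <= 100.0):
            raise ValueError("need 0 <= trim_low < trim_high <= 100")


def trimmed_mean_values(values: np.ndarray, spec: ROIExtractionSpec = ROIExtractionSpec(),
                        bounds_from: np.ndarray | None = None) -> float:
    """Mean of ``values`` strictly inside their [low, high] percentile bounds.

    Percentiles use linear interpolation between order statistics; values
    exactly equal to a bound are excluded.  If the strict trim empties the
    sample (heavily tied data), the inclusive window [lo, hi] is used instead,
    and failing that the plain mean — so constant data yields the constant.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return float("nan")
    ref = v if bounds_from is None else np.asarray(bounds_from, dtype=float)
    lo, hi = np.percentile(ref, [spec.trim_low, spec.trim_high])
    inner = v[(v > lo) & (v < hi)]
    if inner.size == 0:
        inner = v[(v >= lo) & (v <= hi)]
    if inner.size == 0:
        return float(v.mean())
    return float(inner.mean())


def trimmed_roi_mean(scalar_map: np.ndarray, roi_mask: np.ndarray,
                     skeleton_mask: np.ndarray | None = None,
                     spec: ROIExtractionSpec = ROIExtractionSpec(),
                     global_skeleton_values: np.ndarray | None = None) -> float:
    """Trimmed mean of a scalar map over ROI ∩ skeleton.

    Returns NaN (with a warning-free sentinel) on an empty intersection.
    """
    sel = np.asarray(roi_mask, dtype=bool)
    if spec.restrict_to_skeleton and skeleton_mask is not None:
        sel = sel & np.asarray(skeleton_mask, dtype=bool)
    vals = np.asarray(scalar_map, dtype=float)[sel]
    if vals.size == 0:
        return float("nan")
    bounds_from = None if spec.per_roi_bounds else global_skeleton_values
    return trimmed_mean_values(vals, spec, bounds_from=bounds_from)


def extract_roi_table(metric_values: dict[str, np.ndarray], labels_flat: np.ndarray,
                      skeleton_flat: np.ndarray, design: pd.DataFrame,
                      spec: ROIExtractionSpec = ROIExtractionSpec()) -> pd.DataFrame:
    """Subjects × (ROI, metric) table of trimmed means (long format).

    ``metric_values[name]`` has shape (n_subjects, n_vox) over the flattened
    atlas voxels; ROI id 0 is added as the full-skeleton pseudo-ROI.
    Returns a DataFrame with columns subject_id, group, roi, metric, value.
    """
    labels_flat = np.asarray(labels_flat)
    skeleton_flat = np.asarray(skeleton_flat, dtype=bool)
    rois = [FULL_WM_ROI] + sorted(int(r) for r in np.unique(labels_flat) if r > 0)
    roi_sel = {r: (skeleton_flat if r == FULL_WM_ROI else (labels_flat == r) & skeleton_flat)
               for r in rois}
    frames = []
    sids = design["subject_id"].to_numpy()
    grps = design["group"].to_numpy()
    for metric, arr in metric_values.items():
        arr = np.asarray(arr, dtype=float)
        for r, sel in roi_sel.items():
            vals = arr[:, sel]  # (n_subjects, n_roi_vox)
            tm = _trimmed_mean_rows(vals, spec)
            frames.append(pd.DataFrame({"subject_id": sids, "group": grps,
                                        "roi": r, "metric": metric, "value": tm}))
    return pd.concat(frames, ignore_index=True)


def _trimmed_mean_rows(vals: np.ndarray, spec: ROIExtractionSpec) -> np.ndarray:
    """Row-wise strict-bound trimmed mean of a (n_subjects, n_vox) block."""
    if vals.shape[1] == 0:
        return np.full(vals.shape[0], np.nan)
    lo, hi = np.percentile(vals, [spec.trim_low, spec.trim_high], axis=1)
    inside = (vals > lo[:, None]) & (vals < hi[:, None])
    n_in = inside.sum(axis=1)
    if np.any(n_in == 0):  # tied rows: fall back to the inclusive window
        loose = (vals >= lo[:, None]) & (vals <= hi[:, None])
        inside = np.where((n_in == 0)[:, None], loose, inside)
        n_in = inside.sum(axis=1)
    safe = np.where(n_in > 0, n_in, 1)
    trimmed = np.where(inside, vals, 0.0).sum(axis=1) / safe
    return np.where(n_in > 0, trimmed, vals.mean(axis=1))


def pooled_t_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Equal-variance two-sample two-tailed t-test; df = n_a + n_b - 2.

    Zero pooled variance: returns (0, 1) for equal means, (inf sign, 0) else.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    sp2 = _pooled_var(a, b)
    if sp2 <= 0:
        if np.isclose(a.mean(), b.mean()):
            return 0.0, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    df = len(a) + len(b) - 2
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / len(a) + 1.0 / len(b)))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def _pooled_var(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    return ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)


def pooled_t_test_vectorized(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise pooled t-test: a (na, k) vs b (nb, k) → (t, p) arrays (k,)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.shape[-2], b.shape[-2]
    df = na + nb - 2
    va = a.var(axis=-2, ddof=1)
    vb = b.var(axis=-2, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / df
    diff = a.mean(axis=-2) - b.mean(axis=-2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        t = np.where(sp2 > 0, t,
                     np.where(np.isclose(diff, 0.0), 0.0, np.inf * np.sign(diff)))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, p


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Standardized mean difference with the (n-1)-weighted pooled SD."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    sp2 = _pooled_var(a, b)
    if sp2 <= 0:
        return float("nan") if not np.isclose(a.mean(), b.mean()) else 0.0
    return float((a.mean() - b.mean()) / np.sqrt(sp2))


def chi_square_contingency(table: np.ndarray) -> tuple[float, int]:
    """Pearson chi-square Σ(O-E)²/E on an r×c count table, no continuity correction.

    Returns (statistic, df) with df = (r-1)(c-1).
    """
    obs = np.asarray(table, dtype=float)
    if np.any(obs < 0):
        raise ValueError("counts must be nonnegative")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if np.any(rows <= 0) or np.any(cols <= 0):
        raise ValueError("every row and column must have a positive total")
    expected = np.outer(rows, cols) / obs.sum()
    stat = float(np.sum((obs - expected) ** 2 / expected))
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return stat, df


@dataclass
class ComparisonRecord:
    """One two-group test: ROI × metric × group pair."""

    roi: int
    metric: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    t: float
    p: float
    cohens_d: float
    significant: bool
    medium_effect: bool  # |D| > 0.5


def roi_comparison_table(roi_table: pd.DataFrame,
                         pairs: list[tuple[str, str]] | None = None,
                         alpha: float = 0.05,
                         fdr: bool = False) -> pd.DataFrame:
    """All pairwise group comparisons per (ROI, metric), incl. the full-WM row.

    ``pairs`` defaults to all group pairs in first-appearance order (for the
    default HC/EM/CM design: EM-HC, CM-HC, CM-EM).  Returns a DataFrame of
    :class:`ComparisonRecord` fields; ``fdr=True`` applies Benjamini-Hochberg
    within each (metric, pair) across ROIs (off by default).
    """
    groups = list(dict.fromkeys(roi_table["group"]))
    if pairs is None:
        pairs = [(b, a) for a, b in combinations(groups, 2)]
    known = set(groups)
    for a, b in pairs:
        if a not in known or b not in known:
            raise ValueError(f"unknown group in pair ({a}, {b}); design has {sorted(known)}")
    records = []
    pivot = roi_table.pivot_table(index="subject_id", columns=["roi", "metric"],
                                  values="value", sort=False)
    subj_group = roi_table.drop_duplicates("subject_id").set_index("subject_id")["group"]
    for (roi, metric) in pivot.columns:
        col = pivot[(roi, metric)]
        for a, b in pairs:
            va = col[subj_group == a].to_numpy()
            vb = col[subj_group == b].to_numpy()
            t, p = pooled_t_test(va, vb)
            d = cohens_d(va, vb)
            records.append(ComparisonRecord(
                roi=int(roi), metric=str(metric), group_a=a, group_b=b,
                n_a=len(va), n_b=len(vb), t=t, p=p, cohens_d=d,
                significant=bool(p < alpha), medium_effect=bool(abs(d) > 0.5)))
    out = pd.DataFrame([r.__dict__ for r in records])
    if fdr:
        from statsmodels.stats.multitest import multipletests
        out["significant"] = False
        for (_, _), idx in out.groupby(["metric", "group_a"]).groups.items():
            rej, *_ = multipletests(out.loc[idx, "p"], alpha=alpha, method="fdr_bh")
            out.loc[idx, "significant"] = rej
    return out
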