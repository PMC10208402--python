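"""Sample-size robustness by subsample resampling, and CQV stability.

The experiment re-runs the region-wise pooled t-tests on many random
subsamples of each group at a grid of reduced sample sizes (full N down to 10
in steps of 5).  A test is called robustly significant at size n when at
least half of the B subsamples (≥ ceil(B/2), i.e. ≥ 2,501 of 5,001) reject at
α = 0.05.  Stability of each metric is summarized by the coefficient of
quartile variation

    CQV = (Q3 - Q1) / (Q3 + Q1) · 100   (percent)

per group × ROI × metric, reported as the median over subsamples with a 95%
interval from the 2.5 / 97.5 percentiles of the per-subsample CQVs.

Subsampling is without replacement (reduced-size subsets of distinct
subjects); a with-replacement bootstrap mode is available.  The per-subsample
seed is derived from (base_seed, size, iteration) so any draw can be
reconstructed in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .roi_stats import pooled_t_test_vectorized

__all__ = [
    "ResamplingPlan",
    "ResamplingResult",
    "CQVResult",
    "cqv",
    "cqv_array",
    "subsample_experiment",
    "significance_vs_size_curve",
]


@dataclass(frozen=True)
class ResamplingPlan:
    """Size grid and subsample count for the resampling experiment.

    ``sizes`` defaults to full N down to ``min_size`` (10) in steps of
    ``step`` (5).  The majority threshold is ceil(B/2) — 2,501 for the
    reference B = 5,001.
    """

    full_sizes: dict[str, int]
    B: int = 5001
    alpha: float = 0.05
    min_size: int = 10
    step: int = 5
    base_seed: int = 0
    with_replacement: bool = False
    sizes_override: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.min_size < 2:
            raise ValueError("min_size must be >= 2")
        if self.B < 1:
            raise ValueError("B must be >= 1")

    @property
    def threshold(self) -> int:
        return int(np.ceil(self.B / 2))

    @property
    def sizes(self) -> list[int]:
        if self.sizes_override is not None:
            return list(self.sizes_override)
        n_min = min(self.full_sizes.values())
        out = [n_min]
        n = n_min - (n_min % self.step or self.step)
        while n >= self.min_size:
            if n < n_min:
                out.append(n)
            n -= self.step
        return out


@dataclass
class ResamplingResult:
    """Counts of rejecting subsamples and CQV summaries per size."""

    plan: ResamplingPlan
    counts: pd.DataFrame      # size, roi, metric, group_a, group_b, n_reject, significant
    cqv_summary: pd.DataFrame  # size, group, roi, metric, cqv_median, cqv_lo, cqv_hi


@dataclass(frozen=True)
class CQVResult:
    Q1: float
    Q3: float
    cqv: float


def cqv(values: np.ndarray) -> CQVResult:
    """Coefficient of quartile variation of a sample, in percent.

    Quartiles use linear interpolation between order statistics.  Returns a
    NaN CQV when Q1 + Q3 <= 0 (only possible with non-positive data).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 4:
        raise ValueError("CQV needs at least 4 values")
    q1, q3 = np.percentile(v, [25.0, 75.0])
    denom = q3 + q1
    val = float("nan") if denom <= 0 else float((q3 - q1) / denom * 100.0)
    return CQVResult(Q1=float(q1), Q3=float(q3), cqv=val)


def cqv_array(values: np.ndarray, axis: int = -1) -> np.ndarray:
    """CQV along an axis of a stacked array (NaN where Q1+Q3 <= 0)."""
    q1, q3 = np.percentile(values, [25.0, 75.0], axis=axis)
    denom = q3 + q1
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (q3 - q1) / denom * 100.0
    return np.where(denom > 0, out, np.nan)


def _subsample_indices(rng: np.random.Generator, n_group: int, n_draw: int,
                       with_replacement: bool) -> np.ndarray:
    if with_replacement:
        return rng.integers(0, n_group, size=n_draw)
    return rng.permutation(n_group)[:n_draw]


def subsample_experiment(roi_table: pd.DataFrame, plan: ResamplingPlan,
                         pairs: list[tuple[str, str]] | None = None,
                         restrict_to: pd.DataFrame | None = None,
                         compute_cqv: bool = True) -> ResamplingResult:
    """Run the full resampling experiment on a subjects × (ROI, metric) table.

    Parameters
    ----------
    roi_table : long-format table from :func:`amura.roi_stats.extract_roi_table`.
    plan : size grid, subsample count B, α and base seed.
    pairs : group pairs to test; defaults to all pairs (first-appearance order).
    restrict_to : optional comparison table of the full-sample reference run;
        only its ``significant`` rows are re-tested in the subsamples (the
        reference-significant restriction).  ``None`` re-tests everything.

    Returns per (size, ROI, metric, pair) the count of subsamples with
    p < α and the majority flag (count ≥ ceil(B/2)), and per (size, group,
    ROI, metric) the median and 2.5/97.5-percentile interval of the
    per-subsample CQVs.  Bit-for-bit reproducible from ``plan.base_seed``.
    """
    groups = list(dict.fromkeys(roi_table["group"]))
    if pairs is None:
        from itertools import combinations
        pairs = [(b, a) for a, b in combinations(groups, 2)]

    pivot = roi_table.pivot_table(index="subject_id", columns=["roi", "metric"],
                                  values="value", sort=False)
    subj_group = roi_table.drop_duplicates("subject_id").set_index("subject_id")["group"]
    subj_group = subj_group.loc[pivot.index]
    group_mats = {g: pivot[subj_group == g].to_numpy() for g in groups}
    series = list(pivot.columns)  # (roi, metric) tuples

    if restrict_to is not None:
        sig = restrict_to[restrict_to["significant"]]
        keep = {(int(r.roi), r.metric, r.group_a, r.group_b) for r in sig.itertuples()}
    else:
        keep = None

    for g, n in plan.full_sizes.items():
        if g in group_mats and n > group_mats[g].shape[0]:
            raise ValueError(f"plan size {n} exceeds group {g} size {group_mats[g].shape[0]}")

    count_rows = []
    cqv_rows = []
    for size in plan.sizes:
        # subsample index arrays per group: (B, size)
        idx = {}
        for g in groups:
            n_g = group_mats[g].shape[0]
            n_draw = min(size, n_g)
            draws = np.empty((plan.B, n_draw), dtype=int)
            for b_it in range(plan.B):
                ss = np.random.SeedSequence(
                    entropy=plan.base_seed, spawn_key=(size, b_it))
                draws[b_it] = _subsample_indices(np.random.default_rng(ss), n_g,
                                                 n_draw, plan.with_replacement)
            idx[g] = draws

        # sub[g]: (B, n_draw, n_series)
        sub = {g: group_mats[g][idx[g]] for g in groups}

        for a, b in pairs:
            t, p = pooled_t_test_vectorized(sub[a], sub[b])  # (B, n_series)
            rej = p < plan.alpha
            n_rej = rej.sum(axis=0)
            for j, (roi, metric) in enumerate(series):
                key = (int(roi), metric, a, b)
                if keep is not None and key not in keep:
                    continue
                count_rows.append((size, int(roi), metric, a, b, int(n_rej[j]),
                                   bool(n_rej[j] >= plan.threshold)))

        for g in groups if compute_cqv else ():
            c = cqv_array(sub[g], axis=1)  # (B, n_series)
            med = np.median(c, axis=0)
            lo, hi = np.percentile(c, [2.5, 97.5], axis=0)
            for j, (roi, metric) in enumerate(series):
                cqv_rows.append((size, g, int(roi), metric,
                                 float(med[j]), float(lo[j]), float(hi[j])))

    counts = pd.DataFrame(count_rows, columns=["size", "roi", "metric", "group_a",
                                               "group_b", "n_reject", "significant"])
    cqv_summary = pd.DataFrame(cqv_rows, columns=["size", "group", "roi", "metric",
                                                  "cqv_median", "cqv_lo", "cqv_hi"])
    return ResamplingResult(plan=plan, counts=counts, cqv_summary=cqv_summary)


def significance_vs_size_curve(result: ResamplingResult,
                               exclude_full_wm: bool = True) -> pd.DataFrame:
    """Number of robustly significant ROIs per (metric, pair) at each size.

    Monotonicity in size is an empirical expectation, not enforced.
    """
    c = result.counts
    if exclude_full_wm:
        c = c[c["roi"] != 0]
    curve = (c.groupby(["metric", "group_a", "group_b", "size"])["significant"]
             .sum().rename("n_significant_rois").reset_index())
    return curve.sort_values(["metric", "group_a", "group_b", "size"],
                             ascending=[True, True, True, False]).reset_index(drop=True)
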