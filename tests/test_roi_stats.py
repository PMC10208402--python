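"""Trimmed ROI summaries and the two-group statistics."""

import numpy as np
import pandas as pd
import pytest

from amura.roi_stats import (FULL_WM_ROI, ROIExtractionSpec, chi_square_contingency,
                             cohens_d, extract_roi_table, pooled_t_test,
                             pooled_t_test_vectorized, roi_comparison_table,
                             trimmed_mean_values, trimmed_roi_mean)


class TestTrimmedMean:
    def test_constant_is_identity(self):
        assert trimmed_mean_values(np.full(50, 3.3)) == pytest.approx(3.3)

    def test_single_outlier_excluded(self):
        vals = np.concatenate([np.ones(99), [100.0]])
        assert trimmed_mean_values(vals) == pytest.approx(1.0)

    def test_permutation_invariant(self, rng):
        vals = rng.standard_normal(200)
        assert trimmed_mean_values(vals) == pytest.approx(
            trimmed_mean_values(rng.permutation(vals)))

    def test_shift_equivariant(self, rng):
        vals = rng.standard_normal(100)
        assert trimmed_mean_values(vals + 5.0) == pytest.approx(
            trimmed_mean_values(vals) + 5.0)

    def test_roi_skeleton_restriction(self):
        vol = np.zeros((4, 4, 4))
        roi = np.zeros((4, 4, 4), bool)
        skel = np.zeros((4, 4, 4), bool)
        roi[:2] = True
        skel[0] = True
        vol[0] = 2.0
        vol[1] = 99.0  # in ROI but off-skeleton; must not contribute
        assert trimmed_roi_mean(vol, roi, skel) == pytest.approx(2.0)

    def test_empty_intersection_is_nan(self):
        vol = np.zeros((2, 2, 2))
        assert np.isnan(trimmed_roi_mean(vol, np.zeros((2, 2, 2), bool),
                                         np.ones((2, 2, 2), bool)))

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            ROIExtractionSpec(trim_low=98, trim_high=2)


class TestPooledT:
    def test_identical_groups(self):
        a = np.array([1.0, 2.0, 3.0])
        assert pooled_t_test(a, a.copy()) == (0.0, 1.0)

    def test_textbook_formula(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = np.array([2.0, 3.0, 4.0, 5.0, 6.0])
        t, p = pooled_t_test(a, b)
        # hand computation: means 3, 4; s² = 2.5 each; sp² = 2.5; df = 8
        t_hand = (3.0 - 4.0) / np.sqrt(2.5 * (1 / 5 + 1 / 5))
        assert t == pytest.approx(t_hand, abs=1e-10)
        from scipy import stats
        assert p == pytest.approx(2 * stats.t.sf(abs(t_hand), 8), abs=1e-12)

    def test_antisymmetry(self, rng):
        a, b = rng.standard_normal(10), rng.standard_normal(12) + 0.5
        t_ab, p_ab = pooled_t_test(a, b)
        t_ba, p_ba = pooled_t_test(b, a)
        assert t_ab == pytest.approx(-t_ba)
        assert p_ab == pytest.approx(p_ba)

    def test_vectorized_matches_scalar(self, rng):
        A = rng.standard_normal((8, 5))
        B = rng.standard_normal((11, 5)) + 0.3
        t_vec, p_vec = pooled_t_test_vectorized(A, B)
        for j in range(5):
            t, p = pooled_t_test(A[:, j], B[:, j])
            assert t_vec[j] == pytest.approx(t, abs=1e-12)
            assert p_vec[j] == pytest.approx(p, abs=1e-12)

    def test_zero_variance_sentinels(self):
        same = np.array([2.0, 2.0, 2.0])
        other = np.array([3.0, 3.0, 3.0])
        assert pooled_t_test(same, same.copy()) == (0.0, 1.0)
        t, p = pooled_t_test(same, other)
        assert np.isinf(t) and p == 0.0


class TestCohensD:
    def test_identical_is_zero(self):
        a = np.array([1.0, 2.0, 3.0])
        assert cohens_d(a, a.copy()) == 0.0

    def test_one_pooled_sd_gap(self, rng):
        a = rng.standard_normal(500)
        d = cohens_d(a + a.std(ddof=1), a)
        assert d == pytest.approx(1.0, abs=1e-12)

    def test_sign_convention(self):
        a = np.array([2.0, 3.0, 4.0])
        b = np.array([1.0, 2.0, 3.0])
        assert cohens_d(a, b) > 0 > cohens_d(b, a)


class TestChiSquare:
    def test_homogeneous_table_is_zero(self):
        table = np.array([[10, 20, 30], [20, 40, 60]])
        stat, df = chi_square_contingency(table)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert df == 2

    def test_migraine_study_gender_table(self):
        # male/female × (HC, EM, CM) counts of the motivating clinical study
        stat, df = chi_square_contingency([[11, 7, 6], [39, 44, 50]])
        assert df == 2
        assert round(stat, 2) == 2.74

    def test_random_2x2_against_direct_formula(self, rng):
        obs = rng.integers(5, 40, size=(2, 2)).astype(float)
        stat, _ = chi_square_contingency(obs)
        n = obs.sum()
        expected = np.outer(obs.sum(1), obs.sum(0)) / n
        direct = ((obs - expected) ** 2 / expected).sum()
        assert stat == pytest.approx(direct, abs=1e-10)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            chi_square_contingency([[0, 0], [1, 2]])


def toy_roi_table(rng, n_per_group=10, n_rois=3, metrics=("FA", "RTOP"), shift=0.0):
    rows = []
    for g, base in (("HC", 0.0), ("EM", shift), ("CM", 0.0)):
        for i in range(n_per_group):
            sid = f"{g}{i:02d}"
            for r in range(n_rois + 1):
                for m in metrics:
                    rows.append((sid, g, r, m, rng.standard_normal() +
                                 (base if r == 1 else 0.0)))
    return pd.DataFrame(rows, columns=["subject_id", "group", "roi", "metric", "value"])


class TestComparisonTable:
    def test_three_groups_three_pairs(self, rng):
        out = roi_comparison_table(toy_roi_table(rng))
        pairs = set(map(tuple, out[["group_a", "group_b"]].drop_duplicates().to_numpy()))
        assert pairs == {("EM", "HC"), ("CM", "HC"), ("CM", "EM")}

    def test_record_count_single_roi(self, rng):
        tab = toy_roi_table(rng, n_rois=1, metrics=("FA",))
        out = roi_comparison_table(tab)
        # per metric per pair: ROI 1 + full-WM pseudo-ROI 0
        assert len(out) == 2 * 3

    def test_injected_shift_detected_in_right_cell(self, rng):
        tab = toy_roi_table(rng, n_per_group=40, shift=2.0)
        out = roi_comparison_table(tab)
        hit = out[(out.roi == 1) & (out.group_a == "EM") & (out.group_b == "HC")]
        assert hit["significant"].all()
        assert (hit["cohens_d"].abs() > 0.5).all()
        null_cell = out[(out.roi == 2) & (out.group_a == "CM") & (out.group_b == "HC")]
        assert (~null_cell["significant"]).all() or null_cell["p"].min() > 1e-4

    def test_unknown_pair_rejected(self, rng):
        with pytest.raises(ValueError, match="unknown group"):
            roi_comparison_table(toy_roi_table(rng), pairs=[("EM", "XX")])

    def test_type_one_error_calibrated_at_table_level(self, rng):
        # null tables: every cell N(0,1); pooled rejection rate ≈ α
        hits, total = 0, 0
        for _ in range(300):
            a = rng.standard_normal((12, 4))
            b = rng.standard_normal((12, 4))
            _, p = pooled_t_test_vectorized(a, b)
            hits += (p < 0.05).sum()
            total += p.size
        rate = hits / total
        assert 0.03 < rate < 0.07


class TestExtractTable:
    def test_extract_roi_table_layout_and_values(self):
        labels = np.array([1, 1, 1, 2, 2, 2])
        skel = np.array([True, True, False, True, True, True])
        design = pd.DataFrame({"subject_id": ["s1", "s2"], "group": ["HC", "EM"]})
        vals = np.array([[1.0, 2.0, 99.0, 4.0, 5.0, 6.0],
                         [2.0, 4.0, 99.0, 8.0, 10.0, 12.0]])
        tab = extract_roi_table({"MD": vals}, labels, skel, design)
        assert set(tab["roi"]) == {FULL_WM_ROI, 1, 2}
        s1_roi1 = tab[(tab.subject_id == "s1") & (tab.roi == 1)]["value"].item()
        assert s1_roi1 == pytest.approx(1.5)  # off-skeleton voxel ignored
        wm = tab[(tab.subject_id == "s2") & (tab.roi == 0)]["value"].item()
        assert wm == pytest.approx(np.mean([4.0, 8.0, 10.0]))  # strict trim drops 2 & 12
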