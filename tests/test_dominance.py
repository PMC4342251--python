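"""Dominance indices, exact rank-sum verdicts, proximity bias, paternity ANOVA."""

import math
from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from mateguard import (
    dominance_indices,
    dominance_test,
    mann_whitney_exact,
    obtuse_angle_oracle,
    paternity_summary,
    proximity_bias_test,
)
from mateguard.dominance import PairingError

from conftest import make_triad, random_triad


class TestDominanceIndices:
    def test_one_sided_guarding(self):
        # A sits at the center of the (female, B) circle; B far beyond A.
        triad = make_triad((0, 0), (5, 0), (10, 0))
        ra, rb = dominance_indices(triad)
        assert ra.guarding_index == 1.0
        assert rb.guarding_index == 0.0
        assert (ra.focal_id, ra.reference_id) == ("A", "B")
        assert (rb.focal_id, rb.reference_id) == ("B", "A")

    def test_symmetric_males_both_acute(self):
        # Both males equidistant from the female, symmetric about her; each
        # sees the female and the rival at an acute angle.
        triad = make_triad((0, 0), (3, 4), (3, -4))
        assert not obtuse_angle_oracle((0, 0), (3, -4), (3, 4))
        ra, rb = dominance_indices(triad)
        assert ra.guarding_index == 0.0
        assert rb.guarding_index == 0.0

    def test_per_frame_indicator_sum_bounded(self, rng):
        triad = random_triad(rng)
        ra, rb = dominance_indices(triad)
        assert ra.n_in_circle + rb.n_in_circle <= ra.n_frames_used


def enumeration_oracle(a, b):
    """Brute-force two-sided Mann-Whitney p over all C(n, n_a) assignments."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n, n_a = len(pooled), len(a)

    def u_of(xs, ys):
        d = np.subtract.outer(xs, ys)
        return np.sum(d > 0) + 0.5 * np.sum(d == 0)

    u_obs = u_of(a, b)
    le = ge = 0
    for idx in combinations(range(n), n_a):
        sel = np.zeros(n, bool)
        sel[list(idx)] = True
        u = u_of(pooled[sel], pooled[~sel])
        le += u <= u_obs + 1e-12
        ge += u >= u_obs - 1e-12
    total = math.comb(n, n_a)
    return min(1.0, 2 * min(le, ge) / total)


class TestMannWhitneyExact:
    def test_complete_separation_n6(self):
        a = [0.60, 0.62, 0.58, 0.61, 0.59, 0.63]
        b = [0.20, 0.22, 0.18, 0.21, 0.19, 0.23]
        u, p = mann_whitney_exact(a, b)
        assert u == 0
        assert p == pytest.approx(2 / 924)

    def test_matches_scipy_exact_without_ties(self, rng):
        for _ in range(5):
            a = rng.uniform(size=6)
            b = rng.uniform(size=6)
            _, p = mann_whitney_exact(a, b)
            ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert p == pytest.approx(float(ref.pvalue))

    def test_matches_enumeration_oracle_with_ties(self, rng):
        # guarding indices are multiples of 1/21, so ties are common
        for _ in range(3):
            a = rng.integers(0, 8, size=5) / 21
            b = rng.integers(0, 8, size=5) / 21
            _, p = mann_whitney_exact(a, b)
            assert p == pytest.approx(enumeration_oracle(a, b))

    def test_all_tied_gives_p_one(self):
        _, p = mann_whitney_exact([0.5] * 6, [0.5] * 6)
        assert p == 1.0


class TestDominanceTest:
    A = [0.60, 0.62, 0.58, 0.61, 0.59, 0.63]
    B = [0.20, 0.22, 0.18, 0.21, 0.19, 0.23]

    def test_complete_separation_verdict(self):
        out = dominance_test(self.A, self.B, "wt", "tg")
        assert out.verdict == "a_dominant"
        assert out.u_statistic == 0
        assert out.p_value == pytest.approx(2 / 924)

    def test_identical_series_equal(self):
        out = dominance_test([0.5] * 6, [0.5] * 6)
        assert out.verdict == "equal"
        assert out.p_value == 1.0

    def test_antisymmetric_under_label_swap(self, rng):
        for _ in range(5):
            a = list(rng.integers(0, 22, size=6) / 21)
            b = list(rng.integers(0, 22, size=6) / 21)
            fwd = dominance_test(a, b)
            rev = dominance_test(b, a)
            assert fwd.p_value == pytest.approx(rev.p_value)
            flip = {"a_dominant": "b_dominant", "b_dominant": "a_dominant",
                    "equal": "equal"}
            assert rev.verdict == flip[fwd.verdict]

    def test_nonsignificant_is_equal_despite_mean_gap(self):
        out = dominance_test([0.5, 0.6], [0.4, 0.5])
        assert out.p_value > 0.05
        assert out.verdict == "equal"

    def test_unequal_lengths_rejected(self):
        with pytest.raises(PairingError):
            dominance_test([0.1, 0.2, 0.3], [0.1, 0.2])


class TestProximityBias:
    def _triads_with_counts(self, n_a, n_b):
        """Triads whose pooled frames give exactly (n_a, n_b) closer-counts."""
        triads = []
        total = n_a + n_b
        per_trial = 21
        k = 0
        t = 0
        while k < total:
            take = min(per_trial, total - k)
            a_path = np.zeros((21, 2))
            b_path = np.zeros((21, 2))
            for i in range(21):
                if i < take and k + i < n_a:
                    a_path[i] = [1.0, 0.0]
                    b_path[i] = [2.0, 0.0]
                else:
                    a_path[i] = [2.0, 0.0]
                    b_path[i] = [1.0, 0.0]
            triads.append(make_triad((0, 0), a_path, b_path, trial_id=f"p{t}"))
            k += per_trial
            t += 1
        return triads

    def test_balanced_counts(self):
        res = proximity_bias_test(self._triads_with_counts(126, 126))
        assert (res.n_frames_a_closer, res.n_frames_b_closer) == (126, 126)
        assert res.chi_square == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_biased_counts_match_goodness_of_fit_oracle(self):
        res = proximity_bias_test(self._triads_with_counts(150, 102))
        assert (res.n_frames_a_closer, res.n_frames_b_closer) == (150, 102)
        expected_chi2 = (150 - 126) ** 2 / 126 + (102 - 126) ** 2 / 126
        assert res.chi_square == pytest.approx(expected_chi2)
        assert res.chi_square == pytest.approx(9.1429, abs=1e-3)
        assert res.p_value == pytest.approx(stats.chi2.sf(expected_chi2, 1))
        assert res.p_value == pytest.approx(0.0025, abs=2e-4)

    def test_ties_excluded_and_reported(self):
        triad = make_triad((0, 0), (1, 0), (-1, 0), trial_id="tie")
        biased = self._triads_with_counts(21, 0)
        res = proximity_bias_test([triad] + biased)
        assert res.n_frames_tied == 21
        assert res.n_frames_a_closer + res.n_frames_b_closer == 21

    def test_counts_invariant_under_similarity_transform(self, rng):
        paths = rng.uniform(0, 10, size=(3, 21, 2))
        base = proximity_bias_test([make_triad(*paths)])
        theta = 1.1
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        moved = 3.7 * paths @ rot.T + np.array([12.0, -4.0])
        res = proximity_bias_test([make_triad(*moved)])
        assert (res.n_frames_a_closer, res.n_frames_b_closer) == (
            base.n_frames_a_closer, base.n_frames_b_closer)

    def test_no_frames_errors(self):
        with pytest.raises(ValueError):
            proximity_bias_test([])


class TestPaternitySummary:
    def test_extreme_groups(self):
        res = paternity_summary(
            {"tg_dominant": [100.0, 100.0, 100.0], "wt_dominant": [0.0, 0.0, 0.0]}
        )
        assert res.group_means == (100.0, 0.0)
        assert res.p_value < 1e-6

    def test_equal_means_f_near_zero(self):
        res = paternity_summary({"a": [50.0, 60.0], "b": [60.0, 50.0], "c": [55.0, 55.0]})
        assert res.f_statistic == pytest.approx(0.0, abs=1e-10)
        assert res.p_value == pytest.approx(1.0, abs=1e-6)

    def test_f_matches_sum_of_squares_oracle(self):
        groups = {"g1": [10.0, 20.0, 30.0], "g2": [25.0, 35.0, 45.0],
                  "g3": [50.0, 60.0, 70.0]}
        res = paternity_summary(groups)
        all_vals = np.concatenate(list(map(np.asarray, groups.values())))
        grand = all_vals.mean()
        ss_b = sum(len(v) * (np.mean(v) - grand) ** 2 for v in groups.values())
        ss_w = sum(np.sum((np.asarray(v) - np.mean(v)) ** 2) for v in groups.values())
        f_oracle = (ss_b / 2) / (ss_w / 6)
        assert res.f_statistic == pytest.approx(f_oracle)
        assert res.df_between == 2 and res.df_within == 6

    def test_scheffe_pairwise_detects_extreme_contrast(self):
        groups = {"lo": [1.0, 2.0, 1.5], "mid": [1.2, 2.1, 1.6],
                  "hi": [50.0, 52.0, 51.0]}
        res = paternity_summary(groups)
        assert res.scheffe_p[("lo", "hi")] < 0.001
        assert res.scheffe_p[("lo", "mid")] > 0.5

    def test_empty_group_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="empty"):
            res = paternity_summary({"a": [1.0, 2.0], "b": [3.0, 4.0], "c": []})
        assert "c" not in res.group_labels

    def test_too_few_groups_rejected(self):
        with pytest.raises(ValueError):
            paternity_summary({"a": [1.0, 2.0]})
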