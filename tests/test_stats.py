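"""DP-window statistics, FDR, and group comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from drowsyte import (bh_fdr, dp_windows, group_summarize,
                      pairwise_signed_rank, relative_te, rm_anova,
                      window_ranksum_vs_first)
from drowsyte.stats import apply_window_fdr


class TestRelativeTe:
    def test_hand_computed_example(self):
        out = relative_te([1, 2, 3, 4], [0, 1])
        np.testing.assert_allclose(out, [-0.5, 0.5, 1.5, 2.5])

    def test_full_baseline_centers_output(self, rng):
        v = rng.standard_normal(50)
        out = relative_te(v, np.arange(50))
        assert out.sum() == pytest.approx(0.0, abs=1e-10)

    def test_constant_values_give_zeros(self):
        np.testing.assert_allclose(relative_te([2.0] * 5, [0]), 0.0)

    def test_empty_baseline_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            relative_te([1.0, 2.0], [])


class TestDpWindows:
    def test_default_grid_has_26_windows(self):
        prof = dp_windows([2.0], [1.0])
        assert len(prof.members) == 26
        assert (prof.window_lo[0], prof.window_hi[0]) == (1.0, 1.5)
        assert prof.window_lo[-1] == pytest.approx(3.5)
        assert prof.window_hi[-1] == pytest.approx(4.0)

    def test_membership_of_single_dp(self):
        prof = dp_windows(np.full(10, 1.2), np.arange(10.0))
        populated = prof.n > 0
        # 1.2 lies in windows [1.0,1.5), [1.1,1.6) and [1.2,1.7) only
        assert list(np.where(populated)[0]) == [0, 1, 2]

    def test_constant_values_give_constant_means(self, rng):
        dps = rng.uniform(1, 4, 200)
        prof = dp_windows(dps, np.full(200, 3.3))
        np.testing.assert_allclose(prof.mean[prof.n > 0], 3.3)

    def test_dp_exactly_four_in_final_closed_window(self):
        prof = dp_windows([4.0], [7.0])
        assert prof.n[-1] == 1

    def test_empty_input_all_missing(self):
        prof = dp_windows([], [])
        assert np.all(np.isnan(prof.mean))
        assert np.all(prof.n == 0)

    def test_bad_width_rejected(self):
        with pytest.raises(ValueError):
            dp_windows([2.0], [1.0], width=0.0)


class TestRanksum:
    def _profile(self, dps, values):
        return dp_windows(dps, values)

    def test_identical_distributions_p_one(self):
        dps = np.r_[np.full(20, 1.2), np.full(20, 2.2)]
        vals = np.r_[np.full(20, 5.0), np.full(20, 5.0)]
        p = window_ranksum_vs_first(self._profile(dps, vals))
        assert p[0] == 1.0
        assert p[10] == 1.0  # window [2.0, 2.5): same constant values

    def test_large_shift_tiny_p(self):
        rng = np.random.default_rng(0)
        dps = np.r_[np.full(50, 1.2), np.full(50, 3.6)]
        vals = np.r_[rng.standard_normal(50), rng.standard_normal(50) + 10]
        p = window_ranksum_vs_first(self._profile(dps, vals))
        # oracle: normal approximation of the rank-sum statistic for a
        # complete separation of two n=50 samples
        n1 = n2 = 50
        u = n1 * n2
        z = (u - n1 * n2 / 2) / np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
        p_oracle = 2 * sps.norm.sf(z)
        assert p_oracle < 1e-6
        assert np.nanmin(p[1:]) < 1e-6

    def test_empty_first_window_rejected(self):
        prof = self._profile(np.full(10, 3.0), np.arange(10.0))
        with pytest.raises(ValueError, match="first DP window"):
            window_ranksum_vs_first(prof)

    def test_single_member_window_left_missing(self):
        dps = np.r_[np.full(10, 1.2), [3.9]]
        vals = np.arange(11.0)
        p = window_ranksum_vs_first(self._profile(dps, vals))
        assert np.isnan(p[-1])


class TestBhFdr:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.2]), [0.2])

    def test_capped_at_one(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0]), [1.0, 1.0])

    def test_nan_passthrough(self):
        out = bh_fdr([0.01, np.nan, 0.02])
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2]], [0.02, 0.02])

    def test_adjusted_not_below_raw(self, rng):
        p = rng.uniform(0, 1, 40)
        assert np.all(bh_fdr(p) >= p - 1e-12)

    def test_order_invariance(self, rng):
        p = rng.uniform(0, 1, 25)
        perm = rng.permutation(25)
        np.testing.assert_allclose(bh_fdr(p)[perm], bh_fdr(p[perm]))

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(0, 1, 30)
        expected = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(bh_fdr(p), expected, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])


class TestGroupSummarize:
    def test_equal_values_give_equal_means(self):
        t = group_summarize([1.0] * 6,
                            ["optimal", "optimal", "sub_optimal",
                             "sub_optimal", "poor", "poor"],
                            ["s1"] * 6)
        np.testing.assert_allclose(t.loc["s1"].to_numpy(), 1.0)

    def test_missing_group_is_nan(self):
        t = group_summarize([1.0, 2.0, 3.0, 1.0, 2.0],
                            ["optimal", "sub_optimal", "poor",
                             "optimal", "sub_optimal"],
                            ["s1", "s1", "s1", "s2", "s2"])
        assert np.isnan(t.loc["s2", "poor"])
        assert t.loc["s1", "poor"] == 3.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            group_summarize([], [], [])

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown group"):
            group_summarize([1.0], ["great"], ["s1"])


class TestRmAnova:
    def _table(self, arr, n=None):
        arr = np.asarray(arr, dtype=float)
        return pd.DataFrame(arr, columns=["optimal", "sub_optimal", "poor"])

    def test_identical_values_degenerate(self):
        f, p = rm_anova(self._table(np.full((4, 3), 2.0)))
        assert f == 0.0 and p == 1.0

    def test_subject_offsets_without_condition_effect(self):
        # hand-checkable 3x3 toy: rows differ, columns identical
        f, p = rm_anova(self._table([[1, 1, 1], [5, 5, 5], [9, 9, 9]]))
        assert f == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_hand_computed_sums_of_squares(self):
        data = np.array([[1.0, 2.0, 3.0],
                         [2.0, 3.0, 5.0],
                         [0.0, 2.0, 4.0]])
        # direct SS decomposition
        grand = data.mean()
        ss_cond = 3 * ((data.mean(0) - grand) ** 2).sum()
        ss_subj = 3 * ((data.mean(1) - grand) ** 2).sum()
        ss_err = ((data - grand) ** 2).sum() - ss_cond - ss_subj
        f_expected = (ss_cond / 2) / (ss_err / 4)
        f, p = rm_anova(self._table(data))
        assert f == pytest.approx(f_expected)
        assert p == pytest.approx(sps.f.sf(f_expected, 2, 4))

    def test_matches_pingouin(self, rng):
        import pingouin as pg

        data = rng.standard_normal((8, 3)) + np.array([0.0, 0.5, 0.2])
        f, p = rm_anova(self._table(data))
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(8), 3),
            "cond": np.tile(["optimal", "sub_optimal", "poor"], 8),
            "value": data.ravel(),
        })
        ref = pg.rm_anova(data=long, dv="value", within="cond",
                          subject="subject")
        assert f == pytest.approx(float(ref["F"].iloc[0]), rel=1e-6)
        assert p == pytest.approx(float(ref["p_unc"].iloc[0]), rel=1e-6)

    def test_power_under_within_subject_shift(self, rng):
        # effect two error-SDs wide, 12 subjects: essentially always
        # detected
        hits = 0
        for _ in range(20):
            base = rng.standard_normal((12, 1)) * 2.0
            noise = rng.standard_normal((12, 3)) * 0.5
            effect = np.array([0.0, 1.0, 0.5])
            _, p = rm_anova(self._table(base + effect + noise))
            hits += p < 0.05
        assert hits >= 19

    def test_incomplete_subject_dropped(self, caplog):
        t = self._table([[1, 2, 3], [2, 3, 4], [1, np.nan, 3]])
        with caplog.at_level("WARNING"):
            rm_anova(t)
        assert any("dropped" in r.message for r in caplog.records)

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            rm_anova(self._table([[1, 2, 3]]))


class TestPairwiseSignedRank:
    def _table(self, arr):
        return pd.DataFrame(np.asarray(arr, dtype=float),
                            columns=["optimal", "sub_optimal", "poor"])

    def test_identical_groups_p_one(self):
        data = np.tile(np.arange(5.0)[:, None], (1, 3))
        out = pairwise_signed_rank(self._table(data))
        assert (out["p_raw"] == 1.0).all()

    def test_exact_floor_at_twelve_subjects(self):
        # a constant sign across 12 pairs: two-sided exact p = 2/2^12
        rng = np.random.default_rng(0)
        base = rng.standard_normal(12)
        data = np.column_stack([base, base + 1.0 + rng.random(12),
                                base + 3.0 + rng.random(12)])
        out = pairwise_signed_rank(self._table(data))
        assert out["p_raw"].min() == pytest.approx(2 / 4096)

    def test_bh_across_three_contrasts(self):
        np.testing.assert_allclose(bh_fdr([0.01, 1.0, 1.0]),
                                   [0.03, 1.0, 1.0])

    def test_too_few_pairs_rejected(self):
        t = self._table([[1, 2, np.nan], [2, 3, np.nan]])
        with pytest.raises(ValueError, match="fewer than 2"):
            pairwise_signed_rank(t)


def test_window_null_calibration(rng):
    """With no DP effect at all, the average fraction of windows
    flagged at FDR-adjusted p < 0.05 stays at or below 0.05."""
    fracs = []
    for _ in range(100):
        dps = rng.uniform(1, 4, 300)
        vals = rng.standard_normal(300)
        prof = apply_window_fdr(dp_windows(dps, vals), alpha=0.05)
        with np.errstate(invalid="ignore"):
            flags = prof.p_adj[1:] < 0.05
        fracs.append(np.mean(flags))
    assert np.mean(fracs) <= 0.05
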