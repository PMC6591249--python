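"""Effect-size and test-battery checks against independent oracles.

The Mann-Whitney oracle enumerates labelings directly; the Kruskal-Wallis
value is the hand computation from rank means; Holm-Sidak is checked
against statsmodels and against direct evaluation of its step thresholds;
balanced two-way ANOVA is checked against the classical closed-form
decomposition.
"""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from imequant import quantify, stats


def make_cohort(values, label="s", channel="mcherry"):
    return quantify.CohortMeasurements(
        strain_label=label,
        channel=channel,
        animals=[
            quantify.AnimalMeasurement(
                animal_id=f"{label}_{i}", mean_voxel_intensity=float(v),
                area_px=100, strain_label=label, channel=channel,
            )
            for i, v in enumerate(values)
        ],
    )


def exact_mw_pvalue(a, b):
    """Enumerate every assignment of the pooled values to the two groups and
    count assignments with |U - n_a n_b / 2| at least as extreme."""
    pooled = np.concatenate([a, b])
    n_a = len(a)
    ranks = {v: r for r, v in enumerate(np.sort(pooled), start=1)}

    def u_stat(group_a_idx):
        ra = sum(ranks[pooled[i]] for i in group_a_idx)
        return ra - n_a * (n_a + 1) / 2

    u_obs = u_stat(range(n_a))
    mid = n_a * (len(pooled) - n_a) / 2
    count = total = 0
    for idx in combinations(range(len(pooled)), n_a):
        total += 1
        if abs(u_stat(idx) - mid) >= abs(u_obs - mid) - 1e-9:
            count += 1
    return count / total


class TestBaselineAndCorrection:
    def test_baseline_is_arithmetic_mean(self):
        assert stats.autofluorescence_baseline(make_cohort([10, 20, 30])) == 20.0

    def test_mixed_channels_rejected(self):
        cohort = make_cohort([1, 2])
        cohort.animals[1] = quantify.AnimalMeasurement(
            "x", 2.0, 100, "s", "megfp"
        )
        with pytest.raises(ValueError, match="channels"):
            stats.autofluorescence_baseline(cohort)

    def test_self_centering(self):
        cohort = make_cohort([5.0, 15.0, 25.0])
        baseline = stats.autofluorescence_baseline(cohort)
        assert stats.background_correct(cohort, baseline).mean() == pytest.approx(0.0)

    def test_subtraction_preserves_negatives(self):
        corrected = stats.background_correct(make_cohort([100, 120]), 110.0)
        np.testing.assert_allclose(corrected, [-10.0, 10.0])

    def test_channel_mismatch_rejected(self):
        with pytest.raises(ValueError, match="channel"):
            stats.background_correct(make_cohort([1, 2]), 0.0, baseline_channel="megfp")


class TestEffectSize:
    def test_constant_groups_give_exact_percent_and_zero_width_ci(self):
        res = stats.effect_size([100.0] * 5, [150.0] * 5, n_boot=200, seed=0)
        assert res.percent_increase == pytest.approx(50.0)
        assert res.ci_low == pytest.approx(50.0)
        assert res.ci_high == pytest.approx(50.0)

    def test_nonpositive_control_mean_rejected(self):
        with pytest.raises(ValueError, match="control mean"):
            stats.effect_size([-1.0, 1.0], [5.0, 6.0])

    def test_ci_brackets_point_estimate(self, rng):
        a = rng.lognormal(0, 0.3, 50)
        b = 1.4 * rng.lognormal(0, 0.3, 50)
        res = stats.effect_size(a, b, n_boot=2000, seed=1)
        assert res.ci_low <= res.percent_increase <= res.ci_high

    def test_scale_invariant_not_shift_invariant(self, rng):
        a = rng.lognormal(0, 0.2, 40) + 1
        b = rng.lognormal(0.4, 0.2, 40) + 1
        base = stats.effect_size(a, b, n_boot=100, seed=2).percent_increase
        scaled = stats.effect_size(3 * a, 3 * b, n_boot=100, seed=2).percent_increase
        shifted = stats.effect_size(a + 5, b + 5, n_boot=100, seed=2).percent_increase
        assert scaled == pytest.approx(base, rel=1e-12)
        assert shifted != pytest.approx(base, rel=1e-3)


class TestMannWhitney:
    def test_exact_separated_groups(self):
        res = stats.mann_whitney_test([1, 2, 3], [4, 5, 6], mode="exact")
        assert res.statistic_value == 0.0
        assert res.p_value == pytest.approx(0.1)

    def test_identical_groups_symmetric(self):
        a = [1.0, 2.0, 3.0, 4.0]
        res = stats.mann_whitney_test(a, list(a), mode="approx")
        assert res.statistic_value == pytest.approx(len(a) ** 2 / 2)
        assert res.p_value >= 0.99

    def test_exact_with_ties_rejected(self):
        with pytest.raises(ValueError, match="tie"):
            stats.mann_whitney_test([1, 2, 2], [3, 4, 5], mode="exact")

    @pytest.mark.parametrize("seed", range(5))
    def test_exact_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.permutation(20)[:5].astype(float)
        b = np.setdiff1d(np.arange(20), a)[:5].astype(float)
        res = stats.mann_whitney_test(a, b, mode="exact")
        assert res.p_value == pytest.approx(exact_mw_pvalue(a, b), abs=1e-9)

    def test_monotone_transform_invariance(self, rng):
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.8, 1, 12)
        p0 = stats.mann_whitney_test(a, b).p_value
        assert stats.mann_whitney_test(np.exp(a), np.exp(b)).p_value == pytest.approx(p0)
        assert stats.mann_whitney_test(3 * a + 7, 3 * b + 7).p_value == pytest.approx(p0)


class TestKruskalWallis:
    def test_all_tied_limiting_convention(self):
        res = stats.kruskal_wallis_test([[5.0, 5.0], [5.0, 5.0], [5.0]])
        assert res.statistic_value == 0.0 and res.p_value == 1.0

    def test_hand_computed_h(self):
        res = stats.kruskal_wallis_test([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert res.statistic_value == pytest.approx(7.2)

    def test_two_group_h_is_squared_mw_z(self, rng):
        # without ties, two-group H equals (U - n1 n2/2)^2 / (n1 n2 (N+1)/12)
        perm = rng.permutation(100).astype(float)
        a, b = perm[:8], perm[8:16]
        u = stats.mann_whitney_test(a, b).statistic_value
        n1, n2 = len(a), len(b)
        expected_h = (u - n1 * n2 / 2) ** 2 / (n1 * n2 * (n1 + n2 + 1) / 12)
        h = stats.kruskal_wallis_test([a, b]).statistic_value
        assert h == pytest.approx(expected_h)

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            stats.kruskal_wallis_test([[1.0, 2.0]])


class TestDunnVsControl:
    def test_group_identical_to_control(self):
        res = stats.dunn_vs_control([[3.0] * 5, [3.0] * 5, [1.0, 2.0, 4.0, 5.0, 6.0]])
        assert res[0].statistic_value == pytest.approx(0.0)
        assert res[0].p_value == 1.0

    def test_single_comparison_unadjusted(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(1, 1, 10)
        adj = stats.dunn_vs_control([a, b])[0]
        z = adj.statistic_value
        from scipy.stats import norm

        assert adj.p_value == pytest.approx(min(1.0, 2 * norm.sf(abs(z))))

    def test_adjusted_p_at_least_unadjusted(self, rng):
        groups = [rng.normal(i * 0.3, 1, 12) for i in range(4)]
        from scipy.stats import norm

        for r in stats.dunn_vs_control(groups):
            raw = 2 * norm.sf(abs(r.statistic_value))
            assert raw <= r.p_value <= 1.0
            assert r.adjusted

    def test_invalid_control_index(self):
        with pytest.raises(ValueError):
            stats.dunn_vs_control([[1.0], [2.0]], control_index=5)


def classical_balanced_anova(y, fa, fb):
    """Closed-form balanced two-way ANOVA decomposition (oracle)."""
    y = np.asarray(y, float)
    a_levels, b_levels = sorted(set(fa)), sorted(set(fb))
    grand = y.mean()
    n = len(y)
    r = n / (len(a_levels) * len(b_levels))
    ss_a = sum((y[fa == a].mean() - grand) ** 2 * (y[fa == a]).size for a in a_levels)
    ss_b = sum((y[fb == b].mean() - grand) ** 2 * (y[fb == b]).size for b in b_levels)
    ss_cells = sum(
        ((sel := (fa == a) & (fb == b)), r * (y[sel].mean() - grand) ** 2)[1]
        for a in a_levels for b in b_levels
    )
    ss_ab = ss_cells - ss_a - ss_b
    ss_err = sum(
        ((y[(fa == a) & (fb == b)] - y[(fa == a) & (fb == b)].mean()) ** 2).sum()
        for a in a_levels for b in b_levels
    )
    df_a, df_b = len(a_levels) - 1, len(b_levels) - 1
    df_ab = df_a * df_b
    df_err = n - len(a_levels) * len(b_levels)
    return {
        "A": (ss_a / df_a) / (ss_err / df_err),
        "B": (ss_b / df_b) / (ss_err / df_err),
        "A:B": (ss_ab / df_ab) / (ss_err / df_err),
    }


class TestTwoWayAnova:
    def _balanced_data(self, rng, interaction=0.0):
        fa, fb, y = [], [], []
        effects_a = {"no_intron": 0.0, "introns": 2.0}
        effects_b = {"mcherry": 0.0, "megfp": 1.0}
        for a, ea in effects_a.items():
            for b, eb in effects_b.items():
                inter = interaction if (a == "introns" and b == "megfp") else 0.0
                for _ in range(6):
                    fa.append(a)
                    fb.append(b)
                    y.append(10 + ea + eb + inter + rng.normal(0, 1))
        return np.array(y), np.array(fa), np.array(fb)

    def test_exactly_additive_cells_zero_interaction(self):
        # cell means exactly additive; symmetric within-cell deviations keep
        # the residual df positive while the interaction SS stays exactly 0
        fa = np.array(["a1"] * 8 + ["a2"] * 8)
        fb = np.array((["b1"] * 4 + ["b2"] * 4) * 2)
        cell_mean = {("a1", "b1"): 10.0, ("a1", "b2"): 12.0,
                     ("a2", "b1"): 15.0, ("a2", "b2"): 17.0}
        deviations = [1.0, -1.0, 2.0, -2.0] * 4
        y = np.array([cell_mean[(a, b)] + d
                      for (a, b), d in zip(zip(fa, fb), deviations)])
        res = stats.two_way_anova(y, fa, fb)
        assert res["A:B"].statistic_value == pytest.approx(0.0, abs=1e-10)

    def test_balanced_matches_classical_oracle(self, rng):
        y, fa, fb = self._balanced_data(rng, interaction=1.5)
        res = stats.two_way_anova(y, fa, fb)
        oracle = classical_balanced_anova(y, fa, fb)
        for term in ("A", "B", "A:B"):
            assert res[term].statistic_value == pytest.approx(oracle[term], rel=1e-8)

    def test_empty_cell_rejected(self):
        y = [1.0, 2.0, 3.0, 4.0]
        fa = ["a1", "a1", "a2", "a2"]
        fb = ["b1", "b1", "b1", "b2"]  # (a1, b2) empty
        with pytest.raises(ValueError, match="cell"):
            stats.two_way_anova(y, fa, fb)


class TestHolmSidak:
    def test_single_p_unchanged(self):
        reject, adj = stats.holm_sidak_adjust([0.03])
        assert adj[0] == pytest.approx(0.03)
        assert reject[0]

    def test_all_ones_nothing_rejected(self):
        reject, adj = stats.holm_sidak_adjust([1.0, 1.0, 1.0])
        assert not reject.any()
        assert np.all(adj == 1.0)

    def test_worked_example_step_thresholds(self):
        # thresholds 1-0.95^(1/3)=0.01695, 1-0.95^(1/2)=0.02532, 0.05:
        # 0.01 passes step 1, 0.03 fails step 2, procedure stops
        reject, adj = stats.holm_sidak_adjust([0.01, 0.03, 0.04], alpha=0.05)
        np.testing.assert_array_equal(reject, [True, False, False])
        assert adj[0] == pytest.approx(1 - 0.99**3)
        assert adj[1] == pytest.approx(max(1 - 0.99**3, 1 - 0.97**2))

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(0, 1, 9)
        reject, adj = stats.holm_sidak_adjust(p, alpha=0.05)
        sm_reject, sm_adj, _, _ = multipletests(p, alpha=0.05, method="holm-sidak")
        np.testing.assert_allclose(adj, sm_adj, atol=1e-12)
        np.testing.assert_array_equal(reject, sm_reject)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=12))
    def test_adjusted_at_least_raw_and_bounded(self, pvals):
        reject, adj = stats.holm_sidak_adjust(pvals)
        p = np.asarray(pvals)
        assert np.all(adj >= p - 1e-12)
        assert np.all(adj <= 1.0)
        # monotone in rank: sorting p sorts adj the same way
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            stats.holm_sidak_adjust([0.5, 1.2])
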