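"""Block summaries, percent comparisons, and the nonparametric test battery.

The rank tests are checked against independent brute-force oracles: the
Mann-Whitney U via direct pair counting with its exact distribution
enumerated over group assignments, and the Kruskal-Wallis H via hand rank
arithmetic with midranks and the tie correction.
"""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from normpgg import (
    HUMAN_BLOCK_MEANS,
    ValidationError,
    block_means,
    earnings_summary,
    kruskal_wallis,
    mann_whitney,
    percent_excess,
    percent_excess_exact,
    punishment_frequency,
    punishment_intensity,
    wilcoxon_signed_rank,
)


def make_panel(rows):
    """rows: (treatment, rep, group, round, agent, contribution, detail, final)"""
    return pd.DataFrame(
        rows,
        columns=[
            "treatment",
            "replication",
            "group",
            "round",
            "agent",
            "contribution",
            "points_detail",
            "final_payoff",
        ],
    )


def uniform_panel(contribution, final, detail="", treatment="t", groups=(0,)):
    rows = []
    for g in groups:
        for rnd in range(1, 31):
            for agent in range(4):
                d = detail if (agent == 0 and 11 <= rnd <= 20) else ""
                rows.append(
                    (treatment, 0, g, rnd, agent, contribution, d, final)
                )
    return make_panel(rows)


class TestBlockMeans:
    def test_all_cooperate_panel(self):
        panel = uniform_panel(20, 32.0)
        out = block_means(panel, ["1-10", "11-20", "21-30"])
        assert (out.mean_contribution == 20).all()

    def test_two_groups_average_of_group_means(self):
        a = uniform_panel(4, 20.0, groups=(0,))
        b = uniform_panel(6, 20.0, groups=(1,))
        out = block_means(pd.concat([a, b]), ["1-10"])
        assert out.mean_contribution.iloc[0] == pytest.approx(5.0)

    def test_human_fixture_block_16_20(self):
        out = block_means(HUMAN_BLOCK_MEANS, ["16-20"]).set_index("treatment")
        assert out.loc["message", "mean_contribution"] == 9.90
        assert out.loc["punishment", "mean_contribution"] == 10.65
        assert out.loc["sanction", "mean_contribution"] == 14.46

    def test_empty_block_rejected(self):
        with pytest.raises(ValidationError):
            block_means(uniform_panel(0, 20.0), ["31-40"])


class TestFrequencyIntensity:
    def test_no_punishment_zero_frequency(self):
        assert punishment_frequency(uniform_panel(0, 20.0), "11-20") == 0.0

    def test_one_of_twelve_opportunities(self):
        rows = [("t", 0, 0, 11, a, 0, "1:5" if a == 0 else "", 20.0) for a in range(4)]
        assert punishment_frequency(make_panel(rows), "11-20") == pytest.approx(1 / 12)

    def test_intensity_mean_of_nonzero_acts(self):
        rows = [("t", 0, 0, 11, a, 0, "", 20.0) for a in range(4)]
        rows[0] = ("t", 0, 0, 11, 0, 0, "1:2;2:4", 20.0)
        assert punishment_intensity(make_panel(rows), "11-20") == pytest.approx(3.0)

    def test_single_act(self):
        rows = [("t", 0, 0, 11, a, 0, "2:10" if a == 0 else "", 20.0) for a in range(4)]
        assert punishment_intensity(make_panel(rows), "11-20") == 10.0

    def test_all_zero_acts_explicitly_undefined(self):
        assert punishment_intensity(uniform_panel(0, 20.0), "11-20") is None

    def test_uniform_low_point_acts_give_intensity_low(self):
        panel = uniform_panel(0, 20.0, detail="1:5")
        assert punishment_intensity(panel, "11-20") == 5.0
        assert 0 < punishment_frequency(panel, "11-20") < 1


class TestPercentExcess:
    @pytest.mark.parametrize(
        "a, b, expected", [(14.46, 10.65, 36), (9.08, 3.75, 142), (7.7, 7.7, 0)]
    )
    def test_examples(self, a, b, expected):
        assert percent_excess(a, b) == expected

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValidationError):
            percent_excess(1.0, 0.0)

    def test_reciprocal_algebra_prerounding(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            a, b = rng.uniform(0.5, 30, size=2)
            fwd = percent_excess_exact(a, b)
            rev = percent_excess_exact(b, a)
            assert (1 + fwd / 100) * (1 + rev / 100) == pytest.approx(1.0)


# --------------------------------------------------------------------------
# independent oracles


def mw_u_oracle(x, y):
    """U by direct pair counting (ties count one half)."""
    return sum(
        1.0 if xi > yi else 0.5 if xi == yi else 0.0 for xi in x for yi in y
    )


def mw_exact_p_oracle(x, y):
    pooled = list(x) + list(y)
    nx, n = len(x), len(x) + len(y)
    u_obs = mw_u_oracle(x, y)
    mu = nx * len(y) / 2
    extreme = total = 0
    for idx in combinations(range(n), nx):
        rest = [i for i in range(n) if i not in idx]
        u = mw_u_oracle([pooled[i] for i in idx], [pooled[i] for i in rest])
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            extreme += 1
    return extreme / total


def kw_h_oracle(*samples):
    """Tie-corrected H by hand rank arithmetic."""
    pooled = np.concatenate([np.asarray(s, float) for s in samples])
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(len(pooled))
    i = 0
    sorted_vals = pooled[order]
    while i < len(pooled):
        j = i
        while j < len(pooled) and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2  # midrank of the tied run
        i = j
    n_total = len(pooled)
    h = 0.0
    start = 0
    for s in samples:
        r = ranks[start : start + len(s)]
        h += r.sum() ** 2 / len(s)
        start += len(s)
    h = 12 / (n_total * (n_total + 1)) * h - 3 * (n_total + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1 - (counts**3 - counts).sum() / (n_total**3 - n_total)
    return h / correction


class TestRankTestsAgainstOracles:
    def test_mw_all_y_exceed_all_x(self):
        res = mann_whitney([1, 2], [3, 4])
        assert res.statistic == 0.0
        # enumeration over the 6 assignments: only U in {0, 4} are as extreme
        assert res.pvalue == pytest.approx(2 / 6)

    def test_mw_identical_samples_full_tie(self):
        x = [1.0, 2.0, 3.0]
        res = mann_whitney(x, x)
        assert res.statistic == pytest.approx(len(x) ** 2 / 2)
        assert res.pvalue == 1.0

    def test_mw_swap_symmetry(self):
        rng = np.random.default_rng(5)
        x, y = rng.integers(0, 6, size=4).tolist(), rng.integers(0, 6, size=3).tolist()
        u_xy = mann_whitney(x, y).statistic
        u_yx = mann_whitney(y, x).statistic
        assert u_xy + u_yx == len(x) * len(y)

    @pytest.mark.parametrize("nx, ny", [(a, b) for a in range(1, 5) for b in range(1, 5)])
    def test_mw_matches_enumeration_oracle_with_ties(self, nx, ny):
        rng = np.random.default_rng(nx * 10 + ny)
        for _ in range(10):
            x = rng.integers(0, 4, size=nx).tolist()  # small support forces ties
            y = rng.integers(0, 4, size=ny).tolist()
            res = mann_whitney(x, y)
            assert res.statistic == pytest.approx(mw_u_oracle(x, y))
            assert res.pvalue == pytest.approx(mw_exact_p_oracle(x, y))

    def test_mw_large_sample_matches_scipy(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=30), rng.normal(0.5, size=25)
        res = mann_whitney(x, y)
        ref = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert res.statistic == pytest.approx(float(ref.statistic))
        assert res.pvalue == pytest.approx(float(ref.pvalue))

    def test_kw_identical_samples_h_zero(self):
        res = kruskal_wallis([2, 2, 2], [2, 2], [2, 2, 2, 2])
        assert res.statistic == 0.0

    def test_kw_separated_samples_match_hand_rank_oracle(self):
        samples = ([1, 2, 3], [4, 5, 6], [7, 8, 9])
        res = kruskal_wallis(*samples)
        assert res.statistic == pytest.approx(kw_h_oracle(*samples))

    @pytest.mark.parametrize(
        "shape", [(2, 2), (3, 3), (2, 3, 2), (3, 3, 3), (4, 2, 3)]
    )
    def test_kw_matches_oracle_on_small_shapes_with_ties(self, shape):
        rng = np.random.default_rng(sum(shape))
        for _ in range(10):
            samples = [rng.integers(0, 4, size=k).tolist() for k in shape]
            if len(set(np.concatenate(samples).tolist())) == 1:
                continue
            res = kruskal_wallis(*samples)
            assert res.statistic == pytest.approx(kw_h_oracle(*samples))

    def test_kw_label_permutation_invariance(self):
        a, b, c = [1, 4, 2], [3, 3, 5], [6, 0, 2]
        assert kruskal_wallis(a, b, c).statistic == pytest.approx(
            kruskal_wallis(c, a, b).statistic
        )

    def test_kw_needs_two_nonempty_groups(self):
        with pytest.raises(ValidationError):
            kruskal_wallis([1, 2, 3])
        with pytest.raises(ValidationError):
            kruskal_wallis([1, 2], [])


class TestWilcoxon:
    def test_shifted_pairs_one_sided_exact(self):
        x = np.arange(6.0)
        res = wilcoxon_signed_rank(x, x + 1.0, alternative="less")
        assert res.statistic == 0.0
        assert res.pvalue == pytest.approx(1 / 64)

    def test_degenerate_all_zero_differences(self):
        x = np.ones(5)
        res = wilcoxon_signed_rank(x, x)
        assert res.degenerate and res.pvalue == 1.0

    def test_sign_flip_leaves_statistic_unchanged(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=8), rng.normal(size=8)
        assert wilcoxon_signed_rank(x, y).statistic == pytest.approx(
            wilcoxon_signed_rank(y, x).statistic
        )

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(size=9), rng.normal(size=9)
        res = wilcoxon_signed_rank(x, y)
        ref = scipy.stats.wilcoxon(x, y, method="exact")
        assert res.statistic == pytest.approx(float(ref.statistic))
        assert res.pvalue == pytest.approx(float(ref.pvalue))

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValidationError):
            wilcoxon_signed_rank([1, 2], [1, 2, 3])


class TestEarnings:
    def test_all_defect_no_punishment(self):
        out = earnings_summary(uniform_panel(0, 20.0), ["1-10"])
        assert out.mean_net_earnings.iloc[0] == pytest.approx(20.0)

    def test_all_cooperate_no_punishment(self):
        out = earnings_summary(uniform_panel(20, 32.0), ["1-10"])
        assert out.mean_net_earnings.iloc[0] == pytest.approx(32.0)

    def test_punishment_strictly_lowers_group_mean(self, small_run):
        _, res = small_run
        p = res.rounds[res.rounds.treatment == "sanction"].copy()
        punished = p[(p["round"].between(11, 20))]
        if punished.points_received.sum() > 0:
            unpunished_mean = punished.stage1_payoff.mean()
            assert punished.final_payoff.mean() < unpunished_mean
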