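import dataclasses
import math

import numpy as np
import pytest
from scipy import stats as sps

from artfeat.errors import ParameterError, PreconditionError
from artfeat.features import ArticulatoryFeatures
from artfeat.records import ParticipantRecord
from artfeat.stats import (
    anova_from_summary,
    chi_square_independence,
    descriptive_stats,
    fisher_lsd_posthoc,
    kruskal_wallis,
    one_way_anova,
    pearson_correlations,
    presence_percentages,
    split_by_viq,
    tukey_posthoc,
)
from artfeat.synth import null_profiles, simulate_records


def _record(id, group, viq, poa=0, **scores):
    feats = ArticulatoryFeatures(
        sr_area=100, ft_area=10, poa_area=poa, total_area=110 + poa,
        presence={"SR": True, "FT": True, "POA": poa > 0},
    )
    scores.setdefault("mullen_rl", viq)
    scores.setdefault("mullen_el", viq)
    return ParticipantRecord(id=id, group=group, scores=scores, features=feats)


class TestKruskalWallis:
    def test_identical_values_give_h_zero(self):
        res = kruskal_wallis({"a": [3, 3, 3], "b": [3, 3], "c": [3, 3, 3]})
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_matches_rank_formula_oracle(self):
        groups = {"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]}
        res = kruskal_wallis(groups)
        # H = 12/(N(N+1)) * sum R_i^2/n_i - 3(N+1), ranks 1..9 without ties
        assert res.statistic == pytest.approx(7.2)
        assert res.df == (2,)

    def test_null_distribution_is_chi_square(self):
        rng = np.random.default_rng(0)
        hs = []
        for _ in range(400):
            x = rng.standard_normal(60)
            hs.append(
                kruskal_wallis({"a": x[:20], "b": x[20:40], "c": x[40:]}).statistic
            )
        # mean of chi2(2) is 2; K-S against chi2(2) should not reject hard
        stat, p = sps.kstest(hs, sps.chi2(2).cdf)
        assert p > 0.01

    def test_degenerate_groups_rejected(self):
        with pytest.raises(PreconditionError):
            kruskal_wallis({"a": [1.0], "b": [2.0, 3.0]})


class TestAnova:
    def test_equal_means_give_f_zero(self):
        res = one_way_anova({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert res.statistic == pytest.approx(0.0)

    def test_matches_hand_computed_sums_of_squares(self):
        groups = {"a": [2.0, 4.0], "b": [6.0, 8.0], "c": [10.0, 12.0]}
        # grand mean 7; SSB = 2*(16+0+16)=64; SSW = 6*... each group var 2
        ssb = 2 * ((3 - 7) ** 2 + 0 + (11 - 7) ** 2)
        ssw = sum((x - np.mean(v)) ** 2 for v in groups.values() for x in v)
        f = (ssb / 2) / (ssw / 3)
        res = one_way_anova(groups)
        assert res.statistic == pytest.approx(f)
        assert res.df == (2, 3)

    def test_two_groups_equals_t_squared(self):
        rng = np.random.default_rng(1)
        a, b = rng.standard_normal(12), rng.standard_normal(9) + 0.8
        res = one_way_anova({"a": a, "b": b})
        t, p = sps.ttest_ind(a, b)
        assert res.statistic == pytest.approx(t**2)
        assert res.p_value == pytest.approx(p)

    def test_zero_within_variance_flagged(self):
        res = one_way_anova({"a": [5.0, 5.0], "b": [5.0, 5.0]})
        assert math.isnan(res.statistic)
        assert "undefined" in res.note


class TestAnovaFromSummary:
    def test_equal_means_give_zero(self):
        res = anova_from_summary([5, 5, 5], [1, 2, 1], [10, 10, 10])
        assert res.statistic == pytest.approx(0.0)

    def test_equivalent_to_raw_anova_on_matching_data(self):
        # three values per group mean +- sd have exactly that mean and SD
        groups = {
            g: [m - s, m, m + s]
            for g, (m, s) in {"a": (10.0, 2.0), "b": (14.0, 1.0), "c": (9.0, 3.0)}.items()
        }
        raw = one_way_anova(groups)
        summ = anova_from_summary([10, 14, 9], [2, 1, 3], [3, 3, 3])
        assert summ.statistic == pytest.approx(raw.statistic)
        assert summ.p_value == pytest.approx(raw.p_value)
        assert summ.df == raw.df

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ParameterError):
            anova_from_summary([1, 2], [1, 0], [5, 5])
        with pytest.raises(ParameterError):
            anova_from_summary([1, 2], [1, 1], [5, 1])


class TestChiSquare:
    def test_perfectly_dependent_2x2(self):
        res = chi_square_independence([[10, 0], [0, 10]])
        assert res.statistic == pytest.approx(20.0)
        assert res.df == (1.0,)

    def test_independent_table_gives_zero(self):
        res = chi_square_independence([[10, 20], [20, 40]])
        assert res.statistic == pytest.approx(0.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ParameterError):
            chi_square_independence([[0, 0], [5, 5]])


class TestPosthoc:
    def test_tukey_identical_groups_not_significant(self):
        res = tukey_posthoc({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert not res[0].significant
        assert res[0].p_value > 0.9

    def test_tukey_two_groups_equals_t_test(self):
        rng = np.random.default_rng(2)
        a, b = rng.standard_normal(10), rng.standard_normal(10) + 1.0
        res = tukey_posthoc({"a": a, "b": b})
        _, p = sps.ttest_ind(a, b)
        assert res[0].p_value == pytest.approx(p, rel=1e-6)

    def test_tukey_p_ordering_follows_mean_gaps(self):
        groups = {
            "a": [0.0, 0.1, -0.1, 0.05],
            "b": [1.0, 1.1, 0.9, 1.05],
            "c": [5.0, 5.1, 4.9, 5.05],
        }
        res = {r.pair: r.p_value for r in tukey_posthoc(groups)}
        assert res[("a", "c")] < res[("a", "b")]
        assert res[("b", "c")] < res[("a", "b")]

    def test_ranked_variant_flagged(self):
        res = tukey_posthoc(
            {"a": [1, 2, 3], "b": [4, 5, 6]}, ranked=True
        )
        assert "rank" in res[0].note

    def test_lsd_matches_pooled_t_oracle(self):
        groups = {"a": [2.0, 4.0, 6.0], "b": [8.0, 10.0, 12.0], "c": [3.0, 5.0, 7.0]}
        res = fisher_lsd_posthoc(groups, require_omnibus=False)
        arrs = {k: np.array(v) for k, v in groups.items()}
        msw = sum(((v - v.mean()) ** 2).sum() for v in arrs.values()) / 6
        for pr in res:
            i, j = pr.pair
            t = (arrs[i].mean() - arrs[j].mean()) / math.sqrt(msw * (2 / 3))
            assert pr.statistic == pytest.approx(t)

    def test_lsd_suppressed_without_omnibus(self):
        rng = np.random.default_rng(3)
        groups = {k: rng.standard_normal(8) for k in "abc"}
        res = fisher_lsd_posthoc(groups)
        assert all(not pr.significant for pr in res)
        assert any("suppressed" in pr.note for pr in res)

    def test_lsd_identical_groups_nothing_significant(self):
        res = fisher_lsd_posthoc(
            {"a": [1.0, 2.0], "b": [1.0, 2.0]}, require_omnibus=False
        )
        assert not any(pr.significant for pr in res)


class TestCorrelations:
    def test_perfect_positive_and_negative(self):
        recs = [
            _record(f"A{i}", "ASD", viq=30, poa=i, vabs_rl=float(i), vabs_el=float(-i))
            for i in range(8)
        ]
        tabs = pearson_correlations(recs, ["poa_area"], ["vabs_rl", "vabs_el"])
        r_pos = tabs["ASD"].loc["poa_area", "vabs_rl"]
        r_neg = tabs["ASD"].loc["poa_area", "vabs_el"]
        assert r_pos[0] == pytest.approx(1.0)
        assert r_pos[2] == "**"
        assert r_neg[0] == pytest.approx(-1.0)

    def test_constant_column_flagged_nan(self):
        recs = [
            _record(f"A{i}", "ASD", viq=30, poa=5, vabs_rl=float(i))
            for i in range(6)
        ]
        tabs = pearson_correlations(recs, ["poa_area"], ["vabs_rl"])
        assert math.isnan(tabs["ASD"].loc["poa_area", "vabs_rl"][0])


class TestViqSplit:
    def test_partition_matches_bruteforce(self):
        rng = np.random.default_rng(4)
        recs = [
            _record(f"A{i}", "ASD", viq=float(v))
            for i, v in enumerate(rng.uniform(20, 56, 30))
        ]
        high, low = split_by_viq(recs)
        cutoff = np.mean([r.viq for r in recs])
        assert {r.id for r in high} == {r.id for r in recs if r.viq > cutoff}
        assert {r.id for r in low} == {r.id for r in recs if r.viq <= cutoff}
        assert len(high) + len(low) == 30

    def test_explicit_cutoff_and_boundary_goes_low(self):
        recs = [_record("A1", "ASD", viq=44.0), _record("A2", "ASD", viq=50.0)]
        high, low = split_by_viq(recs, cutoff=44.0)
        assert [r.id for r in low] == ["A1"]
        assert [r.id for r in high] == ["A2"]

    def test_all_above_cutoff_warns(self):
        recs = [_record(f"A{i}", "ASD", viq=50.0 + i) for i in range(3)]
        with pytest.warns(UserWarning, match="low-VIQ"):
            split_by_viq(recs, cutoff=10.0)

    def test_non_asd_records_ignored(self):
        recs = [_record("T1", "TD", viq=55.0)]
        with pytest.raises(PreconditionError):
            split_by_viq(recs)


class TestDescriptives:
    def test_basic_values(self):
        d = descriptive_stats([1.0, 2.0, 3.0])
        assert d["mean"] == pytest.approx(2.0)
        assert d["sd"] == pytest.approx(1.0)
        assert d["range"] == pytest.approx(2.0)
        assert d["sem"] == pytest.approx(1.0 / math.sqrt(3))

    def test_ci_halfwidth_matches_t_oracle(self):
        rng = np.random.default_rng(5)
        v = rng.standard_normal(24)
        d = descriptive_stats(v)
        expected = sps.t.ppf(0.975, 23) * v.std(ddof=1) / math.sqrt(24)
        assert d["ci95_halfwidth"] == pytest.approx(expected)

    def test_normality_flag(self):
        rng = np.random.default_rng(6)
        assert descriptive_stats(rng.standard_normal(200))["normal"]
        assert not descriptive_stats(rng.lognormal(0, 1.5, 200))["normal"]

    def test_too_few_values_rejected(self):
        with pytest.raises(PreconditionError):
            descriptive_stats([1.0])


class TestPresence:
    def test_hand_counted_percentages(self):
        recs = [
            _record("A1", "ASD", 30, poa=5),
            _record("A2", "ASD", 30, poa=0),
            _record("T1", "TD", 55, poa=0),
            _record("T2", "TD", 55, poa=0),
        ]
        frame = presence_percentages(recs)
        assert frame.loc["ASD", "POA"] == pytest.approx(50.0)
        assert frame.loc["TD", "POA"] == pytest.approx(0.0)
        assert frame.loc["ASD", "SR"] == pytest.approx(100.0)

    def test_surrogate_cohort_sr_always_present(self):
        recs = simulate_records(null_profiles((10, 10, 10)), seed=7)
        frame = presence_percentages(recs)
        assert (frame["SR"] == 100.0).all()
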