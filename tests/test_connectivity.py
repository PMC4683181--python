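"""Connectivity indexes, control normalization and the statistical battery."""

import math

import numpy as np
import pytest
from scipy import stats

from polyxnet import (
    ConnectivityModel,
    Interactome,
    analyze_all_groups,
    connectivity_for_group,
    dunnett_posthoc,
    extract_group_network,
    generate_interactome,
    normalize_against_controls,
    one_way_anova,
    pearson_correlation,
    per_node_index,
    proportion_index,
    sample_control_groups,
    yates_chi2_test,
)
from polyxnet.connectivity import UndefinedIndexError
from polyxnet.repeats import PolyXGroup

from .conftest import make_interactome


class TestSampleControlGroups:
    def test_deterministic_and_sized(self):
        universe = [f"P{i}" for i in range(10)]
        a = sample_control_groups(universe, 3, n_controls=5, seed=7)
        b = sample_control_groups(universe, 3, n_controls=5, seed=7)
        assert a == b
        assert all(len(s) == 3 for s in a)
        assert len(a) == 5

    def test_different_seed_differs(self):
        universe = [f"P{i}" for i in range(30)]
        assert sample_control_groups(universe, 5, seed=1) != sample_control_groups(
            universe, 5, seed=2
        )

    def test_size_equals_universe(self):
        universe = list("ABCDE")
        for s in sample_control_groups(universe, 5, n_controls=3, seed=0):
            assert s == frozenset(universe)

    def test_size_exceeding_universe_rejected(self):
        with pytest.raises(ValueError):
            sample_control_groups(list("ABCDE"), 6, seed=0)


class TestIndexes:
    def test_proportion_toy(self, toy_group_network):
        assert proportion_index(toy_group_network) == pytest.approx(0.25)

    def test_proportion_boundaries(self):
        only_a = extract_group_network(make_interactome([("A", "B")]), {"A", "B"})
        assert proportion_index(only_a) == 1.0
        only_b = extract_group_network(make_interactome([("A", "X")]), {"A"})
        assert proportion_index(only_b) == 0.0

    def test_proportion_undefined_without_interactions(self):
        gn = extract_group_network(make_interactome([("X", "Y")]), {"A"})
        with pytest.raises(UndefinedIndexError):
            proportion_index(gn)

    def test_per_node_toy(self, toy_group_network):
        assert per_node_index(toy_group_network) == pytest.approx(2 / 3)

    def test_per_node_no_type_a(self):
        gn = extract_group_network(make_interactome([("A", "X")]), {"A"})
        assert per_node_index(gn) == 0.0

    @pytest.mark.parametrize("g", [3, 5, 8])
    def test_per_node_complete_graph(self, g):
        nodes = [f"N{i}" for i in range(g)]
        inter = make_interactome(
            [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1 :]]
        )
        gn = extract_group_network(inter, nodes)
        assert per_node_index(gn) == pytest.approx(g - 1)

    def test_per_node_denominators(self, toy_group_network):
        assert per_node_index(toy_group_network, "typea_nodes") == pytest.approx(1.0)
        assert per_node_index(toy_group_network, "all_members") == pytest.approx(2 / 3)
        with pytest.raises(ValueError):
            per_node_index(toy_group_network, "bogus")

    def test_indexes_invariant_to_outside_edges(self, toy_interactome):
        group = {"A", "B", "C"}
        gn1 = extract_group_network(toy_interactome, group)
        extra = make_interactome(
            list(toy_interactome.edges) + [("X", "Z"), ("Y", "Z")]
        )
        gn2 = extract_group_network(extra, group)
        assert proportion_index(gn1) == proportion_index(gn2)
        assert per_node_index(gn1) == per_node_index(gn2)


class TestNormalization:
    def test_constant_controls(self):
        ratios, mean, sem = normalize_against_controls(0.5, [0.25] * 5)
        assert ratios == [2.0] * 5
        assert mean == 2.0 and sem == 0.0

    def test_sem_closed_form(self):
        controls = [1.0, 1 / 2, 1 / 3, 1 / 4, 1 / 5]
        ratios, mean, sem = normalize_against_controls(1.0, controls)
        assert ratios == pytest.approx([1, 2, 3, 4, 5])
        assert mean == pytest.approx(3.0)
        # sample SD of 1..5 is 1.5811, over sqrt(5)
        assert sem == pytest.approx(np.std([1, 2, 3, 4, 5], ddof=1) / math.sqrt(5))
        assert sem == pytest.approx(0.7071, abs=1e-4)

    def test_identity(self):
        _, mean, _ = normalize_against_controls(0.4, [0.4] * 5)
        assert mean == pytest.approx(1.0)

    def test_zero_control_rejected(self):
        with pytest.raises(ValueError):
            normalize_against_controls(0.5, [0.25, 0.0])


class TestYatesChi2:
    def test_identical_proportions(self):
        stat, p = yates_chi2_test(10, 10, 10, 10)
        assert stat == 0.0 and p == 1.0

    def test_closed_form_example(self):
        stat, _ = yates_chi2_test(10, 20, 30, 40)
        # N(|a1 b2 - b1 a2| - N/2)^2 / product of margins
        expected = 100 * (abs(10 * 40 - 20 * 30) - 50) ** 2 / (30 * 70 * 40 * 60)
        assert stat == pytest.approx(expected)
        assert stat == pytest.approx(0.4464, abs=1e-4)

    def test_matches_scipy_reference(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            a1, b1, a2, b2 = rng.integers(1, 200, size=4)
            stat, p = yates_chi2_test(int(a1), int(b1), int(a2), int(b2))
            ref = stats.chi2_contingency([[a1, b1], [a2, b2]], correction=True)
            assert stat == pytest.approx(ref.statistic, rel=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_scaling_counts_increases_statistic(self):
        s1, _ = yates_chi2_test(10, 20, 30, 40)
        s10, _ = yates_chi2_test(100, 200, 300, 400)
        assert s10 > s1

    def test_zero_marginal_undefined(self):
        with pytest.raises(ValueError, match="marginal"):
            yates_chi2_test(0, 0, 5, 5)


class TestAnova:
    def test_equal_means(self):
        f, dfb, dfw, p = one_way_anova([[1, 2, 3], [1, 2, 3]])
        assert f == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # SSB = 4, SSW = 1, df (1, 2) -> F = (4/1)/(1/2) = 8
        f, dfb, dfw, p = one_way_anova([[1, 2], [3, 4]])
        assert f == pytest.approx(8.0)
        assert (dfb, dfw) == (1, 2)

    def test_19_groups_of_5_df(self):
        rng = np.random.default_rng(0)
        groups = [list(rng.normal(size=5)) for _ in range(19)]
        _, dfb, dfw, _ = one_way_anova(groups)
        assert (dfb, dfw) == (18, 76)

    def test_zero_within_variance_reported_as_infinite(self):
        f, _, _, p = one_way_anova([[1, 1], [2, 2]])
        assert math.isinf(f) and p == 0.0


class TestDunnett:
    def test_identical_copy_has_p_near_one(self):
        g = [1.0, 1.2, 0.9, 1.1]
        ci, pvals = dunnett_posthoc([g, list(g)], control_index=0)
        assert ci == 0
        assert pvals[0] is None
        assert pvals[1] == pytest.approx(1.0, abs=1e-6)

    def test_single_comparison_reduces_to_t_test(self):
        a = [1.0, 1.5, 0.8, 1.2, 1.1]
        b = [2.0, 2.2, 1.9, 2.4, 2.1]
        _, pvals = dunnett_posthoc([b, a], control_index=1)
        t_p = stats.ttest_ind(b, a).pvalue
        assert pvals[0] == pytest.approx(t_p, abs=5e-3)

    def test_auto_control_closest_to_one(self):
        groups = [[3.0, 3.1, 2.9], [1.0, 1.05, 0.95], [0.2, 0.25, 0.15]]
        ci, _ = dunnett_posthoc(groups, "auto")
        assert ci == 1

    def test_adjusted_at_least_pairwise(self):
        rng = np.random.default_rng(11)
        groups = [list(rng.normal(loc=m, size=5)) for m in (1.0, 1.5, 0.7, 2.0)]
        ci, pvals = dunnett_posthoc(groups, control_index=0)
        for i, p in enumerate(pvals):
            if p is None:
                continue
            pair_p = stats.ttest_ind(groups[i], groups[0]).pvalue
            assert p >= pair_p - 5e-3


class TestPearson:
    def test_perfect_correlations(self):
        x = [1.0, 2.0, 5.0, 7.0]
        assert pearson_correlation(x, x)[0] == pytest.approx(1.0)
        assert pearson_correlation(x, [-v for v in x])[0] == pytest.approx(-1.0)

    def test_closed_form_example(self):
        r, _ = pearson_correlation([1, 2, 3], [2, 4, 7])
        # cov = 5/2, sx^2 = 1, sy^2 = 19/3 -> r = 5 / sqrt(2 * 12.667)
        assert r == pytest.approx(5 / math.sqrt(2 * (38 / 3)), rel=1e-9)
        assert r == pytest.approx(0.9934, abs=1e-4)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1, 1, 1], [1, 2, 3])


class TestGroupAnalysis:
    UNIVERSE = [f"P{i:03d}" for i in range(120)]

    def _planted(self, seed=0, p_in=0.4, p_out=0.05):
        group = frozenset(self.UNIVERSE[:25])
        inter, _, _ = generate_interactome(
            {"Q": group}, p_in, p_out, self.UNIVERSE, seed=seed
        )
        return group, inter

    def test_planted_group_ratios_above_one(self):
        group, inter = self._planted()
        res = connectivity_for_group(inter, group, self.UNIVERSE, seed=1, residue="Q")
        assert res.mean_norm_proportion > 1
        assert res.mean_norm_per_node > 1
        assert res.significant

    def test_reproducible_from_seed(self):
        group, inter = self._planted()
        r1 = connectivity_for_group(inter, group, self.UNIVERSE, seed=5)
        r2 = connectivity_for_group(inter, group, self.UNIVERSE, seed=5)
        assert r1 == r2

    def test_chi2_modes_differ_but_agree_in_direction(self):
        group, inter = self._planted()
        rm = connectivity_for_group(inter, group, self.UNIVERSE, seed=2, chi2_controls="mean")
        rp = connectivity_for_group(inter, group, self.UNIVERSE, seed=2, chi2_controls="pooled")
        assert rm.significant and rp.significant
        assert rm.chi2_stat != rp.chi2_stat

    def test_model_skips_small_groups_and_summarizes(self):
        group, inter = self._planted()
        groups = {
            "Q": PolyXGroup("Q", group),
            "W": PolyXGroup("W", frozenset({self.UNIVERSE[-1]})),  # singleton
            "A": PolyXGroup("A", frozenset(self.UNIVERSE[30:55])),
            "K": PolyXGroup("K", frozenset(self.UNIVERSE[55:80])),
        }
        results = analyze_all_groups(groups, inter, universe=self.UNIVERSE, seed=3)
        analyzed = {r.residue for r in results.group_results}
        assert analyzed == {"Q", "A", "K"}
        assert dict(results.skipped)["W"].startswith("size 1")
        assert results.anova is not None
        assert results.dunnett_control in analyzed
        assert results.pearson is not None and results.pearson[1] == 3
        frame = results.frame
        assert len(frame) == 3
        assert "mean_norm_per_node" in frame.columns
        text = results.summary()
        assert "ANOVA" in text and "Dunnett" in text

    def test_model_save_outputs(self, tmp_path):
        group, inter = self._planted()
        model = ConnectivityModel(
            {
                "Q": group,
                "A": frozenset(self.UNIVERSE[40:65]),
                "K": frozenset(self.UNIVERSE[65:90]),
            },
            inter,
            universe=self.UNIVERSE,
        )
        res = model.fit(seed=4)
        res.save(tmp_path)
        conn = (tmp_path / "connectivity.tsv").read_text()
        assert conn.splitlines()[0].startswith("residue\t")
        stats_txt = (tmp_path / "summary_stats.tsv").read_text()
        assert "anova_F" in stats_txt and "pearson_r" in stats_txt

    def test_undefined_group_reported_as_skipped(self):
        inter = make_interactome([("X1", "X2")])
        results = analyze_all_groups(
            {"Q": frozenset({"A1", "A2"})}, inter,
            universe=["A1", "A2", "X1", "X2"], seed=0,
        )
        assert results.group_results == []
        assert results.skipped and results.skipped[0][0] == "Q"
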