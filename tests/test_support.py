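"""Edge proportions, category assignment, profiles, chi-squared comparison."""

import networkx as nx
import pytest

from supportnet.errors import ConfigError, UndefinedStatisticError, UsageError
from supportnet.modules import ModulePartition
from supportnet.network import CooccurrenceNetwork
from supportnet.support import (
    CATEGORIES,
    CategoryLexicon,
    SupportProfile,
    assign_categories,
    category_profile,
    compare_profiles,
    edge_proportions,
    profile_table,
    within_edge_counts,
)


def _net_and_partition():
    """Module A: triangle (3 within edges); module B: one edge; 2 between edges."""
    g = nx.Graph()
    g.add_edges_from([("a1", "a2"), ("a2", "a3"), ("a1", "a3")], weight=1)
    g.add_edge("b1", "b2", weight=1)
    g.add_edges_from([("a1", "b1"), ("a3", "b2")], weight=1)
    p = ModulePartition(
        assignment={"a1": 0, "a2": 0, "a3": 0, "b1": 1, "b2": 1},
        resolution=1.0,
        modularity_q=0.0,
    )
    return CooccurrenceNetwork(graph=g), p


class TestEdgeProportions:
    def test_hand_counted_proportions(self):
        net, p = _net_and_partition()
        pcs = edge_proportions(net, p)
        assert pcs == {0: 0.75, 1: 0.25}
        assert within_edge_counts(net, p) == {0: 3, 1: 1}

    def test_single_module_takes_all(self):
        g = nx.complete_graph(4)
        p = ModulePartition(assignment={n: 0 for n in g}, resolution=1.0, modularity_q=0.0)
        assert edge_proportions(CooccurrenceNetwork(graph=g), p) == {0: 1.0}

    def test_symmetric_modules_get_equal_shares(self):
        g = nx.Graph()
        for base in ("x", "y", "z"):
            g.add_edges_from(
                [(f"{base}1", f"{base}2"), (f"{base}2", f"{base}3")], weight=1
            )
        assignment = {n: "xyz".index(n[0]) for n in g.nodes()}
        p = ModulePartition(assignment=assignment, resolution=1.0, modularity_q=0.0)
        pcs = edge_proportions(CooccurrenceNetwork(graph=g), p)
        assert all(v == pytest.approx(1 / 3) for v in pcs.values())

    def test_sums_to_one(self):
        net, p = _net_and_partition()
        assert sum(edge_proportions(net, p).values()) == pytest.approx(1.0, abs=1e-9)

    def test_no_within_edges_is_undefined(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=1)
        p = ModulePartition(assignment={"a": 0, "b": 1}, resolution=1.0, modularity_q=0.0)
        with pytest.raises(UndefinedStatisticError):
            edge_proportions(CooccurrenceNetwork(graph=g), p)


class TestCategoryLexicon:
    def test_default_lexicon_is_disjoint(self):
        lex = CategoryLexicon.default()
        assert lex.informational and lex.emotional and lex.companionship

    def test_overlap_rejected(self):
        with pytest.raises(ConfigError):
            CategoryLexicon(
                informational=frozenset({"pain"}),
                emotional=frozenset({"pain"}),
                companionship=frozenset(),
            )

    def test_file_roundtrip(self, tmp_path):
        path = tmp_path / "lex.txt"
        path.write_text(
            "[informational]\nchemo\n[emotional]\nhope\n[companionship]\ncoffee\n"
        )
        lex = CategoryLexicon.from_file(path)
        assert lex.words("emotional") == {"hope"}


class TestAssignCategories:
    def _lexicon(self):
        return CategoryLexicon(
            informational=frozenset({"treatment", "scan", "chemo"}),
            emotional=frozenset({"pain", "happy", "awful", "painful", "hope"}),
            companionship=frozenset({"coffee", "walk"}),
        )

    def test_pure_module(self):
        g = nx.complete_graph(["treatment", "scan", "chemo"])
        nx.set_edge_attributes(g, 1, "weight")
        g.add_edge("coffee", "walk", weight=1)
        p = ModulePartition(
            assignment={"treatment": 0, "scan": 0, "chemo": 0, "coffee": 1, "walk": 1},
            resolution=1.0, modularity_q=0.0,
        )
        cats = assign_categories(CooccurrenceNetwork(graph=g), p, self._lexicon())
        assert cats == {0: "informational", 1: "companionship"}

    def test_feelings_module_is_emotional(self):
        # a module whose keywords are mostly patient feelings
        words = ["treatment", "pain", "happy", "awful", "painful"]
        g = nx.complete_graph(words)
        nx.set_edge_attributes(g, 1, "weight")
        g.add_edge("coffee", "walk", weight=1)
        assignment = {w: 0 for w in words} | {"coffee": 1, "walk": 1}
        p = ModulePartition(assignment=assignment, resolution=1.0, modularity_q=0.0)
        cats = assign_categories(CooccurrenceNetwork(graph=g), p, self._lexicon())
        assert cats[0] == "emotional"

    def test_tie_is_unclassified(self):
        g = nx.Graph()
        g.add_edge("treatment", "pain", weight=1)
        g.add_edge("coffee", "walk", weight=1)
        p = ModulePartition(
            assignment={"treatment": 0, "pain": 0, "coffee": 1, "walk": 1},
            resolution=1.0, modularity_q=0.0,
        )
        cats = assign_categories(CooccurrenceNetwork(graph=g), p, self._lexicon())
        assert cats[0] == "unclassified"

    def test_override_precedence_and_validation(self):
        net, p = _net_and_partition()
        cats = assign_categories(net, p, self._lexicon(), overrides={0: "emotional"})
        assert cats[0] == "emotional"
        with pytest.raises(UsageError):
            assign_categories(net, p, self._lexicon(), overrides={99: "emotional"})


class TestCategoryProfile:
    def test_all_informational(self):
        profile = category_profile({0: 0.6, 1: 0.4}, {0: "informational", 1: "informational"})
        assert profile.proportions == {
            "informational": 1.0, "emotional": 0.0, "companionship": 0.0,
        }

    def test_direct_sum(self):
        profile = category_profile(
            {0: 0.6, 1: 0.3, 2: 0.1},
            {0: "informational", 1: "emotional", 2: "companionship"},
            edge_counts={0: 60, 1: 30, 2: 10},
        )
        assert profile.proportions["informational"] == pytest.approx(0.6)
        assert profile.proportions["emotional"] == pytest.approx(0.3)
        assert profile.edge_counts == {"informational": 60, "emotional": 30,
                                       "companionship": 10}
        profile.validate()

    def test_unclassified_mass_renormalized(self):
        profile = category_profile(
            {0: 0.5, 1: 0.25, 2: 0.25},
            {0: "informational", 1: "emotional", 2: "unclassified"},
        )
        assert profile.proportions["informational"] == pytest.approx(2 / 3)
        assert sum(profile.proportions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_all_unclassified_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            category_profile({0: 1.0}, {0: "unclassified"})


class TestProfileTable:
    def test_single_profile_means_equal_profile(self):
        profile = SupportProfile(
            "g", {"informational": 0.5, "emotional": 0.3, "companionship": 0.2}, {}
        )
        table, means = profile_table([profile])
        assert means["informational"] == pytest.approx(50.0)
        assert table.loc["g"].sum() == pytest.approx(100.0, abs=0.01)

    def test_rows_sum_to_hundred(self):
        profiles = [
            SupportProfile(
                f"g{i}",
                {"informational": 0.5494, "emotional": 0.1332, "companionship": 0.3174},
                {},
            )
            for i in range(3)
        ]
        table, _ = profile_table(profiles)
        for _, row in table.iterrows():
            assert row.sum() == pytest.approx(100.0, abs=0.01)


class TestCompareProfiles:
    def _profiles(self, counts):
        out = []
        for i, row in enumerate(counts):
            total = sum(row)
            out.append(
                SupportProfile(
                    f"g{i}",
                    {c: v / total for c, v in zip(CATEGORIES, row)},
                    {c: v for c, v in zip(CATEGORIES, row)},
                )
            )
        return out

    def test_identical_rows_statistic_zero(self):
        chi2, dof, p = compare_profiles(self._profiles([[30, 20, 10], [30, 20, 10]]))
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert dof == 2
        assert p == pytest.approx(1.0)

    def test_two_by_two_hand_computation(self):
        profiles = [
            SupportProfile("g0", {"informational": 1.0, "emotional": 0.0,
                                  "companionship": 0.0},
                           {"informational": 20, "emotional": 0}),
            SupportProfile("g1", {"informational": 0.0, "emotional": 1.0,
                                  "companionship": 0.0},
                           {"informational": 0, "emotional": 20}),
        ]
        chi2, dof, p = compare_profiles(profiles)
        assert chi2 == pytest.approx(40.0)
        assert dof == 1

    def test_invariant_to_group_order(self):
        profiles = self._profiles([[40, 10, 5], [10, 30, 20], [5, 5, 40]])
        chi2_a, _, _ = compare_profiles(profiles)
        chi2_b, _, _ = compare_profiles(profiles[::-1])
        assert chi2_a == pytest.approx(chi2_b, abs=1e-9)

    def test_zero_marginal_is_degenerate(self):
        with pytest.raises(UndefinedStatisticError):
            compare_profiles(self._profiles([[10, 0, 5], [20, 0, 5]]))

    def test_single_group_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            compare_profiles(self._profiles([[10, 5, 5]]))
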