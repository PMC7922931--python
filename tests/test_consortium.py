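import itertools

import pytest

from pgpmkit.consortium import (
    CompatibilityConflictError,
    CompatibilityMatrix,
    Consortium,
    Strain,
    build_graph,
    enumerate_consortia,
    validate_consortium,
)
from pgpmkit.synthetic_data import generate_compatibility

from ._oracles import power_set_maximal_cliques


def make_matrix(entries):
    m = CompatibilityMatrix()
    for a, b, v in entries:
        m.set(a, b, v)
    return m


def make_pool(names, functions=None):
    return {
        n: Strain(canonical_name=n, functions=frozenset(functions or {"PGP_generic"}),
                  selected=True)
        for n in names
    }


class TestCompatibilityMatrix:
    def test_symmetric_lookup_and_diagonal(self):
        m = make_matrix([("a", "b", "nc")])
        assert m.get("a", "b") == m.get("b", "a") == "nc"
        assert m.get("a", "a") == "+"

    def test_conflicting_entries_rejected(self):
        m = make_matrix([("a", "b", "+")])
        with pytest.raises(CompatibilityConflictError):
            m.set("b", "a", "-")

    def test_missing_pair_is_none(self):
        m = make_matrix([("a", "b", "+")])
        assert m.get("a", "c") is None


class TestBuildGraph:
    def test_policy_edges_from_published_tables(self, tables):
        strict = build_graph(tables.compat, "strict")
        lenient = build_graph(tables.compat, "lenient")
        bv84, ps141 = "Bacillus sp. BV84", "Bacillus licheniformis PS141"
        ls132, pp59 = "Azotobacter chroococcum LS132", "Komagataella pastoris PP59"
        mdiii, th01 = "Paraburkholderia tropica MDIIIAzo225", "Trichoderma harzianum TH01"
        assert not strict.has_edge(bv84, ps141)  # incompatible pair
        assert strict.has_edge(ls132, pp59)
        assert lenient.has_edge(mdiii, th01) and not strict.has_edge(mdiii, th01)

    def test_lenient_graph_is_supergraph_of_strict(self, tables):
        strict = build_graph(tables.compat, "strict")
        lenient = build_graph(tables.compat, "lenient")
        assert set(strict.edges) <= set(lenient.edges)

    def test_untested_fungus_fungus_pair_recorded_missing(self, tables):
        fungi = {"Trichoderma harzianum TH01", "Trichoderma harzianum ATCC 48131"}
        g = build_graph(tables.compat, "lenient")
        assert tuple(sorted(fungi)) in set(map(tuple, g.graph["missing_pairs"]))


class TestValidateConsortium:
    def test_published_mc_b_passes_strict(self, tables):
        report = validate_consortium(tables.consortia["MC_B"], tables.compat, tables.strains)
        assert len(report.pair_verdicts) == 10
        assert report.incompatible_pairs == [] and report.unclear_pairs == []
        assert report.passes_strict and report.passes_lenient

    def test_published_mc_c_passes_strict(self, tables):
        report = validate_consortium(tables.consortia["MC_C"], tables.compat, tables.strains)
        assert report.passes_strict

    def test_published_mc_a_fails_strict_on_one_unclear_pair(self, tables):
        report = validate_consortium(tables.consortia["MC_A"], tables.compat, tables.strains)
        assert len(report.pair_verdicts) == 15
        assert report.incompatible_pairs == []
        assert report.unclear_pairs == [
            ("Paraburkholderia tropica MDIIIAzo225", "Trichoderma harzianum TH01")
        ]
        assert report.passes_lenient and not report.passes_strict

    def test_incompatible_pair_fails_both_policies(self, tables):
        consortium = Consortium(
            "bad", ("Bacillus sp. BV84", "Bacillus licheniformis PS141")
        )
        report = validate_consortium(consortium, tables.compat, tables.strains)
        assert report.incompatible_pairs
        assert not report.passes_strict and not report.passes_lenient

    def test_unresolvable_member_raises(self, tables):
        consortium = Consortium("ghost", ("Bacillus sp. BV84", "Unknown strain X"))
        with pytest.raises(KeyError, match="Unknown strain X"):
            validate_consortium(consortium, tables.compat, tables.strains)

    def test_function_coverage_reported(self, tables):
        report = validate_consortium(
            tables.consortia["MC_B"],
            tables.compat,
            tables.strains,
            required_functions={"nitrogen_fixation", "amylolytic", "biocontrol"},
        )
        assert "Azotobacter vinelandii DSM 2289" in report.function_coverage["nitrogen_fixation"]
        assert "Bacillus amyloliquefaciens LMG 9814" in report.function_coverage["amylolytic"]
        assert report.uncovered_functions == []

    def test_strict_pass_implies_lenient_pass(self, tables):
        for consortium in tables.consortia.values():
            report = validate_consortium(consortium, tables.compat, tables.strains)
            assert (not report.passes_strict) or report.passes_lenient


class TestEnumerateConsortia:
    def test_complete_graph_yields_single_maximal_clique(self):
        names = ["a", "b", "c", "d"]
        m = make_matrix([(x, y, "+") for x, y in itertools.combinations(names, 2)])
        result = enumerate_consortia(make_pool(names), m, size_range=(2, 4))
        assert [c.members for c in result] == [("a", "b", "c", "d")]

    def test_planted_clique_recovered(self):
        matrix, planted = generate_compatibility(
            n_strains=12, planted_clique_size=5, edge_density=0.3, nc_rate=0.1, seed=7
        )
        pool = make_pool([f"S{i:02d}" for i in range(12)])
        result = enumerate_consortia(pool, matrix, size_range=(5, 12), policy="strict")
        assert tuple(planted) in {c.members for c in result}

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("policy", ["strict", "lenient"])
    def test_matches_power_set_enumeration(self, seed, policy):
        n = 12
        matrix, _ = generate_compatibility(
            n_strains=n, planted_clique_size=4, edge_density=0.4, nc_rate=0.2, seed=seed
        )
        names = [f"S{i:02d}" for i in range(n)]
        ok = {"+"} if policy == "strict" else {"+", "nc"}
        expected = power_set_maximal_cliques(
            names, lambda a, b: matrix.get(a, b) in ok
        )
        expected = [c for c in expected if len(c) >= 2]
        result = enumerate_consortia(
            make_pool(names), matrix, size_range=(2, n), policy=policy
        )
        assert sorted(c.members for c in result) == sorted(expected)

    def test_every_result_validates_under_same_policy(self):
        matrix, _ = generate_compatibility(
            n_strains=10, planted_clique_size=4, edge_density=0.5, nc_rate=0.3, seed=3
        )
        pool = make_pool([f"S{i:02d}" for i in range(10)])
        for policy in ("strict", "lenient"):
            for candidate in enumerate_consortia(pool, matrix, size_range=(2, 10), policy=policy):
                report = validate_consortium(candidate, matrix)
                assert report.passes_strict if policy == "strict" else report.passes_lenient

    def test_uncoverable_function_warns_and_returns_empty(self):
        names = ["a", "b"]
        m = make_matrix([("a", "b", "+")])
        with pytest.warns(UserWarning, match="phytase"):
            result = enumerate_consortia(
                make_pool(names), m, required_functions={"phytase"}, size_range=(2, 2)
            )
        assert result == []

    def test_function_coverage_filter(self):
        names = ["a", "b", "c"]
        m = make_matrix([(x, y, "+") for x, y in itertools.combinations(names, 2)])
        pool = {
            "a": Strain("a", functions=frozenset({"nitrogen_fixation"}), selected=True),
            "b": Strain("b", functions=frozenset({"biocontrol"}), selected=True),
            "c": Strain("c", functions=frozenset({"PGP_generic"}), selected=True),
        }
        result = enumerate_consortia(
            pool, m, required_functions={"nitrogen_fixation", "biocontrol"},
            size_range=(2, 3),
        )
        assert [c.members for c in result] == [("a", "b", "c")]
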