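"""Over-representation statistics, Bonferroni, grouping and arm comparison."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from omicsfunnel import (
    apply_relevance_exclusion,
    compare_approaches,
    enrich_pathways,
    fisher_two_sided,
    hypergeometric_upper_tail,
    merge_parent_groups,
)
from omicsfunnel.enrichment import enrich_single_datasets, resolve_root, round_half_up
from omicsfunnel.integration import DifferentialProteinRecord

from .conftest import make_input_set, make_pathway


def hypergeom_tail_oracle(k: int, K: int, n: int, N: int) -> float:
    """Exact upper tail by rational-arithmetic enumeration of the pmf."""
    denom = comb(N, n)
    total = Fraction(0)
    for x in range(k, min(K, n) + 1):
        if 0 <= n - x <= N - K:
            total += Fraction(comb(K, x) * comb(N - K, n - x), denom)
    return float(total)


class TestHypergeometricUpperTail:
    def test_zero_overlap_is_certain(self):
        assert hypergeometric_upper_tail(0, 5, 4, 10) == 1.0

    def test_degenerate_single_outcome(self):
        assert hypergeometric_upper_tail(2, 2, 2, 2) == 1.0

    def test_worked_enumeration_example(self):
        # N=10, K=5, n=4: P(X>=3) = (C(5,3)C(5,1)+C(5,4)C(5,0))/C(10,4) = 55/210
        assert hypergeometric_upper_tail(3, 5, 4, 10) == pytest.approx(55 / 210, abs=1e-12)

    @pytest.mark.parametrize("k,K,n,N", [(3, 2, 4, 10), (1, 11, 4, 10), (1, 5, 11, 10)])
    def test_impossible_configurations_rejected(self, k, K, n, N):
        with pytest.raises(ValueError):
            hypergeometric_upper_tail(k, K, n, N)

    @given(st.data())
    @settings(max_examples=200, derandomize=True)
    def test_matches_enumeration_oracle(self, data):
        N = data.draw(st.integers(1, 40))
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        k = data.draw(st.integers(max(0, K + n - N), min(K, n)))
        assert hypergeometric_upper_tail(k, K, n, N) == pytest.approx(
            hypergeom_tail_oracle(k, K, n, N), abs=1e-12
        )

    def test_monotone_nonincreasing_in_k(self):
        ps = [hypergeometric_upper_tail(k, 20, 30, 100) for k in range(0, 21)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestEnrichPathways:
    @pytest.mark.parametrize(
        "k,K,expected",
        [(23, 220, "10.45"), (19, 239, "7.95"), (6, 29, "20.69"), (4, 16, "25.00")],
    )
    def test_coverage_worked_examples(self, k, K, expected):
        universe = {f"U{i}" for i in range(1000)}
        members = set(list(universe)[:K])
        input_genes = sorted(members)[:k]
        pw = make_pathway("PW", members)
        input_set = make_input_set({g: "down" for g in input_genes})
        (res,) = enrich_pathways(input_set, [pw], universe=universe, min_overlap=1)
        assert res.k == k and res.K == K
        assert f"{round_half_up(res.coverage_pct, 2):.2f}" == expected
        # coverage identity before rounding
        assert res.coverage_pct * res.K / 100 == pytest.approx(res.k, abs=1e-9)

    def test_bonferroni_definition_and_bounds(self):
        universe = {f"U{i}" for i in range(50)}
        pws = [make_pathway(f"P{j}", list(sorted(universe))[j : j + 10]) for j in range(5)]
        input_set = make_input_set({g: "up" for g in sorted(universe)[:12]})
        results = enrich_pathways(input_set, pws, universe=universe, min_overlap=1)
        m = len(results)
        for r in results:
            assert r.m_tested == m
            assert r.p_adj == pytest.approx(min(1.0, r.p_raw * m), abs=1e-15)
            assert r.p_raw <= r.p_adj <= 1.0

    def test_up_down_split_follows_input_directions(self):
        universe = {"A", "B", "C", "D", "E", "F"}
        pw = make_pathway("P1", {"A", "B", "C"})
        input_set = make_input_set({"A": "up", "B": "down", "C": "down", "D": "up"})
        (res,) = enrich_pathways(input_set, [pw], universe=universe, min_overlap=1)
        assert res.overlap_up == {"A"} and res.overlap_down == {"B", "C"}
        assert len(res.overlap_genes) == res.k

    def test_min_overlap_filters_pathways(self):
        universe = {f"U{i}" for i in range(20)}
        pws = [make_pathway("BIG", sorted(universe)[:10]), make_pathway("TINY", sorted(universe)[15:18])]
        input_set = make_input_set({g: "up" for g in sorted(universe)[:5]})
        results = enrich_pathways(input_set, pws, universe=universe, min_overlap=3)
        assert [r.pathway_id for r in results] == ["BIG"]

    def test_empty_inputs_rejected(self):
        universe = {"A"}
        with pytest.raises(ValueError):
            enrich_pathways(make_input_set({}), [make_pathway("P", {"A"})], universe)
        with pytest.raises(ValueError):
            enrich_pathways(make_input_set({"A": "up"}), [], universe)

    def test_two_sided_laterality_uses_fisher(self):
        universe = {f"U{i}" for i in range(30)}
        pw = make_pathway("P1", sorted(universe)[:8])
        input_set = make_input_set({g: "up" for g in sorted(universe)[:6]})
        (res,) = enrich_pathways(input_set, [pw], universe=universe, min_overlap=1, laterality="two-sided")
        assert res.p_raw == pytest.approx(fisher_two_sided(res.k, 8, 6, 30), abs=1e-12)


class TestRelevanceExclusion:
    @pytest.mark.parametrize("n_sig,n_excl,n_left", [(28, 13, 15), (19, 6, 13)])
    def test_retained_counts(self, n_sig, n_excl, n_left):
        universe = {f"U{i}" for i in range(200)}
        ordered = sorted(universe)
        pws = [make_pathway(f"P{j:02d}", ordered[j : j + 6]) for j in range(n_sig)]
        input_set = make_input_set({g: "down" for g in ordered[: n_sig + 6]})
        results = enrich_pathways(input_set, pws, universe=universe, min_overlap=1)
        excluded = {f"P{j:02d}" for j in range(n_excl)}
        retained = apply_relevance_exclusion(results, excluded)
        assert len(retained) == n_left
        assert [r.pathway_id for r in retained] == [r.pathway_id for r in results if r.pathway_id not in excluded]

    def test_empty_exclusion_is_identity(self):
        universe = {"A", "B", "C"}
        pw = make_pathway("P", {"A", "B"})
        results = enrich_pathways(make_input_set({"A": "up"}), [pw], universe, min_overlap=1)
        assert apply_relevance_exclusion(results, set()) == results

    def test_unknown_ids_warn(self):
        universe = {"A", "B"}
        results = enrich_pathways(make_input_set({"A": "up"}), [make_pathway("P", {"A"})], universe, 1)
        with pytest.warns(UserWarning, match="not among tested"):
            apply_relevance_exclusion(results, {"NOPE"})


class TestParentGroupMerging:
    def _results(self, pathway_ids, universe_size=40):
        universe = [f"U{i}" for i in range(universe_size)]
        pws = [make_pathway(pid, universe[j * 3 : j * 3 + 5]) for j, pid in enumerate(pathway_ids)]
        input_set = make_input_set({g: "up" for g in universe[: universe_size // 2]})
        return enrich_pathways(input_set, pws, universe=set(universe), min_overlap=1)

    def test_shared_parent_collapses_to_one_group(self):
        results = self._results(["P_activation", "P_degran", "P_signal"])
        hierarchy = {"P_degran": "P_activation", "P_signal": "P_activation"}
        groups = merge_parent_groups(results, hierarchy)
        assert len(groups) == 1
        (g,) = groups
        assert g.group_id == "P_activation"
        assert g.pathway_ids == {"P_activation", "P_degran", "P_signal"}
        assert g.overlap_genes == set().union(*(r.overlap_genes for r in results))

    def test_no_hierarchy_is_identity(self):
        results = self._results(["A", "B", "C"])
        groups = merge_parent_groups(results, {})
        assert [g.group_id for g in groups] == [r.pathway_id for r in results]

    def test_cycle_detected(self):
        results = self._results(["A", "B"])
        with pytest.raises(ValueError, match="cycle"):
            merge_parent_groups(results, {"A": "B", "B": "A"})

    @given(st.data())
    @settings(max_examples=60, derandomize=True)
    def test_group_count_equals_root_count(self, data):
        # random forest of depth <= 3 over 8 pathways
        ids = [f"N{i}" for i in range(8)]
        hierarchy = {}
        for depth_ids in (ids[4:6], ids[6:8]):
            for nid in depth_ids:
                parent = data.draw(st.sampled_from([p for p in ids if p != nid and p not in depth_ids]))
                if resolve_cycle_free(hierarchy, nid, parent):
                    hierarchy[nid] = parent
        results = self._results(ids)
        groups = merge_parent_groups(results, hierarchy)
        roots = {resolve_root(pid, hierarchy) for pid in ids}
        assert {g.group_id for g in groups} == roots
        assert len(groups) == len(roots)


def resolve_cycle_free(hierarchy, child, parent) -> bool:
    """Oracle helper: accept the edge only if it keeps the forest acyclic."""
    node, seen = parent, {child}
    while node in hierarchy:
        if node in seen:
            return False
        seen.add(node)
        node = hierarchy[node]
    return node not in seen


class TestApproachComparison:
    def test_published_style_overlap(self):
        a = {f"A{i}" for i in range(7)} | {f"S{i}" for i in range(8)}  # 15 total
        b = {f"B{i}" for i in range(5)} | {f"S{i}" for i in range(8)}  # 13 total
        cmpr = compare_approaches(a, b)
        assert (len(a), len(b), cmpr.union_size) == (15, 13, 20)
        assert cmpr.overlap_pct == pytest.approx(40.0, abs=1e-12)

    def test_identical_sets_full_overlap(self):
        cmpr = compare_approaches({"X", "Y"}, {"X", "Y"})
        assert cmpr.overlap_pct == 100.0

    def test_disjoint_sets_zero_overlap(self):
        assert compare_approaches({"X"}, {"Y"}).overlap_pct == 0.0

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError):
            compare_approaches(set(), set())


class TestSingleDatasetComparison:
    def _records(self, sid, gene_dirs):
        return [DifferentialProteinRecord(sid, g, d) for g, d in gene_dirs]

    def test_small_studies_flagged_insufficient(self):
        universe = [f"U{i}" for i in range(30)]
        db = [make_pathway("P1", universe[:10])]
        studies = {"S1": self._records("S1", [(universe[0], "up")])}
        _, report = enrich_single_datasets(studies, db, integrated_significant=set(), min_overlap=3)
        assert report["insufficient_identifications"] == ["S1"]

    def test_integration_only_pathway_detected(self):
        # per-study overlap k=2 stays untested (min_overlap=3); union reaches k=6
        universe = [f"U{i}" for i in range(60)]
        db = [make_pathway("P1", universe[:8])] + [
            make_pathway(f"BG{j}", universe[10 + 5 * j : 18 + 5 * j]) for j in range(6)
        ]
        member_pairs = [(universe[i], universe[i + 1]) for i in range(0, 6, 2)]
        studies = {
            f"S{j + 1}": self._records(f"S{j + 1}", [(a, "down"), (b, "down")])
            for j, (a, b) in enumerate(member_pairs)
        }
        all_records = [r for recs in studies.values() for r in recs]
        from omicsfunnel import integrate

        integrated = integrate(all_records)
        results = enrich_pathways(integrated, db, min_overlap=3)
        integrated_sig = {r.pathway_id for r in results if r.significant}
        assert "P1" in integrated_sig
        _, report = enrich_single_datasets(studies, db, integrated_sig, min_overlap=3)
        assert "P1" in report["integration_only"]

    def test_identical_study_gives_empty_difference(self):
        universe = [f"U{i}" for i in range(30)]
        db = [make_pathway("P1", universe[:8])]
        recs = self._records("S1", [(g, "down") for g in universe[:6]])
        from omicsfunnel import integrate

        integrated = integrate(recs)
        results = enrich_pathways(integrated, db, min_overlap=3)
        sig = {r.pathway_id for r in results if r.significant}
        _, report = enrich_single_datasets({"S1": recs}, db, sig, min_overlap=3)
        assert report["integration_only"] == [] and report["single_only"] == []
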