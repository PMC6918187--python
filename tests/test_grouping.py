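"""Gate cascade and group formation, checked against brute-force oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acorf import (
    CandidatePair,
    DeltaEntry,
    DeltaList,
    FeatureTable,
    Parameters,
    SimilarityMatrix,
    build_groups,
    compute_similarity,
    mass_gate,
    rt_gate,
    run_filtration,
    select_pairs,
)


def bfs_components(ids: list[str], edges: list[tuple[str, str]]) -> set[frozenset[str]]:
    """Independent breadth-first-search connected components (the oracle)."""
    adj: dict[str, set[str]] = {i: set() for i in ids}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    seen: set[str] = set()
    comps: set[frozenset[str]] = set()
    for start in ids:
        if start in seen:
            continue
        queue, comp = [start], {start}
        seen.add(start)
        while queue:
            node = queue.pop()
            for nxt in adj[node]:
                if nxt not in seen:
                    seen.add(nxt)
                    comp.add(nxt)
                    queue.append(nxt)
        comps.add(frozenset(comp))
    return comps


def sim_from_array(ids: list[str], arr: np.ndarray) -> SimilarityMatrix:
    return SimilarityMatrix(pd.DataFrame(arr, index=ids, columns=ids))


class TestParameters:
    def test_mass_gate_requires_rt_gate(self):
        with pytest.raises(ValueError, match="RT gate"):
            Parameters(cor_threshold=0.9, mass_tol=0.005)

    def test_top_n_required_only_for_method_4(self):
        with pytest.raises(ValueError, match="top_n"):
            Parameters(cor_threshold=0.9, rep_method="highest_mass_in_top_n")
        with pytest.raises(ValueError, match="top_n"):
            Parameters(cor_threshold=0.9, rep_method="highest_mass", top_n=3)


class TestSelectPairs:
    def test_toy_matrix_six_pairs_negatives_excluded(self, toy_matrix):
        s = compute_similarity(toy_matrix, "pearson")
        pairs = select_pairs(s, 0.9)
        got = {frozenset((p.id_a, p.id_b)) for p in pairs}
        assert got == {
            frozenset(x)
            for x in [
                ("F1", "F2"), ("F1", "F3"), ("F1", "F5"),
                ("F2", "F3"), ("F2", "F5"), ("F3", "F5"),
            ]
        }

    def test_threshold_is_strict(self):
        s = sim_from_array(["A", "B"], np.array([[1.0, 0.75], [0.75, 1.0]]))
        assert select_pairs(s, 0.75) == []

    def test_unreachable_threshold_gives_empty_list(self, toy_matrix):
        s = compute_similarity(toy_matrix, "pearson")
        assert select_pairs(s, 1.5) == []

    def test_missing_similarity_never_selected(self):
        s = sim_from_array(["A", "B"], np.array([[1.0, np.nan], [np.nan, 1.0]]))
        assert select_pairs(s, -10.0) == []

    def test_absolute_mode_selects_anticorrelated(self, toy_matrix):
        s = compute_similarity(toy_matrix, "pearson")
        assert len(select_pairs(s, 0.9, absolute=True)) == 10


class TestRtGate:
    def test_close_pair_kept_far_pair_dropped(self, toy_table):
        pairs = [CandidatePair("F1", "F2", 1.0), CandidatePair("F1", "F4", 1.0)]
        kept = rt_gate(pairs, toy_table, rt_delta=6.0)
        assert [(p.id_a, p.id_b) for p in kept] == [("F1", "F2")]
        assert kept[0].rt_pass

    def test_boundary_is_inclusive_even_at_zero_delta(self, toy_table):
        toy_table.data.loc[toy_table.data["name"] == "F2", "rt"] = "120.0"
        kept = rt_gate([CandidatePair("F1", "F2", 1.0)], toy_table, rt_delta=0.0)
        assert len(kept) == 1

    def test_missing_rt_names_the_feature(self, toy_table):
        toy_table.data.loc[toy_table.data["name"] == "F2", "rt"] = ""
        with pytest.raises(ValueError, match="F2"):
            rt_gate([CandidatePair("F1", "F2", 1.0)], toy_table, 6.0)


class TestMassGate:
    def test_isotope_delta_matched_and_labelled(self, toy_deltas):
        meta = pd.DataFrame({"name": ["A", "B"], "mz": ["292.0134", "293.0167"]})
        t = FeatureTable(meta, "name", mz_column="mz")
        kept = mass_gate(
            [CandidatePair("A", "B", 0.99, rt_pass=True)], t, toy_deltas, 0.002
        )
        assert len(kept) == 1 and kept[0].delta_label == "isotope_13C"

    def test_unlisted_delta_dropped(self, toy_table, toy_deltas):
        # F1 (180.0634) vs F5 (300.1000): delta 120.0366 matches nothing
        kept = mass_gate(
            [CandidatePair("F1", "F5", 1.0, rt_pass=True)], toy_table, toy_deltas, 0.005
        )
        assert kept == []

    def test_boundary_deviation_exactly_tol_kept(self):
        deltas = DeltaList([DeltaEntry("X", 1.0)])
        meta = pd.DataFrame({"name": ["A", "B"], "mz": ["100.0", "101.002"]})
        t = FeatureTable(meta, "name", mz_column="mz")
        kept = mass_gate([CandidatePair("A", "B", 1.0, rt_pass=True)], t, deltas, 0.002)
        assert len(kept) == 1

    def test_tie_breaks_to_closest_then_list_order(self):
        deltas = DeltaList([DeltaEntry("near", 1.000), DeltaEntry("far", 1.010)])
        meta = pd.DataFrame({"name": ["A", "B"], "mz": ["100.0", "101.001"]})
        t = FeatureTable(meta, "name", mz_column="mz")
        kept = mass_gate([CandidatePair("A", "B", 1.0, rt_pass=True)], t, deltas, 0.02)
        assert kept[0].delta_label == "near"

    def test_missing_mz_names_the_feature(self, toy_deltas):
        meta = pd.DataFrame({"name": ["A", "B"], "mz": ["100.0", ""]})
        t = FeatureTable(meta, "name", mz_column="mz")
        with pytest.raises(ValueError, match="B"):
            mass_gate([CandidatePair("A", "B", 1.0, rt_pass=True)], t, toy_deltas, 0.01)


class TestBuildGroups:
    def test_chain_plus_isolate_gives_two_groups(self):
        edges = [CandidatePair("A", "B", 1.0), CandidatePair("B", "C", 1.0)]
        g = build_groups(edges, ["A", "B", "C", "D"])
        assert g.n_groups == 2
        assert g.assignment["A"] == g.assignment["B"] == g.assignment["C"]
        assert g.assignment["D"] != g.assignment["A"]

    def test_no_edges_gives_all_singletons(self):
        ids = [f"F{i}" for i in range(7)]
        g = build_groups([], ids)
        assert g.n_groups == 7
        assert [g.assignment[f] for f in ids] == list(range(1, 8))

    def test_group_numbers_follow_first_appearance(self):
        edges = [CandidatePair("C", "D", 1.0)]
        g = build_groups(edges, ["A", "B", "C", "D"])
        assert (g.assignment["A"], g.assignment["B"], g.assignment["C"]) == (1, 2, 3)
        assert g.assignment["D"] == 3

    def test_unknown_id_in_pair_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            build_groups([CandidatePair("A", "Z", 1.0)], ["A", "B"])

    def test_matches_bfs_oracle_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(2, 51))
            ids = [f"N{i}" for i in range(n)]
            n_edges = int(rng.integers(0, 2 * n))
            edges = [
                tuple(rng.choice(n, size=2, replace=False))
                for _ in range(n_edges)
            ]
            named = [(ids[a], ids[b]) for a, b in edges]
            g = build_groups([CandidatePair(a, b, 1.0) for a, b in named], ids)
            got = {frozenset(m) for m in g.members().values()}
            assert got == bfs_components(ids, named)


class TestRunFiltration:
    def test_gatewise_group_counts_on_toy(self, toy_table, toy_matrix, toy_deltas):
        s = compute_similarity(toy_matrix, "pearson")
        r_sim = run_filtration(toy_table, toy_matrix, s, Parameters(0.9))
        r_rt = run_filtration(toy_table, toy_matrix, s, Parameters(0.9, rt_delta=6.0))
        r_all = run_filtration(
            toy_table, toy_matrix, s, Parameters(0.9, rt_delta=6.0, mass_tol=0.005),
            toy_deltas,
        )
        assert r_sim.grouping.n_groups == 2
        assert r_rt.grouping.n_groups == 2
        assert r_all.grouping.n_groups == 3
        members = {frozenset(m) for m in r_all.grouping.members().values()}
        assert members == {frozenset(["F1", "F2", "F3"]), frozenset(["F4"]), frozenset(["F5"])}

    def test_bridging_keeps_unmatched_pair_in_group(self, toy_table, toy_matrix, toy_deltas):
        # F2-F3 delta (20.9786) matches no entry, yet F1 bridges them
        s = compute_similarity(toy_matrix, "pearson")
        r = run_filtration(
            toy_table, toy_matrix, s, Parameters(0.9, rt_delta=6.0, mass_tol=0.005),
            toy_deltas,
        )
        labelled = {frozenset((p.id_a, p.id_b)) for p in r.validated_pairs}
        assert frozenset(("F2", "F3")) not in labelled
        assert r.grouping.assignment["F2"] == r.grouping.assignment["F3"]

    def test_id_mismatch_between_files_is_hard_error(self, toy_table, toy_matrix):
        s = compute_similarity(toy_matrix, "pearson")
        shrunk = SimilarityMatrix(s.values.iloc[:4, :4])
        with pytest.raises(ValueError, match="F5"):
            run_filtration(toy_table, toy_matrix, shrunk, Parameters(0.9))

    def test_delta_list_without_mass_tol_rejected(self, toy_table, toy_matrix, toy_deltas):
        s = compute_similarity(toy_matrix, "pearson")
        with pytest.raises(ValueError, match="mass_tol"):
            run_filtration(toy_table, toy_matrix, s, Parameters(0.9, rt_delta=6.0), toy_deltas)


class TestGroupingProperties:
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_partition_property(self, seed):
        """Every feature lands in exactly one group, whatever the edges."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 30))
        ids = [f"F{i}" for i in range(n)]
        edges = [
            CandidatePair(ids[int(a)], ids[int(b)], 1.0)
            for a, b in (
                rng.choice(n, size=2, replace=False) for _ in range(int(rng.integers(0, n)))
            )
        ]
        g = build_groups(edges, ids)
        assert set(g.assignment) == set(ids)
        assert sum(len(m) for m in g.members().values()) == n

    def test_each_gate_only_splits_groups(self, toy_deltas):
        """#groups(similarity) <= #groups(+RT) <= #groups(+RT+mass)."""
        from acorf import simulate_dataset

        for seed in range(20):
            m, t, _ = simulate_dataset(
                n_analytes=8, max_derived=3, n_samples=12, n_noise_features=10, seed=seed
            )
            s = compute_similarity(m, "pearson")
            n1 = run_filtration(t, m, s, Parameters(0.8)).grouping.n_groups
            n2 = run_filtration(t, m, s, Parameters(0.8, rt_delta=0.05)).grouping.n_groups
            n3 = run_filtration(
                t, m, s, Parameters(0.8, rt_delta=0.05, mass_tol=0.005), toy_deltas
            ).grouping.n_groups
            assert n1 <= n2 <= n3

    def test_raising_threshold_never_merges_groups(self):
        from acorf import simulate_dataset

        m, t, _ = simulate_dataset(
            n_analytes=10, max_derived=3, n_samples=10, n_noise_features=10, seed=3
        )
        s = compute_similarity(m, "pearson")
        counts = [
            run_filtration(t, m, s, Parameters(thr)).grouping.n_groups
            for thr in (0.5, 0.7, 0.9, 0.99)
        ]
        assert counts == sorted(counts)

    def test_membership_invariant_under_similarity_row_permutation(
        self, toy_table, toy_matrix
    ):
        s = compute_similarity(toy_matrix, "pearson")
        perm = ["F3", "F5", "F1", "F4", "F2"]
        s_perm = SimilarityMatrix(s.values.loc[perm, perm])
        g1 = run_filtration(toy_table, toy_matrix, s, Parameters(0.9)).grouping
        g2 = run_filtration(toy_table, toy_matrix, s_perm, Parameters(0.9)).grouping
        assert {frozenset(m) for m in g1.members().values()} == {
            frozenset(m) for m in g2.members().values()
        }
        # numbering still follows the metadata feature order
        assert g2.assignment["F1"] == 1
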