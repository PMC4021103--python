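"""Downstream interrogation: overlaps, neighbors, subnetworks, modules."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tfminet import (
    EvidenceSet,
    OverlapReport,
    TFList,
    TimeCourseStates,
    ValidationError,
    build_network,
    candidate_new_tfs,
    classify_switches,
    evidence_report,
    induced_subnetwork,
    make_edge,
    neighbors,
    overlap,
    overlay_states,
    seed_neighborhood,
)

TFS = TFList(frozenset(["T1", "T2", "T3"]))


def star_network():
    """T1 is a hub over g1..g3; T2-T3 interact; T2-g1 bridges."""
    edges = [
        make_edge("T1", "g1", 0.9, -60),
        make_edge("T1", "g2", 0.7, -40),
        make_edge("T1", "g3", 0.5, -30),
        make_edge("T2", "T3", 0.6, -40),
        make_edge("T2", "g1", 0.4, -20),
    ]
    return build_network(edges, TFS)


class TestOverlapReport:
    def test_table_style_percentages(self):
        assert OverlapReport(1791, 1930).percent == 92.8
        assert OverlapReport(1835, 1988).percent == 92.3

    def test_integer_style_percentage(self):
        assert OverlapReport(159, 719).percent == 22.1
        assert OverlapReport(159, 719).percent_int == 22

    def test_bounds_enforced(self):
        with pytest.raises(ValidationError):
            OverlapReport(5, 4)

    @given(st.integers(0, 500), st.integers(0, 500))
    @settings(max_examples=100, deadline=None)
    def test_counts_are_the_stored_truth(self, detected, extra):
        total = detected + extra
        if total == 0:
            return
        rep = OverlapReport(detected, total)
        assert rep.n_detected == detected
        assert abs(rep.percent - 100 * detected / total) <= 0.05 + 1e-9


class TestEvidenceReport:
    def test_counts_interacting_tfs_only(self):
        net = star_network()
        ev = EvidenceSet({"T1": frozenset(["rt_pcr"]), "g1": frozenset(["rna_seq"])})
        rep = evidence_report(net, ev)
        # universe: T1, T2, T3 all have edges; only T1 detected
        assert (rep.n_detected, rep.n_total) == (1, 3)

    def test_zero_detected(self):
        rep = evidence_report(star_network(), EvidenceSet({}))
        assert rep.n_detected == 0 and rep.percent == 0.0

    def test_tf_without_edges_excluded_from_universe(self):
        net = star_network().with_edges(
            [make_edge("T1", "g1", 0.9, -60), make_edge("T2", "T3", 0.6, -40)]
        )
        rep = evidence_report(net, EvidenceSet({"T1": frozenset(["ontology"])}))
        assert rep.n_total == 3  # T1, T2, T3 still incident
        net2 = net.with_edges([make_edge("T1", "g1", 0.9, -60)])
        assert evidence_report(net2, EvidenceSet({"T1": frozenset(["ontology"])})).n_total == 1

    def test_no_interacting_tf_is_an_error(self):
        net = star_network().with_edges([])
        with pytest.raises(ValidationError):
            evidence_report(net, EvidenceSet({}))


class TestOverlapLists:
    def test_identical_lists(self):
        assert overlap({"a", "b"}, {"b", "a"}).percent == 100.0

    def test_disjoint_lists(self):
        assert overlap({"a"}, {"b"}).percent == 0.0

    def test_empty_reference_rejected(self):
        with pytest.raises(ValidationError):
            overlap(set(), {"a"})

    @given(
        st.sets(st.integers(0, 30), min_size=1, max_size=20),
        st.sets(st.integers(0, 30), max_size=20),
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force_set_arithmetic(self, a, b):
        rep = overlap(map(str, a), map(str, b))
        assert rep.n_detected == len(a & b)
        assert rep.n_total == len(a)


class TestNeighbors:
    def test_sorted_by_mi_descending(self):
        out = neighbors(star_network(), "T1")
        assert [e.other("T1") for e in out] == ["g1", "g2", "g3"]

    def test_cutoff_gives_prefix_subset(self):
        net = star_network()
        loose = neighbors(net, "T1", p_cutoff_decade=-20)
        tight = neighbors(net, "T1", p_cutoff_decade=-40)
        assert tight == loose[: len(tight)]

    def test_gene_with_no_significant_edges(self):
        assert neighbors(star_network(), "g2", p_cutoff_decade=-140) == []

    def test_unknown_gene_suggests_close_ids(self):
        with pytest.raises(KeyError, match="T1"):
            neighbors(star_network(), "T1x")

    def test_mi_ties_break_on_partner_id(self):
        net = build_network(
            [make_edge("T1", "b", 0.5, -30), make_edge("T1", "a", 0.5, -30)],
            TFS,
        )
        assert [e.other("T1") for e in neighbors(net, "T1")] == ["a", "b"]


class TestInducedSubnetwork:
    def test_path_plus_isolate(self):
        net = build_network(
            [make_edge("A", "B", 0.5, -30), make_edge("B", "C", 0.4, -30),
             make_edge("C", "Z", 0.4, -30)],
            TFList(frozenset(["A"])),
        )
        sub, summary = induced_subnetwork(net, {"A", "B", "C", "D"})
        assert sub.n_nodes == 3 and sub.n_edges == 2
        assert summary.largest_size == 3
        assert summary.largest_fraction_percent == 75.0

    def test_full_gene_list_returns_whole_network(self):
        net = star_network()
        sub, _ = induced_subnetwork(net, net.nodes, p_cutoff_decade=-20)
        assert sub.edges == net.edges

    def test_tight_cutoff_empties_result(self):
        sub, summary = induced_subnetwork(star_network(), {"T1", "g1"}, p_cutoff_decade=-140)
        assert sub.n_edges == 0 and summary.largest_size == 0

    def test_planted_modules_separate_into_components(self, bench_fit):
        results, truth = bench_fit
        m1 = truth.module_members["hub_1"]
        m2 = truth.module_members["hub_2"]
        sub, summary = results.induced_subnetwork(m1 | m2, epsilon=0.0)
        assert summary.n_components == 2
        assert {frozenset(c) for c in summary.components} == {frozenset(m1), frozenset(m2)}

    def test_empty_gene_list_rejected(self):
        with pytest.raises(ValidationError):
            induced_subnetwork(star_network(), set())


class TestTimeCourse:
    TC = TimeCourseStates(
        states={
            "A": ("down", "down", "up", "up"),
            "B": ("up", "down", "up", "down"),
            "C": ("down", "down", "down", "down"),
            "D": ("up", "up", "down", "down"),
        },
        timepoints=("1h", "3h", "6h", "12h"),
    )

    def test_overlay_marks_missing_as_unknown(self):
        net = build_network(
            [make_edge("A", "B", 0.5, -30), make_edge("A", "X", 0.4, -30)],
            TFList(frozenset(["A"])),
        )
        table = overlay_states(net, self.TC)
        assert list(table.loc["A"]) == ["down", "down", "up", "up"]
        assert list(table.loc["X"]) == ["unknown"] * 4
        assert list(table.columns) == ["1h", "3h", "6h", "12h"]

    def test_switch_classes(self):
        classes = classify_switches(self.TC)
        assert classes["down_to_up"] == {"A"}
        assert classes["multi_switch"] == {"B"}
        assert classes["constant"] == {"C"}
        assert classes["up_to_down"] == {"D"}

    @given(
        st.dictionaries(
            st.text(st.characters(whitelist_categories=("Lu",)), min_size=1, max_size=4),
            st.lists(st.sampled_from(["down", "up"]), min_size=3, max_size=3).map(tuple),
            min_size=1,
            max_size=8,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_partition_is_exhaustive_and_exclusive(self, states):
        tc = TimeCourseStates(states=states, timepoints=("t1", "t2", "t3"))
        classes = classify_switches(tc)
        all_assigned = [g for members in classes.values() for g in members]
        assert sorted(all_assigned) == sorted(states)

    def test_mismatched_state_length_rejected(self):
        with pytest.raises(ValidationError):
            TimeCourseStates(states={"A": ("up",)}, timepoints=("t1", "t2"))


class TestSeedExpansion:
    def test_single_seed_star(self):
        net = star_network()
        hood = seed_neighborhood(net, {"T1"})
        assert hood.nodes == {"T1", "g1", "g2", "g3"}
        assert hood.n_edges == 3

    def test_two_seeds_sharing_a_neighbor(self):
        net = build_network(
            [make_edge("S1", "x", 0.5, -30), make_edge("S2", "x", 0.4, -30),
             make_edge("y", "z", 0.9, -80)],
            TFList(frozenset(["S1"])),
        )
        hood = seed_neighborhood(net, {"S1", "S2"})
        assert hood.nodes == {"S1", "S2", "x"} and hood.n_edges == 2

    def test_absent_seeds_recorded_not_dropped(self):
        hood = seed_neighborhood(star_network(), {"T1", "GHOST"})
        assert hood.provenance["seeds_not_in_network"] == "GHOST"

    def test_all_seeds_absent_rejected(self):
        with pytest.raises(ValidationError):
            seed_neighborhood(star_network(), {"GHOST"})

    def test_candidate_ranking_by_seed_connectivity(self):
        edges = [
            make_edge("s1", "TA", 0.5, -30),
            make_edge("s2", "TA", 0.5, -30),
            make_edge("s3", "TA", 0.5, -30),
            make_edge("s1", "TB", 0.9, -80),
        ]
        tfs = TFList(frozenset(["TA", "TB", "s1"]))
        net = build_network(edges, tfs)
        hood = seed_neighborhood(net, {"s1", "s2", "s3"})
        ranked = candidate_new_tfs(hood, {"s1", "s2", "s3"}, tfs)
        assert [r[0] for r in ranked] == ["TA", "TB"]
        assert ranked[0][1] == 3

    def test_candidates_exclude_seeds_and_non_tfs(self):
        net = star_network()
        hood = seed_neighborhood(net, {"T1", "T2"})
        ranked = candidate_new_tfs(hood, {"T1", "T2"}, TFS)
        names = {r[0] for r in ranked}
        assert "T1" not in names and "T2" not in names
        assert names <= set(TFS.ids)

    def test_all_neighborhood_tfs_are_seeds_gives_empty_list(self):
        net = build_network([make_edge("T1", "g1", 0.5, -30)], TFS)
        hood = seed_neighborhood(net, {"T1"})
        assert candidate_new_tfs(hood, {"T1"}, TFS) == []

    def test_hidden_regulator_recovered_on_synthetic_truth(self, bench_fit):
        """Seeding with one hub's targets pulls the hub back in."""
        results, truth = bench_fit
        hub = next(iter(truth.module_members["hub_1"] & truth.tf_ids))
        targets = truth.module_members["hub_1"] - {hub}
        hood = results.seed_neighborhood(targets, p_cutoff_decade=-20, epsilon=0.0)
        ranked = results.candidate_new_tfs(hood, targets)
        assert hub in {r[0] for r in ranked}
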