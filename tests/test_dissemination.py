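"""Dissemination classification, seeding clones, proportions, dispersion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metevol import dissemination as dis
from metevol.core import ROOT_MARKER, classify_clonality
from .conftest import make_tree


def _two_met_tree(met2_ccfs):
    return make_tree(
        "T",
        [
            ("C1", ROOT_MARKER, 50,
             {"R1": 1.0, "M1": 1.0, "M2": met2_ccfs.get("C1", 1.0)}),
            ("C2", "C1", 20,
             {"R1": 0.6, "M1": 1.0, "M2": met2_ccfs.get("C2", 0.0)}),
            ("C3", "C1", 15,
             {"R1": 0.3, "M1": 0.0, "M2": met2_ccfs.get("C3", 0.0)}),
        ],
        [("R1", "primary_region"), ("M1", "primary_LN_satellite"),
         ("M2", "recurrence_progression")],
    )


class TestSampleClonality:
    def test_all_shared_clonal_is_monoclonal(self, late_tree, matrix_of):
        call = dis.classify_dissemination_sample(late_tree, matrix_of(late_tree), "M1")
        assert call.clonality == "monoclonal"
        assert call.origin == "monophyletic"  # forced for monoclonal

    def test_shared_subclonal_cluster_is_polyclonal(self, matrix_of):
        tree = make_tree(
            "T",
            [
                ("C1", ROOT_MARKER, 50, {"R1": 1.0, "M1": 1.0}),
                ("C2", "C1", 20, {"R1": 0.5, "M1": 0.4}),
            ],
            [("R1", "primary_region"), ("M1", "recurrence_progression")],
        )
        call = dis.classify_dissemination_sample(tree, matrix_of(tree), "M1")
        assert call.clonality == "polyclonal"

    def test_root_only_shared_is_monoclonal(self, early_tree, matrix_of):
        # C3 is met-unique, C2 absent from the met: shared = {C1, }
        call = dis.classify_dissemination_sample(
            early_tree, matrix_of(early_tree), "M1"
        )
        assert call.clonality == "monoclonal"


class TestCaseClonality:
    def test_identical_monoclonal_mets_stay_monoclonal(self, matrix_of):
        tree = _two_met_tree({"C1": 1.0, "C2": 1.0})
        call = dis.classify_dissemination_case(tree, matrix_of(tree))
        assert call.clonality == "monoclonal"

    def test_distinct_monoclonal_mets_are_case_polyclonal(self, matrix_of):
        """Each met is monoclonal, but they were founded by different
        clones (different shared sets) -> polyclonal at the case level."""
        tree = _two_met_tree({"C1": 1.0, "C3": 1.0})  # M2 seeded via C3
        matrix = matrix_of(tree)
        for met in ("M1", "M2"):
            assert (
                dis.classify_dissemination_sample(tree, matrix, met).clonality
                == "monoclonal"
            )
        assert dis.classify_dissemination_case(tree, matrix).clonality == "polyclonal"

    def test_restricting_to_one_met_restores_monoclonal(self, matrix_of):
        """Undersampling property: dropping M2 hides the polyclonality."""
        full = _two_met_tree({"C1": 1.0, "C3": 1.0})
        reduced = make_tree(
            "T",
            [
                (c.cluster_id, c.parent_id, c.n_mutations,
                 {k: v for k, v in c.ccf.items() if k != "M2"})
                for c in full.clusters.values()
            ],
            [("R1", "primary_region"), ("M1", "primary_LN_satellite")],
        )
        call = dis.classify_dissemination_case(reduced, classify_clonality(reduced))
        assert call.clonality == "monoclonal"


class TestPhyleticOrigin:
    def test_chain_is_monophyletic(self, chain_tree):
        assert (
            dis.classify_phyletic_origin(chain_tree, ["C1", "C2", "C3"])
            == "monophyletic"
        )

    def test_sibling_branches_are_polyphyletic(self, matrix_of):
        tree = make_tree(
            "T",
            [
                ("C1", ROOT_MARKER, 50, {"R1": 1.0, "M1": 1.0}),
                ("C2", "C1", 20, {"R1": 0.5, "M1": 0.5}),
                ("C3", "C1", 15, {"R1": 0.4, "M1": 0.5}),
            ],
            [("R1", "primary_region"), ("M1", "recurrence_progression")],
        )
        assert dis.classify_phyletic_origin(tree, ["C1", "C2", "C3"]) == "polyphyletic"
        call = dis.classify_dissemination_sample(tree, matrix_of(tree), "M1")
        assert call.clonality == "polyclonal" and call.origin == "polyphyletic"

    def test_consensus_uncertain_when_topologies_disagree(self):
        # default topology: C2 and C3 siblings (polyphyletic);
        # alternate: chain C2 -> C3 (monophyletic)
        topo_sib = {"C1": ROOT_MARKER, "C2": "C1", "C3": "C1"}
        topo_chain = {"C1": ROOT_MARKER, "C2": "C1", "C3": "C2"}
        tree = make_tree(
            "T",
            [
                ("C1", ROOT_MARKER, 50, {"R1": 1.0, "M1": 1.0}),
                ("C2", "C1", 20, {"R1": 0.5, "M1": 0.5}),
                ("C3", "C1", 15, {"R1": 0.4, "M1": 0.5}),
            ],
            [("R1", "primary_region"), ("M1", "recurrence_progression")],
            topologies=[topo_sib, topo_chain],
        )
        matrix = classify_clonality(tree)
        assert dis.consensus_origin(tree, matrix) == "uncertain"


class TestSeedingClusters:
    def test_met_clonal_leaf_is_sole_seeder(self, matrix_of):
        tree = make_tree(
            "T",
            [
                ("C1", ROOT_MARKER, 50, {"R1": 1.0, "M1": 1.0}),
                ("C2", "C1", 20, {"R1": 0.8, "M1": 1.0}),
                ("C3", "C2", 10, {"R1": 0.5, "M1": 1.0}),
            ],
            [("R1", "primary_region"), ("M1", "recurrence_progression")],
        )
        ss = dis.find_seeding_clusters(tree, matrix_of(tree), "M1")
        assert ss.seeding_cluster_ids == ("C3",)
        assert ss.truncal == {"C3": False}

    def test_leaf_up_walk_includes_cca_with_higher_ccf(self, matrix_of):
        """Chain root -> A -> B with B at met CCF 0.4 and A clonal:
        seeding = {A, B}."""
        tree = make_tree(
            "T",
            [
                ("C1", ROOT_MARKER, 50, {"R1": 1.0, "M1": 1.0}),
                ("CA", "C1", 20, {"R1": 0.8, "M1": 1.0}),
                ("CB", "CA", 10, {"R1": 0.5, "M1": 0.4}),
            ],
            [("R1", "primary_region"), ("M1", "recurrence_progression")],
        )
        ss = dis.find_seeding_clusters(tree, matrix_of(tree), "M1")
        assert ss.seeding_cluster_ids == ("CA", "CB")

    def test_branch_ccfs_sum_at_shared_parent(self, matrix_of):
        """Two sibling branches at met CCF 0.5 each under a clonal parent:
        both leaves seed, and the parent (reached with summed CCF 1.0,
        clonal in the met) terminates the walk as a seeder."""
        tree = make_tree(
            "T",
            [
                ("C1", ROOT_MARKER, 50, {"R1": 1.0, "M1": 1.0}),
                ("C2", "C1", 20, {"R1": 0.5, "M1": 0.5}),
                ("C3", "C1", 15, {"R1": 0.4, "M1": 0.5}),
            ],
            [("R1", "primary_region"), ("M1", "recurrence_progression")],
        )
        ss = dis.find_seeding_clusters(tree, matrix_of(tree), "M1")
        assert ss.seeding_cluster_ids == ("C1", "C2", "C3")
        assert ss.truncal["C1"] is True

    def test_equal_ccf_ancestor_not_seeding(self, matrix_of):
        """Strict '>' rule: a non-clonal path ancestor whose met CCF equals
        its child's does not seed."""
        tree = make_tree(
            "T",
            [
                ("C1", ROOT_MARKER, 50, {"R1": 1.0, "M1": 1.0}),
                ("CA", "C1", 20, {"R1": 0.8, "M1": 0.5}),
                ("CB", "CA", 10, {"R1": 0.5, "M1": 0.5}),
            ],
            [("R1", "primary_region"), ("M1", "recurrence_progression")],
        )
        ss = dis.find_seeding_clusters(tree, matrix_of(tree), "M1")
        assert ss.seeding_cluster_ids == ("C1", "CB")

    def test_every_seeding_cluster_is_shared(self, matrix_of):
        cohort_tree = _two_met_tree({"C1": 1.0, "C3": 1.0})
        matrix = matrix_of(cohort_tree)
        for met in ("M1", "M2"):
            ss = dis.find_seeding_clusters(cohort_tree, matrix, met)
            shared = set(dis.shared_clusters(cohort_tree, matrix, met))
            assert set(ss.seeding_cluster_ids) <= shared


class TestCloneProportions:
    def test_leaf_ccf_one_zeroes_all_ancestors(self, matrix_of):
        tree = make_tree(
            "T",
            [
                ("C1", ROOT_MARKER, 50, {"R1": 1.0}),
                ("C2", "C1", 20, {"R1": 1.0}),
                ("C3", "C2", 10, {"R1": 1.0}),
            ],
            [("R1", "primary_region")],
        )
        cp = dis.clone_proportions(tree, "R1", matrix_of(tree))
        assert cp.proportions == {"C1": 0.0, "C2": 0.0, "C3": 1.0}

    def test_leaf_075_leaves_quarter_to_ancestors(self, matrix_of):
        tree = make_tree(
            "T",
            [
                ("C1", ROOT_MARKER, 50, {"R1": 1.0}),
                ("C2", "C1", 20, {"R1": 1.0}),
                ("C3", "C2", 10, {"R1": 0.75}),
            ],
            [("R1", "primary_region")],
        )
        cp = dis.clone_proportions(tree, "R1", matrix_of(tree))
        assert cp.proportions["C3"] == pytest.approx(0.75)
        assert cp.proportions["C1"] + cp.proportions["C2"] == pytest.approx(0.25)

    def test_chain_subtraction(self):
        tree = make_tree(
            "T",
            [
                ("C1", ROOT_MARKER, 50, {"R1": 1.0}),
                ("C2", "C1", 20, {"R1": 0.6}),
                ("C3", "C2", 10, {"R1": 0.2}),
            ],
            [("R1", "primary_region")],
        )
        cp = dis.clone_proportions(tree, "R1")  # no clonal correction
        assert cp.proportions == pytest.approx({"C1": 0.4, "C2": 0.4, "C3": 0.2})

    def test_noisy_negative_clamped_and_renormalised(self):
        tree = make_tree(
            "T",
            [
                ("C1", ROOT_MARKER, 50, {"R1": 0.95}),
                ("C2", "C1", 20, {"R1": 0.6}),
                ("C3", "C1", 10, {"R1": 0.45}),  # children sum 1.05 > 0.95
            ],
            [("R1", "primary_region")],
        )
        cp = dis.clone_proportions(tree, "R1")
        assert all(v >= 0 for v in cp.proportions.values())
        assert sum(cp.proportions.values()) == pytest.approx(1.0)


class TestDispersion:
    @pytest.mark.parametrize(
        "vector, expected",
        [
            ((0.5, 0.5, 0.5), 1.0),  # even spread
            ((0.8, 0.0, 0.0), 0.0),  # region-private
            ((0.6, 0.2, 0.2), 0.6),  # direct formula evaluation
        ],
    )
    def test_worked_values(self, vector, expected):
        assert dis.dispersion_index(vector).dispersion == pytest.approx(expected)

    def test_single_region_undefined(self):
        assert dis.dispersion_index([0.7]).dispersion is None

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0.0, 1.0), min_size=2, max_size=8).filter(
            lambda v: sum(v) > 1e-6
        ),
        st.floats(0.1, 10.0),
    )
    def test_bounded_and_scale_invariant(self, vector, scale):
        d1 = dis.dispersion_index(vector).dispersion
        d2 = dis.dispersion_index([x * scale for x in vector]).dispersion
        assert 0.0 <= d1 <= 1.0 + 1e-12
        assert d1 == pytest.approx(d2)
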