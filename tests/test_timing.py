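"""Divergence timing: phylogenetic, region-based, LOH, WGD, downsampling."""

import pandas as pd
import pytest

from metevol import synth, timing
from metevol.core import ROOT_MARKER, TreeError, classify_clonality
from metevol.io import SegmentSet
from metevol.timing import ArmLOHEvent, WGDCall
from .conftest import make_tree


class TestPrimaryClonal:
    def test_chain_with_regionally_subclonal_cluster(self, chain_tree, matrix_of):
        """Only the root is clonal in every primary region."""
        ids, total = timing.primary_clonal_mutation_count(
            chain_tree, matrix_of(chain_tree)
        )
        assert ids == ["C1"]
        assert total == 50

    def test_all_clusters_clonal(self, matrix_of):
        tree = make_tree(
            "T",
            [
                ("C1", ROOT_MARKER, 10, {"R1": 1.0, "M1": 1.0}),
                ("C2", "C1", 5, {"R1": 1.0, "M1": 1.0}),
            ],
            [("R1", "primary_region"), ("M1", "recurrence_progression")],
        )
        ids, total = timing.primary_clonal_mutation_count(tree, matrix_of(tree))
        assert ids == ["C1", "C2"] and total == 15


class TestPhylogeneticTiming:
    def test_late_when_all_primary_clonal_shared(self, late_tree, matrix_of):
        call = timing.time_divergence_sample(late_tree, matrix_of(late_tree), "M1")
        assert call.label == "late"
        assert call.shared_clonal_fraction == 1.0

    def test_early_when_primary_clonal_absent_from_met(self, early_tree, matrix_of):
        call = timing.time_divergence_sample(early_tree, matrix_of(early_tree), "M1")
        assert call.label == "early"
        assert call.shared_clonal_fraction == pytest.approx(0.6)

    def test_fraction_is_mutation_weighted(self, matrix_of):
        """Two primary-clonal clusters of 60 and 40 mutations; the second is
        subclonal in the met -> shared fraction 0.6."""
        tree = make_tree(
            "T",
            [
                ("C1", ROOT_MARKER, 60, {"R1": 1.0, "M1": 1.0}),
                ("C2", "C1", 40, {"R1": 1.0, "M1": 0.5}),
            ],
            [("R1", "primary_region"), ("M1", "recurrence_progression")],
        )
        call = timing.time_divergence_sample(tree, matrix_of(tree), "M1")
        assert call.shared_clonal_fraction == pytest.approx(0.6)
        assert call.label == "early"

    def test_case_level_any_early_rule(self, matrix_of):
        tree = make_tree(
            "T",
            [
                ("C1", ROOT_MARKER, 60, {"R1": 1.0, "M1": 1.0, "M2": 1.0}),
                ("C2", "C1", 40, {"R1": 1.0, "M1": 1.0, "M2": 0.0}),
            ],
            [("R1", "primary_region"), ("M1", "primary_LN_satellite"),
             ("M2", "recurrence_progression")],
        )
        call = timing.time_divergence_case(tree, matrix_of(tree))
        assert call.label == "early"  # M2 early trumps M1 late

    def test_met_sample_must_not_be_primary(self, late_tree, matrix_of):
        with pytest.raises(ValueError):
            timing.time_divergence_sample(late_tree, matrix_of(late_tree), "R1")


class TestRegionBased:
    @staticmethod
    def _table(rows):
        return pd.DataFrame(rows, columns=["chrom", "pos", "sample_id", "present"])

    def test_loh_filter_and_fraction(self):
        """10 primary-ubiquitous loci, 2 under LOH, 6 of the remaining 8 in
        the met -> 0.75."""
        rows = []
        for i in range(10):
            pos = 100 + i
            for sid in ("R1", "R2"):
                rows.append(("1", pos, sid, 1))
            rows.append(("1", pos, "M1", 1 if i < 6 or i >= 8 else 0))
        # loci 108, 109 fall under an LOH segment in R2
        segments = SegmentSet.from_frame(
            pd.DataFrame(
                [{"chrom": "1", "start": 107, "end": 109, "sample_id": "R2",
                  "allele": "A"}]
            )
        )
        frac = timing.region_based_shared_fraction(
            self._table(rows), segments, "M1", ["R1", "R2"]
        )
        assert frac == pytest.approx(0.75)

    def test_all_loci_under_loh_returns_undefined(self):
        rows = [("1", 100, sid, 1) for sid in ("R1", "M1")]
        segments = SegmentSet.from_frame(
            pd.DataFrame(
                [{"chrom": "1", "start": 0, "end": 1000, "sample_id": "R1",
                  "allele": "A"}]
            )
        )
        assert (
            timing.region_based_shared_fraction(
                self._table(rows), segments, "M1", ["R1"]
            )
            is None
        )

    def test_no_loh_full_sharing(self):
        rows = [("1", 100, sid, 1) for sid in ("R1", "M1")]
        frac = timing.region_based_shared_fraction(
            self._table(rows), None, "M1", ["R1"]
        )
        assert frac == 1.0


class TestLOHTiming:
    def test_all_shared_is_late(self):
        events = [
            ArmLOHEvent(arm, "A", sid, 0.9)
            for arm in ("1p", "17p", "9q")
            for sid in ("R1", "R2", "M1")
        ]
        call = timing.loh_based_timing(events, ["R1", "R2"], "M1")
        assert call.label == "late" and call.shared_clonal_fraction == 1.0

    def test_other_allele_lost_in_met_is_early(self):
        """17p loss of allele A ubiquitous in the primary; the met lost
        allele B instead -> parallel event, early."""
        events = [
            ArmLOHEvent("17p", "A", "R1", 1.0),
            ArmLOHEvent("17p", "A", "R2", 0.8),
            ArmLOHEvent("17p", "B", "M1", 0.9),
        ]
        call = timing.loh_based_timing(events, ["R1", "R2"], "M1")
        assert call.label == "early" and call.shared_clonal_fraction == 0.0

    def test_partial_sharing_fraction(self):
        events = []
        for arm in ("1p", "3p", "9q", "17p"):
            for sid in ("R1", "R2"):
                events.append(ArmLOHEvent(arm, "A", sid, 0.8))
        for arm in ("1p", "3p", "9q"):
            events.append(ArmLOHEvent(arm, "A", "M1", 0.8))
        call = timing.loh_based_timing(events, ["R1", "R2"], "M1")
        assert call.label == "early"
        assert call.shared_clonal_fraction == pytest.approx(0.75)

    def test_sub_threshold_losses_ignored(self):
        events = [ArmLOHEvent("1p", "A", sid, 0.5) for sid in ("R1", "M1")]
        assert timing.loh_based_timing(events, ["R1"], "M1") is None


class TestWGDTiming:
    def test_same_event_late(self):
        calls = [WGDCall(s, True, "w1") for s in ("R1", "R2", "M1")]
        assert timing.wgd_based_timing(calls, ["R1", "R2"], "M1").label == "late"

    def test_met_without_wgd_early(self):
        calls = [WGDCall("R1", True, "w1"), WGDCall("R2", True, "w1"),
                 WGDCall("M1", False)]
        assert timing.wgd_based_timing(calls, ["R1", "R2"], "M1").label == "early"

    def test_parallel_wgd_early(self):
        calls = [WGDCall("R1", True, "w1"), WGDCall("R2", True, "w1"),
                 WGDCall("M1", True, "w2")]
        assert timing.wgd_based_timing(calls, ["R1", "R2"], "M1").label == "early"

    def test_not_applicable_without_clonal_primary_wgd(self):
        calls = [WGDCall("R1", True, "w1"), WGDCall("R2", False),
                 WGDCall("M1", True, "w1")]
        assert timing.wgd_based_timing(calls, ["R1", "R2"], "M1") is None


class TestDownsampling:
    def test_full_set_reproduces_full_sampling_label(self, late_tree, matrix_of):
        res = timing.downsample_timing(late_tree, matrix_of(late_tree), k=2)
        assert res.label_at_k == "late"
        assert res.n_combinations == 1

    def test_clonal_illusion_cluster_flips_single_region_label(self, matrix_of):
        """A cluster clonal in R1 only and absent from the met looks
        primary-clonal at k=1, dragging the mean shared fraction below 1."""
        tree = make_tree(
            "T",
            [
                ("C1", ROOT_MARKER, 50, {"R1": 1.0, "R2": 1.0, "M1": 1.0}),
                ("C2", "C1", 25, {"R1": 0.95, "R2": 0.0, "M1": 0.0}),
            ],
            [("R1", "primary_region"), ("R2", "primary_region"),
             ("M1", "recurrence_progression")],
        )
        matrix = matrix_of(tree)
        assert timing.time_divergence_case(tree, matrix).label == "late"
        res1 = timing.downsample_timing(tree, matrix, k=1)
        assert res1.label_at_k == "early"
        assert res1.mean_shared_fraction < 1.0

    def test_k_out_of_range(self, late_tree, matrix_of):
        with pytest.raises(ValueError):
            timing.downsample_timing(late_tree, matrix_of(late_tree), k=3)

    def test_mean_fraction_non_decreasing_in_k_on_synthetic_late_cases(self):
        cohort = synth.generate_cohort(
            synth.SynthConfig(
                n_cases=12, fraction_early=0.0, fraction_polyclonal=0.2,
                clonal_illusion=True, primary_regions_range=(3, 5), seed=5,
            )
        )
        for tree, _truth in cohort:
            matrix = classify_clonality(tree)
            profile = timing.downsample_profile(tree, matrix)
            fractions = [r.mean_shared_fraction for r in profile]
            assert all(
                b >= a - 1e-12 for a, b in zip(fractions, fractions[1:])
            ), f"{tree.case_id}: {fractions}"
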