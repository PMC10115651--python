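"""Deme-based spatial agent model of tumour growth and metastatic seeding.

The tumour grows on a 3D cubic lattice of demes (carrying capacity 5,000
cells by default) from a single founder cell.  In each synchronous
sweep, every cell of a deme attempts division with probability
``(fitness / max fitness in deme) * (1 - occupancy / capacity)``; an
attempting cell divides with probability ``1 - death_rate`` and dies
with probability ``death_rate``.  A deme exceeding its capacity splits,
half of its cells moving to an empty neighbouring lattice site (or,
when none is adjacent, to the nearest empty site along a random
direction, budging intervening demes outward).

Each division acquires Poisson-distributed new mutations whose fitness
effects are drawn from an asymmetric Laplace distribution centred at 0
and skewed towards deleterious values; rare driver mutations (probability
1e-5) confer a fixed benefit of ten times the global selection
coefficient and switch on susceptibility to large genomic events, whose
broader fitness-effect distribution is applied per division with
probability 0.3 thereafter.

Bookkeeping is at the genotype level (counts of cells per genotype per
deme, never per-cell objects); this is equivalent in distribution to
per-cell semantics and is what makes 1e9-cell tumours representable.
Whole-exome sequencing is emulated per sampled region (Poisson depth,
binomial allele counts with a per-base error rate, and a detection
filter), and timing of metastatic divergence is read out from the
emulated VAFs with the same clonality rule used on real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numba import njit

EARLY = "early"
LATE = "late"

_DIRECTIONS = (
    (1, 0, 0),
    (-1, 0, 0),
    (0, 1, 0),
    (0, -1, 0),
    (0, 0, 1),
    (0, 0, -1),
)

#: Sign probabilities of the asymmetric Laplace fitness-effect
#: distributions, following the continuous-density convention
#: P(positive) = mean_pos / (mean_pos + mean_neg).
P_POSITIVE_MUTATION = 1.0 / 3.0  # means (s/2 positive, s negative)
P_POSITIVE_EVENT = 1.0 / 4.0  # means (s positive, 3s negative)


@dataclass
class SimConfig:
    """Parameters of one simulated tumour.

    ``mutation_rate`` is the expected number of new exome mutations per
    cell division (0.4 and 0.6 are the two study settings; with an
    exome of ~6e7 bp these correspond to per-bp rates of ~6.6e-9 and
    ~1e-8, stored only as bookkeeping).
    """

    deme_capacity: int = 5000
    final_size: int = 1_000_000_000
    death_rate: float = 0.2
    mutation_rate: float = 0.4
    selection_coefficient: float = 0.01
    driver_prob: float = 1e-5
    driver_multiplier: float = 10.0
    event_prob: float = 0.3
    event_pos_mean_mult: float = 2.0
    event_neg_mean_mult: float = 3.0
    exome_size: int = 60_000_000
    n_regions: int = 8
    region_cells: int = 50_000
    depth_mean: float = 400.0
    error_rate: float = 1e-3
    detect_min_alt: int = 2
    detect_min_vaf: float = 0.02
    #: read-simulation floor on the true VAF: variants carried by fewer
    #: cells cannot pass the detection filter at the default depth and
    #: are not read-simulated (keeps the emitted tables bounded)
    min_reported_vaf: float = 0.005
    #: "peripheral": an over-full deme splits only when an empty
    #: neighbouring site exists, so the tumour grows at its surface over
    #: a quiescent core (the classic boundary-growth deme model, which
    #: preserves the spatial sector structure multi-region sampling
    #: relies on); "budge": it also splits by pushing intervening demes
    #: towards the nearest empty site, giving volumetric growth
    growth_mode: str = "peripheral"
    seed: int = 0
    max_extinction_retries: int = 50

    def __post_init__(self) -> None:
        for name in ("death_rate", "driver_prob", "event_prob", "error_rate"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.selection_coefficient < 0:
            raise ValueError("selection_coefficient must be >= 0")
        if self.final_size < self.deme_capacity:
            raise ValueError("final_size must be >= deme_capacity")


class ExtinctionError(RuntimeError):
    """The simulated tumour died out before reaching its target size."""


def draw_fitness_effect(
    s: float,
    kind: str,
    rng: np.random.Generator,
    size: int = 1,
    driver_prob: float = 0.0,
    driver_multiplier: float = 10.0,
    event_pos_mean_mult: float = 2.0,
    event_neg_mean_mult: float = 3.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw fitness effects from the mutation or genomic-event DFE.

    Mutations: exponential branches with means -s (deleterious) and +s/2
    (beneficial); each draw is a driver with probability ``driver_prob``,
    overriding the effect with +``driver_multiplier`` * s.  Events use
    branch means scaled from the mutation DFE (positive x2 -> +s,
    negative x3 -> -3s by default) and are never drivers.  Returns
    (effects, driver_mask); s = 0 gives all-zero effects.
    """
    if s < 0:
        raise ValueError("selection coefficient must be >= 0")
    if kind == "mutation":
        p_pos, pos_mean, neg_mean = P_POSITIVE_MUTATION, s / 2.0, s
    elif kind == "event":
        pos_mean = event_pos_mean_mult * s / 2.0
        neg_mean = event_neg_mean_mult * s
        p_pos = pos_mean / (pos_mean + neg_mean) if s > 0 else P_POSITIVE_EVENT
    else:
        raise ValueError(f"kind must be 'mutation' or 'event', got {kind!r}")
    if s == 0.0:
        return np.zeros(size), np.zeros(size, dtype=bool)
    positive = rng.random(size) < p_pos
    effects = np.where(
        positive,
        rng.exponential(pos_mean, size),
        -rng.exponential(neg_mean, size),
    )
    drivers = np.zeros(size, dtype=bool)
    if kind == "mutation" and driver_prob > 0:
        drivers = rng.random(size) < driver_prob
        effects = np.where(drivers, driver_multiplier * s, effects)
    return effects, drivers


class GenotypeRegistry:
    """Append-only columnar store of clone genotypes.

    Each genotype records its parent genotype, multiplicative fitness,
    lineage depth (number of genotype-creation events since the
    founder), whether structural rearrangements are enabled, and the
    half-open slice ``[mut_offset, mut_offset + mut_count)`` of global
    mutation ids created with it.
    """

    def __init__(self, capacity: int = 1024) -> None:
        self._cap = capacity
        self.parent = np.full(capacity, -1, dtype=np.int64)
        self.fitness = np.ones(capacity, dtype=np.float64)
        self.depth = np.zeros(capacity, dtype=np.int32)
        self.mut_offset = np.zeros(capacity, dtype=np.int64)
        self.mut_count = np.zeros(capacity, dtype=np.int32)
        self.can_rearrange = np.zeros(capacity, dtype=bool)
        self.n = 0
        self.next_mutation_id = 0
        # founder genotype: no mutations, fitness 1, rearrangements off
        self.add_batch(
            np.array([-1], dtype=np.int64),
            np.array([1.0]),
            np.array([0], dtype=np.int64),
            np.array([False]),
        )

    def _ensure(self, extra: int) -> None:
        need = self.n + extra
        if need <= self._cap:
            return
        new_cap = max(need, self._cap * 2)
        for name in ("parent", "fitness", "depth", "mut_offset", "mut_count", "can_rearrange"):
            old = getattr(self, name)
            grown = np.zeros(new_cap, dtype=old.dtype)
            grown[: self.n] = old[: self.n]
            setattr(self, name, grown)
        self._cap = new_cap

    def add_batch(
        self,
        parents: np.ndarray,
        fitness: np.ndarray,
        mut_counts: np.ndarray,
        can_rearrange: np.ndarray,
    ) -> np.ndarray:
        m = len(parents)
        if m == 0:
            return np.empty(0, dtype=np.int64)
        self._ensure(m)
        lo, hi = self.n, self.n + m
        self.parent[lo:hi] = parents
        self.fitness[lo:hi] = fitness
        parent_depth = np.where(parents >= 0, self.depth[np.maximum(parents, 0)], -1)
        self.depth[lo:hi] = parent_depth + 1
        offsets = self.next_mutation_id + np.concatenate(
            ([0], np.cumsum(mut_counts[:-1]))
        )
        self.mut_offset[lo:hi] = offsets
        self.mut_count[lo:hi] = mut_counts
        self.can_rearrange[lo:hi] = can_rearrange
        self.next_mutation_id += int(np.sum(mut_counts))
        self.n = hi
        return np.arange(lo, hi, dtype=np.int64)

    def genotype_of_mutation(self, mutation_ids: np.ndarray) -> np.ndarray:
        """Map global mutation ids to the genotype that created them."""
        offsets = self.mut_offset[: self.n]
        order = np.argsort(offsets, kind="stable")
        idx = np.searchsorted(offsets[order], mutation_ids, side="right") - 1
        return order[idx]


@dataclass
class SimTumor:
    """A growing tumour: demes on a lattice plus the genotype registry."""

    config: SimConfig
    registry: GenotypeRegistry
    rng: np.random.Generator
    demes: dict[tuple[int, int, int], list[np.ndarray]] = field(default_factory=dict)
    totals: dict[tuple[int, int, int], int] = field(default_factory=dict)
    total_cells: int = 0
    history: list[tuple[int, str]] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    @classmethod
    def founder(
        cls,
        config: SimConfig,
        rng: np.random.Generator,
        registry: GenotypeRegistry | None = None,
        founder_counts: dict[int, int] | None = None,
    ) -> "SimTumor":
        registry = registry if registry is not None else GenotypeRegistry()
        counts = founder_counts or {0: 1}
        gids = np.array(sorted(counts), dtype=np.int64)
        n = np.array([counts[g] for g in sorted(counts)], dtype=np.int64)
        tumor = cls(config=config, registry=registry, rng=rng)
        tumor.demes[(0, 0, 0)] = [gids, n]
        tumor.totals[(0, 0, 0)] = int(n.sum())
        tumor.total_cells = int(n.sum())
        return tumor

    def surface_demes(self) -> list[tuple[int, int, int]]:
        """Demes with at least one empty lattice neighbour, sorted."""
        out = []
        for pos in self.demes:
            x, y, z = pos
            if any((x + dx, y + dy, z + dz) not in self.demes for dx, dy, dz in _DIRECTIONS):
                out.append(pos)
        return sorted(out)


# ---------------------------------------------------------------------------
# growth
# ---------------------------------------------------------------------------


@njit(cache=True)
def _binom_scalar(n: int, p: float) -> int:
    # Bernoulli loop beats the generic sampler for the small counts that
    # dominate genotype bookkeeping
    if n <= 16:
        k = 0
        for _ in range(n):
            if np.random.random() < p:
                k += 1
        return k
    return np.random.binomial(n, p)


@njit(cache=True)
def _sweep_counts(
    counts: np.ndarray,
    fit: np.ndarray,
    rearr: np.ndarray,
    deme_ptr: np.ndarray,
    density: np.ndarray,
    death_rate: float,
    p_mut: float,
    event_prob: float,
    seed: int,
) -> np.ndarray:
    """Per-entry division/death/mutation-count draws (updates counts in place).

    For each genotype entry: attempts ~ Binomial(count, fitness-ratio x
    density); of the attempts, deaths ~ Binomial(attempts, death_rate)
    and the rest divide; of the divisions, the returned ``n_new`` are
    daughters acquiring new mutations and/or genomic events (they leave
    the parent genotype and are instantiated by the caller).
    """
    np.random.seed(seed)
    n_entries = counts.size
    n_new = np.zeros(n_entries, dtype=np.int64)
    for d in range(deme_ptr.size - 1):
        lo, hi = deme_ptr[d], deme_ptr[d + 1]
        dens = density[d]
        if dens <= 0.0:
            continue
        fmax = 0.0
        for i in range(lo, hi):
            if fit[i] > fmax:
                fmax = fit[i]
        for i in range(lo, hi):
            p = (fit[i] / fmax) * dens
            a = _binom_scalar(counts[i], p)
            if a == 0:
                continue
            deaths = _binom_scalar(a, death_rate)
            divisions = a - deaths
            nn = 0
            if divisions > 0:
                p_change = 1.0 - (1.0 - p_mut) * (1.0 - event_prob * rearr[i])
                nn = _binom_scalar(divisions, p_change)
            counts[i] += divisions - deaths - nn
            n_new[i] = nn
    return n_new


def _sweep(t: SimTumor) -> None:
    """One synchronous division/death/mutation sweep over all demes."""
    cfg = t.config
    k_cap = cfg.deme_capacity
    rng = t.rng
    reg = t.registry
    active = sorted(pos for pos, tot in t.totals.items() if 0 < tot < k_cap)
    if active:
        lens = np.array([len(t.demes[p][0]) for p in active])
        gids = np.concatenate([t.demes[p][0] for p in active])
        counts = np.concatenate([t.demes[p][1] for p in active]).copy()
        offsets = np.concatenate(([0], np.cumsum(lens)[:-1]))
        deme_ptr = np.concatenate((offsets, [gids.size])).astype(np.int64)
        fit = reg.fitness[gids]
        density = 1.0 - np.array([t.totals[p] for p in active], dtype=float) / k_cap
        rearr = reg.can_rearrange[gids]
        p_mut = -np.expm1(-cfg.mutation_rate)
        n_new = _sweep_counts(
            counts,
            fit,
            rearr.astype(np.float64),
            deme_ptr,
            density,
            cfg.death_rate,
            p_mut,
            cfg.event_prob,
            int(rng.integers(2**31)),
        )
        counts_after = counts
        deme_idx = np.repeat(np.arange(len(active)), lens)

        m_total = int(n_new.sum())
        if m_total:
            parent_g = np.repeat(gids, n_new)
            parent_deme = np.repeat(deme_idx, n_new)  # sorted by construction
            par_rearr = np.repeat(rearr, n_new)
            q = cfg.event_prob * par_rearr
            p_cond = 1.0 - (1.0 - q) * (1.0 - p_mut)
            has_mut = rng.random(m_total) < (p_mut / p_cond)
            has_event = np.where(has_mut, rng.random(m_total) < q, True)
            k = np.where(has_mut, rng.poisson(cfg.mutation_rate, m_total), 0)
            redo = has_mut & (k == 0)
            while redo.any():  # zero-truncated Poisson for mutated daughters
                k[redo] = rng.poisson(cfg.mutation_rate, int(redo.sum()))
                redo = has_mut & (k == 0)
            k = k.astype(np.int64)
            n_muts = int(k.sum())
            log_mult = np.zeros(m_total)
            drv_any = np.zeros(m_total, dtype=bool)
            if n_muts:
                effects, drivers = draw_fitness_effect(
                    cfg.selection_coefficient,
                    "mutation",
                    rng,
                    size=n_muts,
                    driver_prob=cfg.driver_prob,
                    driver_multiplier=cfg.driver_multiplier,
                )
                owner = np.repeat(np.arange(m_total), k)
                log_mult += np.bincount(
                    owner,
                    weights=np.log(np.clip(1.0 + effects, 1e-9, None)),
                    minlength=m_total,
                )
                drv_any = (
                    np.bincount(owner, weights=drivers.astype(float), minlength=m_total)
                    > 0
                )
            ev_idx = np.nonzero(has_event)[0]
            if ev_idx.size:
                ev_eff, _ = draw_fitness_effect(
                    cfg.selection_coefficient,
                    "event",
                    rng,
                    size=ev_idx.size,
                    event_pos_mean_mult=cfg.event_pos_mean_mult,
                    event_neg_mean_mult=cfg.event_neg_mean_mult,
                )
                log_mult[ev_idx] += np.log(np.clip(1.0 + ev_eff, 1e-9, None))
            new_fitness = np.clip(reg.fitness[parent_g] * np.exp(log_mult), 1e-9, None)
            new_rearr = par_rearr | drv_any
            new_ids = reg.add_batch(parent_g, new_fitness, k, new_rearr)
            new_bounds = np.searchsorted(parent_deme, np.arange(len(active) + 1))
        # scatter updated state back into the demes
        for i, pos in enumerate(active):
            sl = slice(offsets[i], offsets[i] + lens[i])
            cs = counts_after[sl]
            gs = gids[sl]
            keep = cs > 0
            gs, cs = gs[keep], cs[keep]
            if m_total:
                lo, hi = new_bounds[i], new_bounds[i + 1]
                if hi > lo:
                    gs = np.concatenate((gs, new_ids[lo:hi]))
                    cs = np.concatenate((cs, np.ones(hi - lo, dtype=np.int64)))
            new_total = int(cs.sum())
            t.total_cells += new_total - t.totals[pos]
            if new_total == 0:
                del t.demes[pos]
                del t.totals[pos]
            else:
                t.demes[pos] = [gs, cs]
                t.totals[pos] = new_total
    # deme fission wherever capacity was reached
    for pos in [p for p, tot in t.totals.items() if tot >= k_cap]:
        _split_deme(t, pos)


def _split_deme(t: SimTumor, pos: tuple[int, int, int]) -> None:
    """Move half of an over-full deme to an empty neighbouring site."""
    rng = t.rng
    x, y, z = pos
    empty = [
        (x + dx, y + dy, z + dz)
        for dx, dy, dz in _DIRECTIONS
        if (x + dx, y + dy, z + dz) not in t.demes
    ]
    if empty:
        target = empty[rng.integers(len(empty))]
    elif t.config.growth_mode == "budge":
        target = _budge(t, pos)
    else:
        return  # peripheral growth: an enclosed deme stays quiescent
    gids, counts = t.demes[pos]
    n_move = t.totals[pos] // 2
    moved = rng.multivariate_hypergeometric(counts, n_move)
    stay = counts - moved
    keep_src = stay > 0
    keep_dst = moved > 0
    t.demes[pos] = [gids[keep_src], stay[keep_src]]
    t.totals[pos] = int(stay.sum())
    t.demes[target] = [gids[keep_dst].copy(), moved[keep_dst]]
    t.totals[target] = int(moved.sum())


def _budge(t: SimTumor, pos: tuple[int, int, int]) -> tuple[int, int, int]:
    """Free the site adjacent to ``pos`` along a random direction.

    Walks outward until an empty lattice site is found and shifts every
    intervening deme one step towards it; returns the freed adjacent
    site.
    """
    dx, dy, dz = _DIRECTIONS[t.rng.integers(len(_DIRECTIONS))]
    x, y, z = pos
    m = 1
    while (x + m * dx, y + m * dy, z + m * dz) in t.demes:
        m += 1
    for i in range(m, 1, -1):
        src = (x + (i - 1) * dx, y + (i - 1) * dy, z + (i - 1) * dz)
        dst = (x + i * dx, y + i * dy, z + i * dz)
        t.demes[dst] = t.demes.pop(src)
        t.totals[dst] = t.totals.pop(src)
    return (x + dx, y + dy, z + dz)


def grow_until(t: SimTumor, target_size: int, max_sweeps: int = 200_000) -> SimTumor:
    """Run sweeps until the tumour reaches ``target_size`` cells."""
    sweeps = 0
    while t.total_cells < target_size:
        if t.total_cells == 0:
            raise ExtinctionError("tumour went extinct")
        _sweep(t)
        sweeps += 1
        if sweeps > max_sweeps:
            raise RuntimeError(f"no convergence after {max_sweeps} sweeps")
    t.history.append((t.total_cells, f"reached {target_size}"))
    return t


def grow_tumor(config: SimConfig) -> SimTumor:
    """Grow a tumour from one founder cell to ``config.final_size``.

    A lineage starting from a single cell goes extinct with positive
    probability; extinct runs are retried with consecutive seeds and the
    retries recorded in provenance.
    """
    for attempt in range(config.max_extinction_retries):
        seed = config.seed + attempt
        rng = np.random.default_rng(seed)
        tumor = SimTumor.founder(config, rng)
        try:
            grow_until(tumor, config.final_size)
        except ExtinctionError:
            continue
        tumor.provenance = {
            "seed": seed,
            "requested_seed": config.seed,
            "extinction_retries": attempt,
            "final_cells": tumor.total_cells,
            "n_genotypes": tumor.registry.n,
            "n_mutations": tumor.registry.next_mutation_id,
        }
        return tumor
    raise ExtinctionError(
        f"extinct in all {config.max_extinction_retries} attempts from seed {config.seed}"
    )


# ---------------------------------------------------------------------------
# metastatic seeding
# ---------------------------------------------------------------------------


def seed_metastasis(
    tumor: SimTumor,
    at_size: int,
    n_cells: int,
    n_source_regions: int = 1,
    met_config: SimConfig | None = None,
) -> SimTumor:
    """Found a metastasis from surface cells of the growing primary.

    The primary is grown (if needed) until it first reaches ``at_size``;
    founder cells are then drawn uniformly from ``n_source_regions``
    randomly chosen surface demes (cells split evenly across sources).
    The returned metastasis shares the primary's genotype registry and
    must be grown explicitly (the primary can continue growing
    afterwards).
    """
    if at_size < n_cells:
        raise ValueError(f"cannot draw {n_cells} founder cells at size {at_size}")
    if tumor.total_cells < at_size:
        grow_until(tumor, at_size)
    rng = tumor.rng
    surface = tumor.surface_demes()
    if not surface:
        surface = sorted(tumor.demes)
    n_src = min(n_source_regions, len(surface))
    sources = [surface[i] for i in rng.choice(len(surface), size=n_src, replace=False)]
    per_source = _even_split(n_cells, n_src)
    founder_counts: dict[int, int] = {}
    for pos, take in zip(sources, per_source):
        gids, counts = tumor.demes[pos]
        take = min(take, int(counts.sum()))
        picked = rng.multivariate_hypergeometric(counts, take)
        for g, c in zip(gids[picked > 0], picked[picked > 0]):
            founder_counts[int(g)] = founder_counts.get(int(g), 0) + int(c)
    met_cfg = met_config if met_config is not None else replace(tumor.config)
    met = SimTumor.founder(
        met_cfg,
        np.random.default_rng(rng.integers(2**31)),
        registry=tumor.registry,
        founder_counts=founder_counts,
    )
    met.provenance = {
        "seeded_at_primary_size": tumor.total_cells,
        "n_founder_cells": n_cells,
        "n_source_regions": n_src,
        "founder_counts": dict(founder_counts),
    }
    tumor.history.append((tumor.total_cells, f"seeded metastasis ({n_cells} cells)"))
    return met


def _even_split(n: int, k: int) -> list[int]:
    base, rem = divmod(n, k)
    return [base + (1 if i < rem else 0) for i in range(k)]


# ---------------------------------------------------------------------------
# region sampling and WES emulation
# ---------------------------------------------------------------------------


def sample_regions(
    tumor: SimTumor, n_regions: int | None = None, region_cells: int | None = None
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Spatially contiguous, disjoint bulk regions of ~``region_cells`` cells.

    Seeds one region per spatial octant around the tumour centroid
    (falling back to random unassigned demes) and grows each by
    breadth-first search over neighbouring demes until it holds the
    requested number of cells.  Returns per-region aggregated
    (genotype_ids, counts).
    """
    cfg = tumor.config
    n_regions = n_regions if n_regions is not None else cfg.n_regions
    region_cells = region_cells if region_cells is not None else cfg.region_cells
    if tumor.total_cells < n_regions * region_cells:
        raise ValueError(
            f"tumour has {tumor.total_cells} cells; need "
            f"{n_regions} x {region_cells}"
        )
    rng = tumor.rng
    # regions emulate peripheral multi-region sampling: seeded on the
    # tumour surface in distinct octants and grown over surface demes
    # first, descending into the bulk only when a patch runs out of
    # unassigned surface neighbours
    surface = set(tumor.surface_demes())
    positions = sorted(surface) if surface else sorted(tumor.demes)
    centroid = np.array(sorted(tumor.demes), dtype=float).mean(axis=0)
    octant = {
        pos: tuple(int(v) for v in (np.array(pos) >= centroid))
        for pos in positions
    }
    by_octant: dict[tuple, list] = {}
    for pos in positions:
        by_octant.setdefault(octant[pos], []).append(pos)
    octant_keys = sorted(by_octant)
    assigned: set = set()
    regions: list[tuple[np.ndarray, np.ndarray]] = []
    for r in range(n_regions):
        bucket = by_octant.get(octant_keys[r % len(octant_keys)], [])
        candidates = [p for p in bucket if p not in assigned]
        if not candidates:
            candidates = [p for p in positions if p not in assigned]
        if not candidates:
            candidates = [p for p in sorted(tumor.demes) if p not in assigned]
        if not candidates:
            raise ValueError("ran out of unassigned demes while sampling regions")
        seed_pos = candidates[rng.integers(len(candidates))]
        # BFS until the region holds enough cells
        frontier = [seed_pos]
        members: list = []
        cells = 0
        while frontier and cells < region_cells:
            pos = frontier.pop(0)
            if pos in assigned:
                continue
            assigned.add(pos)
            members.append(pos)
            cells += tumor.totals[pos]
            x, y, z = pos
            for dx, dy, dz in _DIRECTIONS:
                nb = (x + dx, y + dy, z + dz)
                if nb in surface and nb not in assigned and nb not in frontier:
                    frontier.append(nb)
            if not frontier:
                for pos2 in members:
                    x, y, z = pos2
                    for dx, dy, dz in _DIRECTIONS:
                        nb = (x + dx, y + dy, z + dz)
                        if nb in tumor.demes and nb not in assigned:
                            frontier.append(nb)
        agg: dict[int, int] = {}
        for pos in members:
            gids, counts = tumor.demes[pos]
            for g, c in zip(gids, counts):
                agg[int(g)] = agg.get(int(g), 0) + int(c)
        gid_arr = np.array(sorted(agg), dtype=np.int64)
        cnt_arr = np.array([agg[g] for g in sorted(agg)], dtype=np.int64)
        regions.append((gid_arr, cnt_arr))
    return regions


@dataclass
class RegionVAF:
    """Detected variants of one emulated WES sample."""

    region_id: str
    mutation_id: np.ndarray
    depth: np.ndarray
    alt: np.ndarray
    vaf: np.ndarray
    n_cells: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mutation_id": self.mutation_id,
                "region": self.region_id,
                "depth": self.depth,
                "alt": self.alt,
                "vaf": self.vaf,
            }
        )


def subtree_cell_counts(
    regions: list[tuple[np.ndarray, np.ndarray]], registry: GenotypeRegistry
) -> tuple[np.ndarray, np.ndarray]:
    """Cells per region carrying each genotype's mutations (subtree sums).

    Returns (genotype_ids, matrix) where matrix[i, j] is the number of
    cells in region j whose lineage passes through genotype i — the
    carrier count of every mutation created with genotype i.
    """
    n_geno = registry.n
    known = np.zeros(n_geno, dtype=bool)
    frontier = np.unique(np.concatenate([g for g, _ in regions]))
    known[frontier] = True
    while frontier.size:
        parents = registry.parent[frontier]
        parents = np.unique(parents[parents >= 0])
        new = parents[~known[parents]]
        known[new] = True
        frontier = new
    ids = np.nonzero(known)[0]
    local = np.full(n_geno, -1, dtype=np.int64)
    local[ids] = np.arange(ids.size)
    mat = np.zeros((ids.size, len(regions)), dtype=np.int64)
    for j, (gids, counts) in enumerate(regions):
        np.add.at(mat[:, j], local[gids], counts)
    depths = registry.depth[ids]
    parent_local = np.where(
        registry.parent[ids] >= 0, local[np.maximum(registry.parent[ids], 0)], -1
    )
    for d in range(int(depths.max()), 0, -1):
        sel = np.nonzero(depths == d)[0]
        if sel.size:
            np.add.at(mat, parent_local[sel], mat[sel])
    return ids, mat


def simulate_wes(
    region: tuple[np.ndarray, np.ndarray],
    registry: GenotypeRegistry,
    config: SimConfig,
    rng: np.random.Generator,
    region_id: str = "R1",
    carrier: tuple[np.ndarray, np.ndarray] | None = None,
) -> RegionVAF:
    """Emulate whole-exome sequencing of one bulk region.

    Every mutation is assumed heterozygous on a diploid background, so
    its true VAF is half the carrier-cell fraction.  Per mutation the
    read depth is Poisson(depth_mean) and the alt count binomial at the
    error-adjusted VAF; records failing the detection filter (minimum
    alt reads and observed VAF) are dropped.
    """
    if carrier is None:
        ids, mat = subtree_cell_counts([region], registry)
        carriers = mat[:, 0]
    else:
        ids, carriers = carrier
    total = int(region[1].sum())
    if total == 0:
        raise ValueError("empty region")
    mut_counts = registry.mut_count[ids]
    true_vaf_geno = carriers / (2.0 * total)
    keep = (mut_counts > 0) & (true_vaf_geno >= config.min_reported_vaf)
    ids_k = ids[keep]
    vaf_k = true_vaf_geno[keep]
    k = registry.mut_count[ids_k].astype(np.int64)
    n_mut = int(k.sum())
    # expand genotype slices into individual mutation ids
    starts = registry.mut_offset[ids_k]
    mut_ids = np.repeat(starts, k) + _within_group_arange(k)
    true_vaf = np.repeat(vaf_k, k)
    depth = rng.poisson(config.depth_mean, n_mut)
    eff_vaf = true_vaf * (1.0 - config.error_rate) + (1.0 - true_vaf) * config.error_rate
    alt = rng.binomial(depth, eff_vaf)
    obs_vaf = np.divide(alt, np.maximum(depth, 1), dtype=float)
    detected = (alt >= config.detect_min_alt) & (obs_vaf >= config.detect_min_vaf)
    return RegionVAF(
        region_id=region_id,
        mutation_id=mut_ids[detected],
        depth=depth[detected],
        alt=alt[detected],
        vaf=obs_vaf[detected],
        n_cells=total,
    )


def _within_group_arange(sizes: np.ndarray) -> np.ndarray:
    """[0..s0), [0..s1), ... concatenated."""
    total = int(sizes.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64)
    idx = np.arange(total, dtype=np.int64)
    resets = np.repeat(np.concatenate(([0], np.cumsum(sizes[:-1]))), sizes)
    return idx - resets


def wes_readout(
    tumor: SimTumor,
    n_regions: int | None = None,
    region_cells: int | None = None,
    prefix: str = "R",
) -> list[RegionVAF]:
    """Sample regions and emulate WES for each in one pass."""
    regions = sample_regions(tumor, n_regions, region_cells)
    ids, mat = subtree_cell_counts(regions, tumor.registry)
    return [
        simulate_wes(
            regions[j],
            tumor.registry,
            tumor.config,
            tumor.rng,
            region_id=f"{prefix}{j + 1}",
            carrier=(ids, mat[:, j]),
        )
        for j in range(len(regions))
    ]


# ---------------------------------------------------------------------------
# timing read-out and size conversion
# ---------------------------------------------------------------------------


def classify_sim_timing(
    primary_vafs: list[RegionVAF],
    met_vafs: list[RegionVAF],
    clonal_vaf: float = 0.3,
    clonal_region_fraction: float = 0.9,
) -> str:
    """Early/late divergence from emulated sequencing.

    Mutations with VAF above ``clonal_vaf`` in at least
    ``clonal_region_fraction`` of the primary regions are primary-clonal;
    the pair is late iff every primary-clonal mutation is detected in at
    least one metastasis region, early otherwise.
    """
    if not primary_vafs or not met_vafs:
        raise ValueError("need at least one primary and one metastasis sample")
    n_prim = len(primary_vafs)
    tally: dict[int, int] = {}
    for rv in primary_vafs:
        high = rv.mutation_id[rv.vaf > clonal_vaf]
        for m in high:
            tally[int(m)] = tally.get(int(m), 0) + 1
    need = clonal_region_fraction * n_prim
    clonal = {m for m, c in tally.items() if c >= need - 1e-9}
    if not clonal:
        return LATE
    met_present: set[int] = set()
    for rv in met_vafs:
        met_present.update(int(m) for m in rv.mutation_id)
    return LATE if clonal <= met_present else EARLY


def cells_to_diameter(
    n_cancer_cells: float, purity: float = 1.0, cell_side_um: float = 15.0
) -> float:
    """Tumour diameter in mm from a cancer-cell count.

    Total cellularity is ``n_cancer_cells / purity`` (stromal and immune
    cells contribute volume too); each cell is a cube of side
    ``cell_side_um``; the reported diameter is the side of the
    equivalent cube of the total volume.
    """
    if n_cancer_cells <= 0 or not (0 < purity <= 1) or cell_side_um <= 0:
        raise ValueError("inputs must be positive and purity in (0, 1]")
    total_cells = n_cancer_cells / purity
    return cell_side_um * total_cells ** (1.0 / 3.0) / 1000.0


# ---------------------------------------------------------------------------
# divergence-size experiment
# ---------------------------------------------------------------------------


def run_timing_experiment(
    divergence_sizes: list[int],
    replicates: int = 20,
    config: SimConfig | None = None,
    met_final_size: int | None = None,
    met_config: SimConfig | None = None,
    n_seed_cells: int = 1,
    n_met_regions: int = 2,
    met_region_cells: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Fraction of replicates classified early per divergence size.

    Each replicate grows one primary tumour, founding one metastasis at
    every divergence size as the primary first crosses it (a paired
    design: the metastases of one replicate share their primary).
    Metastases are grown to ``met_final_size`` (default one hundredth of
    the primary's final size), both tumours are region-sampled and
    WES-emulated, and each pair is classified early or late.
    """
    config = config if config is not None else SimConfig()
    sizes = sorted(set(int(s) for s in divergence_sizes))
    if any(s > config.final_size for s in sizes):
        raise ValueError("divergence sizes must not exceed final_size")
    if met_final_size is None:
        met_final_size = max(int(config.final_size // 100), 10 * config.deme_capacity)
    if met_region_cells is None:
        met_region_cells = min(
            config.region_cells, max(met_final_size // (2 * n_met_regions), 1000)
        )
    early_counts = {s: 0 for s in sizes}
    done = {s: 0 for s in sizes}
    rep = 0
    attempts = 0
    while rep < replicates:
        attempts += 1
        if attempts > replicates + config.max_extinction_retries:
            raise ExtinctionError("too many extinct replicates")
        cfg = replace(config, seed=seed + 1000 * attempts)
        rng = np.random.default_rng(cfg.seed)
        primary = SimTumor.founder(cfg, rng)
        mets: dict[int, SimTumor] = {}
        try:
            for s in sizes:
                grow_until(primary, s)
                mets[s] = seed_metastasis(primary, s, n_seed_cells)
            grow_until(primary, cfg.final_size)
        except ExtinctionError:
            continue
        primary_vafs = wes_readout(primary, prefix="P")
        for s in sizes:
            met = mets[s]
            if met_config is not None:
                met.config = replace(met_config, deme_capacity=cfg.deme_capacity)
            founder_counts = met.provenance["founder_counts"]
            grown = False
            for retry in range(cfg.max_extinction_retries):
                try:
                    grow_until(met, met_final_size)
                    grown = True
                    break
                except ExtinctionError:
                    # a metastasis observed in the clinic is one that survived:
                    # re-run the same founder cells with fresh randomness
                    met = SimTumor.founder(
                        met.config,
                        np.random.default_rng(rng.integers(2**31)),
                        registry=primary.registry,
                        founder_counts=founder_counts,
                    )
            if not grown:
                continue
            met_vafs = wes_readout(
                met, n_regions=n_met_regions, region_cells=met_region_cells, prefix="M"
            )
            label = classify_sim_timing(primary_vafs, met_vafs)
            early_counts[s] += label == EARLY
            done[s] += 1
        rep += 1
    rows = [
        {
            "divergence_size": s,
            "n_replicates": done[s],
            "fraction_early": early_counts[s] / done[s] if done[s] else float("nan"),
        }
        for s in sizes
    ]
    return pd.DataFrame(rows)
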