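"""Timing of metastatic divergence relative to the last clonal sweep.

Four orthogonal read-outs are implemented:

* **phylogenetic** — the fraction of mutations in clusters clonal across
  all primary regions that are also clonal in a metastasis sample; a
  fraction below one means a clonal sweep completed in the primary after
  the metastatic lineage branched, i.e. *early* divergence;
* **region-based** — the same idea on raw per-region mutation presence
  calls, with loci under LOH in any sample removed (LOH can delete a
  truly shared mutation from one sample and fake divergence);
* **LOH-based** — primary-ubiquitous arm-level allele-specific LOH
  events act as an irreversible ratchet: a metastasis missing the event
  (or having lost the other allele) must have diverged before it;
* **WGD-based** — same ratchet logic on whole-genome doubling events.

The module also quantifies the *illusion of clonality*: how often a
late-diverging case is misclassified as early when only a subset of the
primary regions is used to define clonal mutations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .core import (
    ClonalityMatrix,
    Clonality,
    ClusterTree,
    SampleKind,
    TreeError,
    group_status,
    subsets,
)

#: Tolerance on "shared clonal fraction < 1".  Fractions are ratios of
#: integer mutation counts, so exact equality holds unless upstream CCF
#: noise flips a clonality call.
EPSILON = 1e-9

EARLY = "early"
LATE = "late"


@dataclass(frozen=True)
class TimingCall:
    level: str  # "sample" | "case"
    target_id: str
    label: str  # "early" | "late"
    shared_clonal_fraction: float
    method: str  # "phylogenetic" | "region_based" | "loh" | "wgd"


@dataclass(frozen=True)
class ArmLOHEvent:
    chrom_arm: str
    lost_allele: str  # "A" | "B"
    sample_id: str
    fraction_arm_lost: float


@dataclass(frozen=True)
class WGDCall:
    sample_id: str
    has_wgd: bool
    wgd_event_id: str | None = None


@dataclass
class DownsampleResult:
    case_id: str
    k_regions: int
    mean_shared_fraction: float
    label_at_k: str
    n_combinations: int
    per_met_fractions: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# phylogenetic method
# ---------------------------------------------------------------------------


def primary_clonal_mutation_count(
    tree: ClusterTree,
    matrix: ClonalityMatrix,
    region_ids: list[str] | None = None,
) -> tuple[list[str], int]:
    """Clusters clonal across all primary regions and their mutation total.

    ``region_ids`` restricts the primary-region set (used by the
    downsampling analysis); default is all primary regions of the case.
    """
    regions = region_ids if region_ids is not None else tree.primary_ids()
    if not regions:
        raise TreeError(f"case {tree.case_id}: no primary regions")
    clonal_ids = [
        cid
        for cid in sorted(tree.clusters)
        if group_status(matrix, cid, regions, group="primary").status
        is Clonality.CLONAL
    ]
    if not clonal_ids:
        raise TreeError(
            f"case {tree.case_id}: no cluster is clonal across primary regions "
            f"{regions} (the root should be; malformed input?)"
        )
    total = sum(tree.clusters[cid].n_mutations for cid in clonal_ids)
    return clonal_ids, total


def shared_clonal_fraction(
    tree: ClusterTree,
    matrix: ClonalityMatrix,
    met_sample: str,
    region_ids: list[str] | None = None,
) -> float:
    """Fraction of primary-clonal mutations that are also clonal in the met."""
    clonal_ids, total = primary_clonal_mutation_count(tree, matrix, region_ids)
    shared = sum(
        tree.clusters[cid].n_mutations
        for cid in clonal_ids
        if matrix.get(cid, met_sample) is Clonality.CLONAL
    )
    return shared / total


def time_divergence_sample(
    tree: ClusterTree, matrix: ClonalityMatrix, met_sample: str
) -> TimingCall:
    """Phylogenetic early/late call for one metastasis sample."""
    sample = tree.samples.get(met_sample)
    if sample is None:
        raise TreeError(f"case {tree.case_id}: unknown sample {met_sample!r}")
    if sample.kind is SampleKind.PRIMARY_REGION:
        raise ValueError(f"{met_sample} is a primary region, not a metastasis")
    fraction = shared_clonal_fraction(tree, matrix, met_sample)
    label = EARLY if fraction < 1.0 - EPSILON else LATE
    return TimingCall(
        level="sample",
        target_id=met_sample,
        label=label,
        shared_clonal_fraction=fraction,
        method="phylogenetic",
    )


def time_divergence_case(tree: ClusterTree, matrix: ClonalityMatrix) -> TimingCall:
    """Case-level call: early iff any metastasis sample diverged early."""
    mets = tree.metastasis_ids()
    if not mets:
        raise TreeError(f"case {tree.case_id}: no metastasis samples")
    calls = [time_divergence_sample(tree, matrix, m) for m in mets]
    label = EARLY if any(c.label == EARLY for c in calls) else LATE
    fraction = min(c.shared_clonal_fraction for c in calls)
    return TimingCall(
        level="case",
        target_id=tree.case_id,
        label=label,
        shared_clonal_fraction=fraction,
        method="phylogenetic",
    )


# ---------------------------------------------------------------------------
# region-based method
# ---------------------------------------------------------------------------


def region_based_shared_fraction(
    mutation_table: pd.DataFrame,
    loh_segments,
    met_sample: str,
    primary_ids: list[str],
) -> float | None:
    """Fraction of LOH-free primary-ubiquitous mutations present in the met.

    ``mutation_table`` is long format with columns chrom, pos (1-based),
    sample_id, present (0/1).  ``loh_segments`` is a
    :class:`metevol.io.SegmentSet` (or None for no filtering): mutation
    loci overlapping an LOH segment in *any* sample are removed before
    the fraction is computed.  Returns None (undefined marker) when no
    primary-ubiquitous mutation survives filtering.
    """
    required = {"chrom", "pos", "sample_id", "present"}
    missing = required - set(mutation_table.columns)
    if missing:
        raise ValueError(f"mutation table missing columns: {sorted(missing)}")
    wide = (
        mutation_table.pivot_table(
            index=["chrom", "pos"], columns="sample_id", values="present", fill_value=0
        )
        .astype(int)
        .sort_index()
    )
    for sid in primary_ids + [met_sample]:
        if sid not in wide.columns:
            wide[sid] = 0
    ubiquitous = wide[(wide[primary_ids] == 1).all(axis=1)]
    if loh_segments is not None and len(ubiquitous):
        # 1-based position p overlaps a 0-based half-open segment [s, e) iff
        # s <= p - 1 < e
        keep = [
            not loh_segments.overlaps_any_sample(chrom, pos - 1)
            for chrom, pos in ubiquitous.index
        ]
        ubiquitous = ubiquitous[keep]
    if len(ubiquitous) == 0:
        return None
    return float((ubiquitous[met_sample] == 1).mean())


# ---------------------------------------------------------------------------
# LOH- and WGD-based methods
# ---------------------------------------------------------------------------


def loh_based_timing(
    arm_loh_events: list[ArmLOHEvent],
    primary_ids: list[str],
    met_sample: str,
) -> TimingCall | None:
    """Early/late from arm-level LOH shared between primary and metastasis.

    An (arm, allele) event is primary-ubiquitous if every primary region
    lost that allele of that arm.  Because LOH cannot be regained, a
    metastasis lacking such an event (or having lost the other allele)
    must have diverged before it occurred.  Returns None when the
    primary has no ubiquitous arm-LOH event (method not applicable).
    """
    by_sample: dict[str, set[tuple[str, str]]] = {}
    for ev in arm_loh_events:
        if ev.fraction_arm_lost < 0.75:  # arm-level loss requires >=75% lost
            continue
        by_sample.setdefault(ev.sample_id, set()).add((ev.chrom_arm, ev.lost_allele))
    ubiquitous: set[tuple[str, str]] | None = None
    for sid in sorted(primary_ids):
        events = by_sample.get(sid, set())
        ubiquitous = events if ubiquitous is None else ubiquitous & events
    if not ubiquitous:
        return None
    met_events = by_sample.get(met_sample, set())
    shared = ubiquitous & met_events
    fraction = len(shared) / len(ubiquitous)
    label = LATE if fraction >= 1.0 - EPSILON else EARLY
    return TimingCall(
        level="sample",
        target_id=met_sample,
        label=label,
        shared_clonal_fraction=fraction,
        method="loh",
    )


def wgd_based_timing(
    wgd_calls: list[WGDCall],
    primary_ids: list[str],
    met_sample: str,
) -> TimingCall | None:
    """Early/late from shared whole-genome doubling identity.

    Applicable only when every primary region carries the *same* WGD
    event (clonal WGD).  The metastasis diverged late iff it carries
    that same event; no WGD, or a parallel independent WGD, implies the
    lineage branched before the primary's doubling.
    """
    by_sample = {c.sample_id: c for c in wgd_calls}
    primary = [by_sample.get(sid) for sid in sorted(primary_ids)]
    if any(c is None or not c.has_wgd for c in primary):
        return None
    event_ids = {c.wgd_event_id for c in primary}
    if len(event_ids) != 1 or None in event_ids:
        return None  # WGD present but not the same clonal event everywhere
    primary_event = event_ids.pop()
    met = by_sample.get(met_sample)
    same = met is not None and met.has_wgd and met.wgd_event_id == primary_event
    return TimingCall(
        level="sample",
        target_id=met_sample,
        label=LATE if same else EARLY,
        shared_clonal_fraction=1.0 if same else 0.0,
        method="wgd",
    )


# ---------------------------------------------------------------------------
# downsampling / illusion of clonality
# ---------------------------------------------------------------------------


def downsample_timing(
    tree: ClusterTree, matrix: ClonalityMatrix, k: int
) -> DownsampleResult:
    """Recompute divergence timing using every k-subset of primary regions.

    For each subset, the primary-clonal cluster set is re-derived within
    the subset and the shared-clonal fraction recomputed per metastasis;
    fractions are averaged over subsets and then over metastasis
    samples.  The case is labelled early at k iff the mean fraction is
    below one.  ``k = n`` (full set) is allowed and reproduces the
    full-sampling call.
    """
    regions = tree.primary_ids()
    n = len(regions)
    if not (1 <= k <= n):
        raise ValueError(f"k={k} out of range [1, {n}]")
    mets = tree.metastasis_ids()
    if not mets:
        raise TreeError(f"case {tree.case_id}: no metastasis samples")
    combos = subsets(regions, k)
    per_met: dict[str, float] = {}
    for met in mets:
        fractions = [
            shared_clonal_fraction(tree, matrix, met, region_ids=list(combo))
            for combo in combos
        ]
        per_met[met] = sum(fractions) / len(fractions)
    mean_fraction = sum(per_met.values()) / len(per_met)
    # any-early convention: a met whose mean fraction is < 1 marks the case
    label = EARLY if any(f < 1.0 - EPSILON for f in per_met.values()) else LATE
    return DownsampleResult(
        case_id=tree.case_id,
        k_regions=k,
        mean_shared_fraction=mean_fraction,
        label_at_k=label,
        n_combinations=math.comb(n, k),
        per_met_fractions=per_met,
    )


def downsample_profile(
    tree: ClusterTree, matrix: ClonalityMatrix, k_max: int | None = None
) -> list[DownsampleResult]:
    """Downsampling results for k = 1 .. n-1 (or up to ``k_max``)."""
    n = len(tree.primary_ids())
    upper = min(k_max, n - 1) if k_max is not None else n - 1
    return [downsample_timing(tree, matrix, k) for k in range(1, upper + 1)]
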