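"""Dissemination patterns, seeding clones, clone proportions, dispersion.

A metastasis is *monoclonal* if every mutation cluster shared between
primary and metastasis is clonal within the metastasis (a single primary
clone founded it), and *polyclonal* if any shared cluster is subclonal
in the metastasis.  The shared clusters' placement on the tree further
splits cases into *monophyletic* (one branch) and *polyphyletic*
(multiple branches); a monoclonal metastasis is monophyletic by
construction.

Seeding clusters are found leaf-up: the most recent shared cluster on
each shared branch demonstrably reached the metastasis and is always
seeding; if it is subclonal in the metastasis the walk ascends towards
the root, adding path ancestors whose metastasis CCF exceeds that of
their path child, until the first met-clonal cluster (always included)
terminates the branch.  Where several shared branches converge on one
parent, their CCFs are summed before the comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .core import (
    ClonalityMatrix,
    Clonality,
    ClusterTree,
    ROOT_MARKER,
    TreeError,
    group_status,
)

MONOCLONAL = "monoclonal"
POLYCLONAL = "polyclonal"
MONOPHYLETIC = "monophyletic"
POLYPHYLETIC = "polyphyletic"
UNCERTAIN = "uncertain"


@dataclass
class DisseminationCall:
    level: str  # "sample" | "case"
    target_id: str
    clonality: str  # monoclonal | polyclonal
    origin: str  # monophyletic | polyphyletic | uncertain
    shared_clusters: dict[str, tuple[str, ...]]  # met sample -> shared set


@dataclass
class SeedingSet:
    met_sample_id: str
    seeding_cluster_ids: tuple[str, ...]
    truncal: dict[str, bool] = field(default_factory=dict)


@dataclass
class CloneProportions:
    sample_id: str
    proportions: dict[str, float]


@dataclass
class DispersionResult:
    cluster_id: str
    n_regions: int
    max_ccf: float
    dispersion: float | None  # None when undefined (single region)


# ---------------------------------------------------------------------------
# shared-cluster bookkeeping
# ---------------------------------------------------------------------------


def shared_clusters(
    tree: ClusterTree, matrix: ClonalityMatrix, met_sample: str
) -> tuple[str, ...]:
    """Clusters present in the primary tumour and in the metastasis sample.

    Presence in the primary is at the tumour level (clonal or subclonal,
    i.e. not absent from every region); presence in the metastasis is at
    the sample level.
    """
    primaries = tree.primary_ids()
    out = []
    for cid in sorted(tree.clusters):
        in_primary = (
            group_status(matrix, cid, primaries, group="primary").status
            is not Clonality.ABSENT
        )
        in_met = matrix.get(cid, met_sample) is not Clonality.ABSENT
        if in_primary and in_met:
            out.append(cid)
    return tuple(out)


def classify_dissemination_sample(
    tree: ClusterTree, matrix: ClonalityMatrix, met_sample: str
) -> DisseminationCall:
    shared = shared_clusters(tree, matrix, met_sample)
    if not shared:
        raise TreeError(
            f"case {tree.case_id}: no shared clusters with {met_sample} "
            "(the root cluster should always be shared)"
        )
    polyclonal = any(
        matrix.get(cid, met_sample) is Clonality.SUBCLONAL for cid in shared
    )
    clonality = POLYCLONAL if polyclonal else MONOCLONAL
    if clonality == MONOCLONAL:
        origin = MONOPHYLETIC  # forced: a single clone is a single branch
    else:
        origin = classify_phyletic_origin(tree, shared)
    return DisseminationCall(
        level="sample",
        target_id=met_sample,
        clonality=clonality,
        origin=origin,
        shared_clusters={met_sample: shared},
    )


def classify_dissemination_case(
    tree: ClusterTree, matrix: ClonalityMatrix
) -> DisseminationCall:
    """Case-level dissemination over all metastasis samples.

    Polyclonal if any sample-level call is polyclonal; if all samples
    are monoclonal, still polyclonal when their shared-cluster sets
    differ (different metastases were founded by different clones).
    """
    mets = tree.metastasis_ids()
    if not mets:
        raise TreeError(f"case {tree.case_id}: no metastasis samples")
    calls = [classify_dissemination_sample(tree, matrix, m) for m in mets]
    shared_by_met = {m: c.shared_clusters[m] for m, c in zip(mets, calls)}
    if any(c.clonality == POLYCLONAL for c in calls):
        clonality = POLYCLONAL
    elif len({frozenset(s) for s in shared_by_met.values()}) > 1:
        clonality = POLYCLONAL
    else:
        clonality = MONOCLONAL
    union = tuple(sorted(set().union(*map(set, shared_by_met.values()))))
    if clonality == MONOCLONAL:
        origin = MONOPHYLETIC
    elif any(c.origin == POLYPHYLETIC for c in calls):
        origin = POLYPHYLETIC
    else:
        origin = classify_phyletic_origin(tree, union)
    return DisseminationCall(
        level="case",
        target_id=tree.case_id,
        clonality=clonality,
        origin=origin,
        shared_clusters=shared_by_met,
    )


def classify_phyletic_origin(
    tree: ClusterTree,
    cluster_ids: Sequence[str],
    topology: Mapping[str, str] | None = None,
) -> str:
    """Monophyletic iff all clusters lie on a single root-to-leaf path."""
    ids = sorted(set(cluster_ids))
    if len(ids) <= 1:
        return MONOPHYLETIC
    # on one path <=> pairwise ancestor-related <=> the deepest cluster's
    # ancestor path covers all others
    deepest = max(ids, key=lambda c: tree.depth(c, topology))
    path = set(tree.ancestors(deepest, topology)) | {deepest}
    return MONOPHYLETIC if all(c in path for c in ids) else POLYPHYLETIC


def consensus_origin(
    tree: ClusterTree, matrix: ClonalityMatrix, met_samples: Sequence[str] | None = None
) -> str:
    """Phyletic origin consensus over all alternate tree topologies.

    Classifies the case-level shared-cluster union on every topology;
    returns the common label, or "uncertain" when topologies disagree.
    """
    mets = list(met_samples) if met_samples is not None else tree.metastasis_ids()
    union: set[str] = set()
    for m in mets:
        union |= set(shared_clusters(tree, matrix, m))
    labels = {
        classify_phyletic_origin(tree, sorted(union), topology=topo)
        for topo in tree.alternate_topologies
    }
    return labels.pop() if len(labels) == 1 else UNCERTAIN


# ---------------------------------------------------------------------------
# seeding clusters (leaf-up walk)
# ---------------------------------------------------------------------------


def find_seeding_clusters(
    tree: ClusterTree, matrix: ClonalityMatrix, met_sample: str
) -> SeedingSet:
    """Identify the clusters whose clones seeded a metastasis sample."""
    shared = set(shared_clusters(tree, matrix, met_sample))
    if not shared:
        raise TreeError(f"case {tree.case_id}: no shared clusters with {met_sample}")
    topo = tree.default_topology
    root_id = tree.root_id

    def met_ccf(cid: str) -> float:
        return tree.ccf(cid, met_sample)

    def met_clonal(cid: str) -> bool:
        return matrix.get(cid, met_sample) is Clonality.CLONAL

    def shared_parent(cid: str) -> str | None:
        """Nearest ancestor that is itself shared (skips unshared gaps)."""
        current = topo.get(cid)
        while current is not None and current != ROOT_MARKER:
            if current in shared:
                return current
            current = topo.get(current)
        return None

    # children count within the shared set (via nearest-shared-ancestor links)
    n_shared_children = {cid: 0 for cid in shared}
    for cid in shared:
        parent = shared_parent(cid)
        if parent is not None:
            n_shared_children[parent] += 1

    order = sorted(shared, key=lambda c: (-tree.depth(c), c))
    carry: dict[str, float] = {}  # summed branch CCF arriving from below
    seeding: set[str] = set()
    for cid in order:
        is_leaf = n_shared_children[cid] == 0
        if is_leaf:
            # deepest shared cluster of the branch: its clone reached the met
            seeding.add(cid)
            if met_clonal(cid):
                continue  # branch terminated
            incoming = met_ccf(cid)
        else:
            if cid not in carry:
                continue  # all child branches terminated below
            incoming = carry.pop(cid)
            if met_clonal(cid):
                # first met-clonal cluster on the path: seeding, walk stops
                seeding.add(cid)
                continue
            if met_ccf(cid) > incoming:
                seeding.add(cid)
            incoming = met_ccf(cid)
        parent = shared_parent(cid)
        if parent is None:
            if cid == root_id:
                raise TreeError(
                    f"case {tree.case_id}: leaf-up walk reached the root without a "
                    f"met-clonal cluster for {met_sample} (root should be clonal)"
                )
            # shared branch detached from root path: terminate here
            continue
        carry[parent] = carry.get(parent, 0.0) + incoming
    ordered = tuple(sorted(seeding))
    return SeedingSet(
        met_sample_id=met_sample,
        seeding_cluster_ids=ordered,
        truncal={cid: cid == root_id for cid in ordered},
    )


# ---------------------------------------------------------------------------
# clone proportions & dispersion
# ---------------------------------------------------------------------------


def clone_proportions(
    tree: ClusterTree,
    sample_id: str,
    matrix: ClonalityMatrix | None = None,
) -> CloneProportions:
    """Per-clone cell-fraction estimates for one sample (leaf-up subtraction).

    A leaf clone's proportion equals its phyloCCF; an internal clone's is
    its phyloCCF minus the summed phyloCCFs of its direct children
    (subtracting all descendants would double-count).  Before the
    subtraction, clusters classified clonal in the sample have their CCF
    corrected to exactly 1 (phyloCCF is a point estimate and clonal
    clusters can deviate from 1), and all CCFs are capped at 1.  Negative
    internal proportions caused by CCF noise are clamped to zero and the
    vector renormalised to sum to one.
    """
    children = tree.children()
    ccf: dict[str, float] = {}
    for cid in sorted(tree.clusters):
        value = min(tree.ccf(cid, sample_id), 1.0)
        if matrix is not None and matrix.get(cid, sample_id) is Clonality.CLONAL:
            value = 1.0
        ccf[cid] = value
    raw: dict[str, float] = {}
    for cid in sorted(tree.clusters):
        kids = children.get(cid, [])
        value = ccf[cid] - sum(ccf[k] for k in kids)
        raw[cid] = max(value, 0.0)
    total = sum(raw.values())
    if total <= 0.0:
        raise TreeError(
            f"case {tree.case_id}: all-zero clone proportions in sample {sample_id}"
        )
    return CloneProportions(
        sample_id=sample_id,
        proportions={cid: v / total for cid, v in sorted(raw.items())},
    )


def dispersion_index(
    ccf_vector: Sequence[float], cluster_id: str = ""
) -> DispersionResult:
    """Clonal dispersion index D = 1 - (max(p_i) - 1/n) / (1 - 1/n).

    ``p_i = x_i / sum(x)`` are the normalised regional CCFs of one
    cluster across the n primary regions.  D is 1 when the clone is
    evenly spread across regions and 0 when it is entirely private to a
    single region.  Undefined (None) for n = 1.
    """
    x = np.asarray(ccf_vector, dtype=float)
    n = x.size
    if n == 0 or np.any(x < 0):
        raise ValueError("CCF vector must be non-empty and non-negative")
    max_ccf = float(x.max())
    if n == 1:
        return DispersionResult(cluster_id, n, max_ccf, None)
    total = x.sum()
    if total <= 0:
        raise ValueError("CCF vector must have a positive sum")
    p = x / total
    d = 1.0 - (float(p.max()) - 1.0 / n) / (1.0 - 1.0 / n)
    return DispersionResult(cluster_id, n, max_ccf, d)


def dispersion_table(
    tree: ClusterTree, subclonal_only: bool = True, matrix: ClonalityMatrix | None = None
) -> list[DispersionResult]:
    """Dispersion index of every (by default subclonal) cluster over primaries."""
    regions = tree.primary_ids()
    out = []
    for cid in sorted(tree.clusters):
        if subclonal_only and matrix is not None:
            status = group_status(matrix, cid, regions).status
            if status is not Clonality.SUBCLONAL:
                continue
        x = [tree.ccf(cid, r) for r in regions]
        if sum(x) <= 0:
            continue
        out.append(dispersion_index(x, cluster_id=cid))
    return out
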