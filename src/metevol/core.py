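"""Core domain types for multi-region tumour phylogenies.

The substrate of every downstream analysis is a rooted tree of mutation
clusters, each carrying a per-sample phylogenetic cancer cell fraction
(phyloCCF) and a mutation count, together with a categorical clonality
matrix (clonal / subclonal / absent) derived from those CCFs.

Samples belong to one of three kinds: primary tumour regions, primary
lymph-node or satellite lesions, and recurrence/progression samples.
The latter two form the "metastasis" group for timing and dissemination
analyses; the first forms the "primary tumour" group.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

ROOT_MARKER = "ROOT"

#: Default per-region clonality thresholds on the phyloCCF point estimate.
#: A cluster is clonal in a region if its CCF is at least ``CLONAL_MIN``,
#: absent if below ``ABSENT_MAX``, and subclonal otherwise.  Both are
#: config-exposed throughout the package.
CLONAL_MIN = 0.9
ABSENT_MAX = 0.05


class SampleKind(str, enum.Enum):
    PRIMARY_REGION = "primary_region"
    PRIMARY_LN_SATELLITE = "primary_LN_satellite"
    RECURRENCE_PROGRESSION = "recurrence_progression"

    @property
    def is_metastasis(self) -> bool:
        return self is not SampleKind.PRIMARY_REGION


class Clonality(str, enum.Enum):
    CLONAL = "clonal"
    SUBCLONAL = "subclonal"
    ABSENT = "absent"


#: Ordering used when reducing over samples ("maximum clonality").
_CLONALITY_RANK = {Clonality.ABSENT: 0, Clonality.SUBCLONAL: 1, Clonality.CLONAL: 2}


def clonality_rank(status: Clonality) -> int:
    return _CLONALITY_RANK[status]


@dataclass(frozen=True)
class Sample:
    sample_id: str
    case_id: str
    kind: SampleKind


@dataclass
class MutationCluster:
    cluster_id: str
    parent_id: str  # ROOT_MARKER for the root cluster
    n_mutations: int
    ccf: dict[str, float] = field(default_factory=dict)  # sample_id -> phyloCCF

    @property
    def is_root(self) -> bool:
        return self.parent_id == ROOT_MARKER


class TreeError(ValueError):
    """Raised for structurally invalid cluster trees or missing entries."""


@dataclass
class ClusterTree:
    """Rooted tree of mutation clusters for one case.

    ``alternate_topologies`` is a list of parent maps (cluster_id ->
    parent_id); the first entry is the default topology and is used by
    every operation unless it explicitly iterates topologies.
    """

    case_id: str
    clusters: dict[str, MutationCluster]
    samples: dict[str, Sample]
    alternate_topologies: list[dict[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.alternate_topologies:
            self.alternate_topologies = [
                {c.cluster_id: c.parent_id for c in self.clusters.values()}
            ]

    # -- accessors ---------------------------------------------------------

    @property
    def default_topology(self) -> dict[str, str]:
        return self.alternate_topologies[0]

    @property
    def root_id(self) -> str:
        roots = [cid for cid, c in self.clusters.items() if c.is_root]
        if len(roots) != 1:
            raise TreeError(
                f"case {self.case_id}: expected exactly one root cluster, found {roots}"
            )
        return roots[0]

    def sample_ids(self, kinds: Iterable[SampleKind] | None = None) -> list[str]:
        """Lexicographically sorted sample ids, optionally filtered by kind."""
        kinds = set(kinds) if kinds is not None else None
        return sorted(
            s.sample_id
            for s in self.samples.values()
            if kinds is None or s.kind in kinds
        )

    def primary_ids(self) -> list[str]:
        return self.sample_ids([SampleKind.PRIMARY_REGION])

    def metastasis_ids(self) -> list[str]:
        return self.sample_ids(
            [SampleKind.PRIMARY_LN_SATELLITE, SampleKind.RECURRENCE_PROGRESSION]
        )

    def ccf(self, cluster_id: str, sample_id: str) -> float:
        try:
            cluster = self.clusters[cluster_id]
        except KeyError:
            raise TreeError(f"case {self.case_id}: unknown cluster {cluster_id!r}")
        try:
            return cluster.ccf[sample_id]
        except KeyError:
            raise TreeError(
                f"case {self.case_id}: cluster {cluster_id!r} has no CCF for "
                f"sample {sample_id!r}"
            )

    def children(self, topology: Mapping[str, str] | None = None) -> dict[str, list[str]]:
        """Children map of a topology (default if None), children sorted by id."""
        topo = topology if topology is not None else self.default_topology
        out: dict[str, list[str]] = {cid: [] for cid in topo}
        for cid in sorted(topo):
            parent = topo[cid]
            if parent != ROOT_MARKER:
                out.setdefault(parent, []).append(cid)
        return out

    def ancestors(self, cluster_id: str, topology: Mapping[str, str] | None = None) -> list[str]:
        """Path of ancestors from the cluster's parent up to the root."""
        topo = topology if topology is not None else self.default_topology
        path: list[str] = []
        seen = set()
        current = topo.get(cluster_id)
        while current is not None and current != ROOT_MARKER:
            if current in seen:
                raise TreeError(f"case {self.case_id}: cycle through {current!r}")
            seen.add(current)
            path.append(current)
            current = topo.get(current)
        return path

    def depth(self, cluster_id: str, topology: Mapping[str, str] | None = None) -> int:
        return len(self.ancestors(cluster_id, topology))


@dataclass
class ClonalityMatrix:
    """Categorical status per (cluster, sample), complete over the case."""

    status: dict[tuple[str, str], Clonality]

    def get(self, cluster_id: str, sample_id: str) -> Clonality:
        try:
            return self.status[(cluster_id, sample_id)]
        except KeyError:
            raise TreeError(
                f"no clonality status for cluster {cluster_id!r}, sample {sample_id!r}"
            )


@dataclass(frozen=True)
class GroupStatus:
    cluster_id: str
    group: str  # "primary" | "metastases" | "custom"
    status: Clonality


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def classify_clonality(
    tree: ClusterTree,
    clonal_min: float = CLONAL_MIN,
    absent_max: float = ABSENT_MAX,
) -> ClonalityMatrix:
    """Classify every (cluster, sample) pair as clonal / subclonal / absent.

    A cluster is clonal in a sample if its phyloCCF is >= ``clonal_min``,
    absent if < ``absent_max``, and subclonal otherwise.  Point-estimate
    overshoots (CCF > 1) are treated as clonal.
    """
    if not (0.0 <= absent_max < clonal_min <= 1.0):
        raise ValueError(
            f"require 0 <= absent_max < clonal_min <= 1, got "
            f"({clonal_min=}, {absent_max=})"
        )
    status: dict[tuple[str, str], Clonality] = {}
    for cid in sorted(tree.clusters):
        for sid in tree.sample_ids():
            ccf = tree.ccf(cid, sid)
            if not (ccf == ccf and abs(ccf) != float("inf")):  # NaN / inf guard
                raise TreeError(
                    f"case {tree.case_id}: non-finite CCF for cluster {cid!r}, "
                    f"sample {sid!r}"
                )
            if ccf >= clonal_min:
                status[(cid, sid)] = Clonality.CLONAL
            elif ccf < absent_max:
                status[(cid, sid)] = Clonality.ABSENT
            else:
                status[(cid, sid)] = Clonality.SUBCLONAL
    return ClonalityMatrix(status)


def group_status(
    matrix: ClonalityMatrix,
    cluster_id: str,
    sample_ids: Sequence[str],
    group: str = "custom",
) -> GroupStatus:
    """Aggregate per-sample clonality over a sample group.

    Clonal iff clonal in every sample of the group; absent iff absent in
    every sample; subclonal otherwise (i.e. subclonal or absent from at
    least one sample, but not absent everywhere).
    """
    if not sample_ids:
        raise ValueError("sample_ids must be non-empty")
    statuses = [matrix.get(cluster_id, sid) for sid in sorted(sample_ids)]
    if all(s is Clonality.CLONAL for s in statuses):
        agg = Clonality.CLONAL
    elif all(s is Clonality.ABSENT for s in statuses):
        agg = Clonality.ABSENT
    else:
        agg = Clonality.SUBCLONAL
    return GroupStatus(cluster_id=cluster_id, group=group, status=agg)


def validate_tree(tree: ClusterTree, sum_rule_tolerance: float = 0.1) -> list[str]:
    """Return a list of violation messages; empty means the tree is valid.

    Hard violations: no or multiple roots, dangling parents, cycles,
    incomplete CCF maps, non-positive mutation counts.  Sum-rule
    violations (children CCFs exceeding the parent's by more than the
    tolerance in some sample) are reported as warnings, prefixed with
    ``"warning:"``, and do not make the tree invalid.
    """
    problems: list[str] = []
    roots = [cid for cid, c in tree.clusters.items() if c.is_root]
    if len(roots) != 1:
        problems.append(f"expected exactly one root cluster, found {sorted(roots)}")
    for cid in sorted(tree.clusters):
        cluster = tree.clusters[cid]
        if cluster.n_mutations < 1:
            problems.append(f"cluster {cid}: n_mutations must be >= 1")
        if not cluster.is_root and cluster.parent_id not in tree.clusters:
            problems.append(f"cluster {cid}: unknown parent {cluster.parent_id!r}")
        for sid in tree.sample_ids():
            if sid not in cluster.ccf:
                problems.append(f"cluster {cid}: missing CCF for sample {sid}")
    # cycle check by walking parents
    for cid in sorted(tree.clusters):
        seen = {cid}
        current = tree.clusters[cid].parent_id
        while current != ROOT_MARKER and current in tree.clusters:
            if current in seen:
                problems.append(f"cycle involving cluster {cid}")
                break
            seen.add(current)
            current = tree.clusters[current].parent_id
    if problems:
        return problems
    # soft sum-rule check (children CCFs should not exceed the parent's)
    children = tree.children()
    for parent, kids in sorted(children.items()):
        if not kids:
            continue
        for sid in tree.sample_ids():
            child_sum = sum(tree.ccf(k, sid) for k in kids)
            if child_sum > tree.ccf(parent, sid) + sum_rule_tolerance:
                problems.append(
                    f"warning: sum-rule violation at cluster {parent}, sample {sid}: "
                    f"children sum {child_sum:.3f} > parent {tree.ccf(parent, sid):.3f} "
                    f"+ tol {sum_rule_tolerance}"
                )
    return problems


def build_tree(
    case_id: str,
    clusters: Iterable[MutationCluster],
    samples: Iterable[Sample],
    alternate_topologies: list[dict[str, str]] | None = None,
) -> ClusterTree:
    """Convenience constructor with id indexing and duplicate checks."""
    cluster_map: dict[str, MutationCluster] = {}
    for c in clusters:
        if c.cluster_id in cluster_map:
            raise TreeError(f"case {case_id}: duplicate cluster id {c.cluster_id!r}")
        cluster_map[c.cluster_id] = c
    sample_map: dict[str, Sample] = {}
    for s in samples:
        if s.sample_id in sample_map:
            raise TreeError(f"case {case_id}: duplicate sample id {s.sample_id!r}")
        sample_map[s.sample_id] = s
    return ClusterTree(
        case_id=case_id,
        clusters=cluster_map,
        samples=sample_map,
        alternate_topologies=alternate_topologies or [],
    )


def subsets(items: Sequence[str], k: int) -> list[tuple[str, ...]]:
    """All k-subsets of items in lexicographic order (deterministic)."""
    return list(itertools.combinations(sorted(items), k))
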