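"""Synthetic cohorts of clone trees with known ground truth.

Every analytic stage of the package needs input whose correct answer is
known by construction.  The generator builds rooted cluster trees with
tree-consistent phyloCCF matrices (clone proportions are drawn first and
CCFs computed as subtree sums, so the sum rule holds exactly before
noise), then manufactures each requested label:

* **late** metastases are seeded from a clone below the trunk terminus,
  so every trunk (primary-clonal) cluster is clonal in the metastasis;
* **early** metastases branch from an internal trunk cluster, leaving
  the later trunk sweeps absent from the metastasis;
* **polyclonal** metastases retain a shared cluster at subclonal CCF;
* **polyphyletic** metastases are seeded from two sibling branches;
* the **clonal illusion** artefact adds a cluster clonal in exactly one
  primary region and absent from the metastases, which flips a late
  case to early under single-region downsampling.

Ground-truth labels are recorded from the construction itself, never by
running the classifiers.  Selection tables with known favouring
enrichment and a bridge from agent-based-model output to cluster-table
inputs are also provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import abm
from .core import (
    ClusterTree,
    MutationCluster,
    ROOT_MARKER,
    Sample,
    SampleKind,
    build_tree,
)

EARLY = "early"
LATE = "late"


@dataclass
class SynthConfig:
    n_cases: int = 20
    clusters_range: tuple[int, int] = (5, 9)
    primary_regions_range: tuple[int, int] = (3, 5)
    mets_range: tuple[int, int] = (1, 2)
    fraction_early: float = 0.3
    fraction_polyclonal: float = 0.3
    fraction_polyphyletic: float = 0.3  # of polyclonal cases
    ccf_noise_sd: float = 0.0
    clonal_illusion: bool = False
    mutations_nb_mean: float = 20.0  # shifted negative binomial, min 1
    mutations_nb_shape: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fraction_early", "fraction_polyclonal", "fraction_polyphyletic"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class GroundTruth:
    case_id: str
    timing_per_met: dict[str, str]
    timing_case: str
    clonality_case: str  # monoclonal | polyclonal
    origin_case: str  # monophyletic | polyphyletic
    seeding_per_met: dict[str, tuple[str, ...]]
    artefacts: list[str] = field(default_factory=list)
    illusion_cluster: str | None = None
    illusion_region: str | None = None


# ---------------------------------------------------------------------------
# single-case generation
# ---------------------------------------------------------------------------


def generate_case(
    config: SynthConfig,
    rng: np.random.Generator,
    case_id: str = "SYN0001",
    force_timing: str | None = None,
    force_polyclonal: bool | None = None,
) -> tuple[ClusterTree, GroundTruth]:
    """One synthetic case with tree, CCFs and construction ground truth."""
    n_clusters = int(rng.integers(config.clusters_range[0], config.clusters_range[1] + 1))
    n_primary = int(
        rng.integers(config.primary_regions_range[0], config.primary_regions_range[1] + 1)
    )
    n_mets = int(rng.integers(config.mets_range[0], config.mets_range[1] + 1))
    want_early = (
        (force_timing == EARLY)
        if force_timing is not None
        else bool(rng.random() < config.fraction_early)
    )
    want_poly = (
        force_polyclonal
        if force_polyclonal is not None
        else bool(rng.random() < config.fraction_polyclonal)
    )
    want_polyphyletic = want_poly and bool(rng.random() < config.fraction_polyphyletic)

    # --- topology: a trunk chain, then uniform attachment below its end ---
    trunk_len = int(rng.integers(2, 4))  # root + 1-2 further clonal sweeps
    trunk = [f"C{i + 1}" for i in range(trunk_len)]
    parent: dict[str, str] = {trunk[0]: ROOT_MARKER}
    for a, b in zip(trunk, trunk[1:]):
        parent[b] = a
    below = [f"C{i + 1}" for i in range(trunk_len, n_clusters)]
    attachable = [trunk[-1]]
    for cid in below:
        parent[cid] = attachable[int(rng.integers(len(attachable)))]
        attachable.append(cid)
    # polyphyletic needs two siblings under a common parent below the trunk
    if want_polyphyletic:
        host = trunk[-1]
        kids = [c for c in below if parent[c] == host]
        while len(kids) < 2:
            extra = f"C{len(parent) + 1}"
            parent[extra] = host
            below.append(extra)
            kids.append(extra)
        sib1, sib2 = kids[0], kids[1]

    samples = [
        Sample(f"{case_id}_R{i + 1}", case_id, SampleKind.PRIMARY_REGION)
        for i in range(n_primary)
    ]
    met_kinds = [SampleKind.PRIMARY_LN_SATELLITE, SampleKind.RECURRENCE_PROGRESSION]
    mets = [
        Sample(f"{case_id}_M{i + 1}", case_id, met_kinds[i % 2]) for i in range(n_mets)
    ]
    primary_ids = [s.sample_id for s in samples]
    met_ids = [s.sample_id for s in mets]

    children: dict[str, list[str]] = {c: [] for c in parent}
    for c, p in parent.items():
        if p != ROOT_MARKER:
            children[p].append(c)

    def subtree(cid: str) -> list[str]:
        out, stack = [], [cid]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(children[node])
        return out

    # --- clonal-illusion cluster (clonal in one region, absent elsewhere) ---
    illusion_cluster = illusion_region = None
    if config.clonal_illusion:
        illusion_cluster = f"C{len(parent) + 1}"
        parent[illusion_cluster] = trunk[-1]
        children[trunk[-1]].append(illusion_cluster)
        children[illusion_cluster] = []
        below.append(illusion_cluster)
        illusion_region = primary_ids[int(rng.integers(n_primary))]

    # at most one early metastasis is constructed (the first); it branches
    # from an internal trunk cluster via a metastasis-unique cluster
    mu_id = None
    divergence_anchor = None
    if want_early:
        i_div = int(rng.integers(0, trunk_len - 1))
        divergence_anchor = trunk[i_div]
        mu_id = f"{case_id}_MU1"
        parent[mu_id] = divergence_anchor
        children[divergence_anchor].append(mu_id)
        children[mu_id] = []

    all_clusters = trunk + below + ([mu_id] if mu_id else [])
    fillable = [c for c in subtree(trunk[-1]) if c not in (illusion_cluster, mu_id)]

    # clusters the construction depends on must be visibly present in the
    # primary tumour; their proportions are boosted in every normal region
    shared_seed_choice = fillable[int(rng.integers(len(fillable)))]
    poly_cands = [c for c in fillable if c != trunk[-1]]
    poly_seed = (
        shared_seed_choice
        if shared_seed_choice != trunk[-1]
        else poly_cands[int(rng.integers(len(poly_cands)))]
    )
    critical = {shared_seed_choice, poly_seed}
    if want_polyphyletic:
        critical |= {sib1, sib2}

    # --- primary-region clone proportions (mass confined below trunk end) ---
    proportions: dict[str, dict[str, float]] = {}
    for sid in primary_ids:
        props = {c: 0.0 for c in all_clusters}
        if sid == illusion_region:
            props[illusion_cluster] = 0.95
            props[trunk[-1]] = 0.05
        else:
            alpha = np.full(len(fillable), 0.6)
            alpha[int(rng.integers(len(fillable)))] = 4.0  # a dominant clone per region
            weights = rng.dirichlet(alpha)
            for idx, c in enumerate(fillable):
                if c in critical:
                    weights[idx] += 0.25
            weights = weights / weights.sum()
            # trunk end keeps a 0.2 floor so no non-trunk cluster can look clonal
            for c, w in zip(fillable, weights):
                props[c] = 0.8 * float(w)
            props[trunk[-1]] += 0.2
        proportions[sid] = props

    # --- per-metastasis clone proportions --------------------------------
    timing_per_met: dict[str, str] = {}
    seeding_per_met: dict[str, tuple[str, ...]] = {}
    for j, sid in enumerate(met_ids):
        met_early = want_early and j == 0
        props = {c: 0.0 for c in all_clusters}
        if met_early:
            anchor = divergence_anchor
            if want_polyphyletic:
                # mass on two sibling branches plus the met-unique branch:
                # later trunk sweeps reach only CCF 0.8 in the met (early),
                # both siblings are shared and subclonal (polyclonal,
                # polyphyletic)
                props[sib1] = 0.4
                props[sib2] = 0.4
                props[mu_id] = 0.2
                seeding_per_met[sid] = tuple(sorted((sib1, sib2, anchor)))
            elif want_poly:
                # half the met below the divergence point, half on a shared
                # cluster below the trunk end -> that cluster is shared and
                # subclonal (polyclonal) while later trunk sweeps stay
                # subclonal in the met (early)
                props[mu_id] = 0.5
                props[poly_seed] = 0.5
                seeding_per_met[sid] = tuple(sorted((poly_seed, anchor)))
            else:
                props[mu_id] = 0.6
                props[anchor] = 0.4
                seeding_per_met[sid] = (anchor,)
            timing_per_met[sid] = EARLY
        else:
            if want_polyphyletic:
                props[sib1] = 0.5
                props[sib2] = 0.5
                seeding_per_met[sid] = tuple(sorted((sib1, sib2, trunk[-1])))
            elif want_poly:
                props[poly_seed] = 0.5
                props[parent[poly_seed]] = 0.5
                seeding_per_met[sid] = tuple(sorted((poly_seed, parent[poly_seed])))
            else:
                props[shared_seed_choice] = 1.0
                seeding_per_met[sid] = (shared_seed_choice,)
            timing_per_met[sid] = LATE
        proportions[sid] = props

    # --- CCFs as subtree proportion sums (sum rule exact) ------------------
    clusters = []
    for cid in all_clusters:
        ccf = {}
        for sid in primary_ids + met_ids:
            props = proportions[sid]
            value = sum(props.get(c, 0.0) for c in subtree(cid))
            if config.ccf_noise_sd > 0:
                value = float(
                    np.clip(value + rng.normal(0.0, config.ccf_noise_sd), 0.0, 1.0)
                )
            ccf[sid] = value
        n_mut = 1 + int(
            rng.negative_binomial(
                config.mutations_nb_shape,
                config.mutations_nb_shape / (config.mutations_nb_shape + config.mutations_nb_mean),
            )
        )
        clusters.append(
            MutationCluster(
                cluster_id=cid, parent_id=parent[cid], n_mutations=n_mut, ccf=ccf
            )
        )
    tree = build_tree(case_id, clusters, samples + mets)

    case_timing = EARLY if EARLY in timing_per_met.values() else LATE
    if want_poly:
        clonality = "polyclonal"
    elif len({frozenset(_shared_from_construction(tree, s)) for s in seeding_per_met.values()}) > 1:
        clonality = "polyclonal"  # distinct monoclonal mets
    else:
        clonality = "monoclonal"
    origin = "polyphyletic" if want_polyphyletic else "monophyletic"
    truth = GroundTruth(
        case_id=case_id,
        timing_per_met=timing_per_met,
        timing_case=case_timing,
        clonality_case=clonality,
        origin_case=origin,
        seeding_per_met=seeding_per_met,
        artefacts=(["clonal_illusion"] if config.clonal_illusion else [])
        + ([f"noise_sd={config.ccf_noise_sd}"] if config.ccf_noise_sd else []),
        illusion_cluster=illusion_cluster,
        illusion_region=illusion_region,
    )
    return tree, truth


def _shared_from_construction(tree: ClusterTree, seeding: tuple[str, ...]) -> frozenset:
    """Shared-cluster set implied by a met's seeding clones (ancestors union)."""
    out: set[str] = set()
    for cid in seeding:
        out.add(cid)
        out.update(tree.ancestors(cid))
    return frozenset(out)


def generate_cohort(config: SynthConfig) -> list[tuple[ClusterTree, GroundTruth]]:
    """A reproducible cohort; label fractions follow the configuration.

    The early and polyclonal fractions are applied deterministically
    (first ``round(f * n)`` cases early, etc., after shuffling ids) so
    small cohorts carry exactly the requested mix.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    n_early = round(config.fraction_early * n)
    n_poly = round(config.fraction_polyclonal * n)
    early_flags = np.zeros(n, dtype=bool)
    early_flags[:n_early] = True
    poly_flags = np.zeros(n, dtype=bool)
    poly_flags[:n_poly] = True
    rng.shuffle(early_flags)
    rng.shuffle(poly_flags)
    out = []
    for i in range(n):
        tree, truth = generate_case(
            config,
            rng,
            case_id=f"SYN{i + 1:04d}",
            force_timing=EARLY if early_flags[i] else LATE,
            force_polyclonal=bool(poly_flags[i]),
        )
        out.append((tree, truth))
    return out


# ---------------------------------------------------------------------------
# selection tables
# ---------------------------------------------------------------------------


def generate_selection_tables(
    n_null_genes: int = 100,
    n_enriched_genes: int = 5,
    background: tuple[float, float, float] = (0.15, 0.15, 0.70),
    enriched_shift: float = 0.5,
    events_per_gene_mean: float = 8.0,
    min_events: int = 5,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-gene favouring-count tables with a known enriched gene set.

    Null genes draw their (met, primary, maintained) counts from the
    background proportions; enriched genes shift ``enriched_shift`` of
    the maintained probability mass onto the metastasis-favoured class.
    Returns (table, true_enriched_genes).
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    bg = np.asarray(background, dtype=float)
    bg = bg / bg.sum()
    shifted = bg.copy()
    moved = enriched_shift * shifted[2]
    shifted[2] -= moved
    shifted[0] += moved
    rows = []
    enriched: list[str] = []
    for i in range(n_null_genes + n_enriched_genes):
        gene = f"GENE{i + 1:04d}"
        probs = bg if i < n_null_genes else shifted
        if i >= n_null_genes:
            enriched.append(gene)
        n_events = min_events + int(rng.poisson(max(events_per_gene_mean - min_events, 0)))
        counts = rng.multinomial(n_events, probs)
        rows.append(
            {
                "gene": gene,
                "n_met_fav": int(counts[0]),
                "n_prim_fav": int(counts[1]),
                "n_maint": int(counts[2]),
                "is_enriched": i >= n_null_genes,
            }
        )
    return pd.DataFrame(rows), enriched


# ---------------------------------------------------------------------------
# bridge from the agent-based model to cluster-table inputs
# ---------------------------------------------------------------------------


def abm_bridge(
    registry: "abm.GenotypeRegistry",
    primary_vafs: list["abm.RegionVAF"],
    met_vafs: list["abm.RegionVAF"],
    case_id: str = "SIM0001",
    min_cluster_ccf: float = 0.05,
) -> ClusterTree:
    """Turn emulated WES read-outs into pipeline-ready cluster-tree input.

    Mutations are grouped by the simulator genotype lineage that created
    them (a stand-in for the external mutation-clustering step, which is
    out of scope here); a pseudo-cluster's per-sample CCF is twice the
    mean VAF of its member mutations (diploid heterozygous convention),
    counting undetected members as VAF 0.  Parent links follow genotype
    ancestry, collapsed over genotypes whose mutations fall below
    ``min_cluster_ccf`` everywhere.  A zero-mutation founder genotype is
    represented by a synthetic truncal root cluster with CCF 1.
    """
    all_vafs = primary_vafs + met_vafs
    if not met_vafs or all(rv.mutation_id.size == 0 for rv in met_vafs):
        raise ValueError("metastasis read-out is empty; nothing to bridge")
    sample_ids = [rv.region_id for rv in all_vafs]
    # per (genotype, sample) mean CCF over member mutations
    ccf_by_geno: dict[int, dict[str, float]] = {}
    for rv in all_vafs:
        if rv.mutation_id.size == 0:
            continue
        genos = registry.genotype_of_mutation(rv.mutation_id)
        frame = pd.DataFrame({"geno": genos, "vaf": 2.0 * rv.vaf})
        sums = frame.groupby("geno")["vaf"].sum()
        for g, total in sums.items():
            ccf_by_geno.setdefault(int(g), {})[rv.region_id] = float(total)
    # normalise by mutation count, counting undetected members as 0
    for g, per_sample in ccf_by_geno.items():
        k = int(registry.mut_count[g])
        for sid in sample_ids:
            per_sample[sid] = min(per_sample.get(sid, 0.0) / k, 1.5)
    kept = sorted(
        g
        for g, per_sample in ccf_by_geno.items()
        if max(per_sample.values()) >= min_cluster_ccf
    )
    if not kept:
        raise ValueError("no genotype cluster passes the CCF floor")

    kept_set = set(kept)

    def cluster_parent(g: int) -> int | None:
        p = int(registry.parent[g])
        while p >= 0:
            if p in kept_set:
                return p
            p = int(registry.parent[p])
        return None

    clusters = []
    root_label = "C0"
    samples = [
        Sample(rv.region_id, case_id, SampleKind.PRIMARY_REGION) for rv in primary_vafs
    ] + [
        Sample(rv.region_id, case_id, SampleKind.RECURRENCE_PROGRESSION)
        for rv in met_vafs
    ]
    clusters.append(
        MutationCluster(
            cluster_id=root_label,
            parent_id=ROOT_MARKER,
            n_mutations=1,
            ccf={sid: 1.0 for sid in sample_ids},
        )
    )
    for g in kept:
        p = cluster_parent(g)
        clusters.append(
            MutationCluster(
                cluster_id=f"G{g}",
                parent_id=root_label if p is None else f"G{p}",
                n_mutations=int(registry.mut_count[g]),
                ccf={sid: ccf_by_geno[g].get(sid, 0.0) for sid in sample_ids},
            )
        )
    return build_tree(case_id, clusters, samples)
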