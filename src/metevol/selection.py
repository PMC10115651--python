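"""Paired primary-metastasis selection analyses.

Covers four layers:

* the paired mutation-cluster favouring truth table (metastasis
  favoured / primary favoured / maintained) and a per-gene multinomial
  goodness-of-fit test of driver-mutation favouring against the
  background proportions observed in non-driver mutations;
* gene-level SCNA event calling relative to sample ploidy and the
  analogous paired favouring classification and test;
* G-score differences between a metastasis and a non-metastatic cohort
  from GISTIC-style segment score tables (neighbour-mean fallback for
  genes in score gaps);
* dN/dS odds-ratio classification of genes from externally supplied
  per-gene estimates (seeding vs non-seeding mutation sets).

dNdScv and GISTIC2.0 themselves are consumed through their standard
output tables, never re-implemented.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import Clonality, clonality_rank

MET_FAVOURED = "metastasis_favoured"
PRIMARY_FAVOURED = "primary_favoured"
MAINTAINED = "maintained"

AMPLIFIED = "amplified"
LOST = "lost"
NEUTRAL = "neutral"

SEEDING_FAVOURED = "seeding_favoured"
BOTH_FAVOURED = "both"
UNDETERMINED = "undetermined"

#: total-event threshold below which the multinomial p-value is computed
#: by full enumeration rather than Monte Carlo
EXACT_ENUMERATION_MAX = 12


@dataclass(frozen=True)
class FavourClass:
    entity: str
    label: str  # metastasis_favoured | primary_favoured | maintained


@dataclass(frozen=True)
class GeneScoreDiff:
    gene: str
    g_score_met: float
    g_score_nonmet: float
    gsd: float
    q_met: float


@dataclass(frozen=True)
class DndsOddsRatio:
    gene: str
    dnds_seeding: float
    dnds_nonseeding: float
    odds_ratio: float | None
    label: str


# ---------------------------------------------------------------------------
# paired mutation classification
# ---------------------------------------------------------------------------


def classify_paired_mutation(
    primary_status: Clonality, met_statuses: Clonality | list[Clonality]
) -> str:
    """Favouring label from tumour-level primary and metastasis clonality.

    Metastasis favoured: absent in the primary and present in the
    metastasis, or subclonal in the primary and clonal in the
    metastasis.  Primary favoured: clonal in the primary and not clonal
    in the metastasis, or subclonal in the primary and absent in the
    metastasis.  Maintained otherwise.  When several metastasis samples
    are supplied the maximum clonality across them is used ("higher
    clonality in metastases").
    """
    if isinstance(met_statuses, Clonality):
        met = met_statuses
    else:
        if not met_statuses:
            raise ValueError("met_statuses must be non-empty")
        met = max(met_statuses, key=clonality_rank)
    p, m = clonality_rank(primary_status), clonality_rank(met)
    if m > p:
        return MET_FAVOURED
    if m < p:
        return PRIMARY_FAVOURED
    return MAINTAINED


# ---------------------------------------------------------------------------
# multinomial goodness-of-fit test
# ---------------------------------------------------------------------------


def multinomial_test(
    counts: np.ndarray | list[int],
    probs: np.ndarray | list[float],
    rng: np.random.Generator | None = None,
    n_draws: int = 100_000,
) -> float:
    """Exact (or seeded Monte-Carlo) multinomial goodness-of-fit p-value.

    The p-value is the probability, under the null proportions, of an
    outcome vector at most as probable as the observed one.  Outcomes
    with total count <= 12 are fully enumerated; larger totals use
    Monte-Carlo with the add-one estimator (so p is never exactly 0).
    """
    counts = np.asarray(counts, dtype=int)
    probs = np.asarray(probs, dtype=float)
    if counts.ndim != 1 or counts.shape != probs.shape:
        raise ValueError("counts and probs must be 1-D and the same length")
    if np.any(counts < 0) or np.any(probs < 0):
        raise ValueError("counts and probs must be non-negative")
    total_p = probs.sum()
    if not math.isclose(total_p, 1.0, rel_tol=1e-9, abs_tol=1e-9):
        probs = probs / total_p
    n = int(counts.sum())
    if n == 0:
        return 1.0
    dist = stats.multinomial(n, probs)
    p_obs = float(dist.pmf(counts))
    # numeric slack: outcomes exactly as probable as the observed one count
    cutoff = p_obs * (1.0 + 1e-9)
    k = counts.size
    if n <= EXACT_ENUMERATION_MAX:
        p_val = 0.0
        for combo in _compositions(n, k):
            p_c = float(dist.pmf(combo))
            if p_c <= cutoff:
                p_val += p_c
        return min(p_val, 1.0)
    if rng is None:
        rng = np.random.default_rng(0)
    draws = rng.multinomial(n, probs, size=n_draws)
    p_draws = dist.pmf(draws)
    hits = int(np.sum(p_draws <= cutoff))
    return (hits + 1) / (n_draws + 1)


def _compositions(n: int, k: int):
    """All k-part compositions of n (ordered, includes zeros)."""
    for dividers in itertools.combinations(range(n + k - 1), k - 1):
        prev = -1
        combo = []
        for d in dividers:
            combo.append(d - prev - 1)
            prev = d
        combo.append(n + k - 2 - prev)
        yield combo


def paired_mutation_test(
    gene_counts: pd.DataFrame,
    background: tuple[float, float, float] | np.ndarray,
    min_events: int = 5,
    rng: np.random.Generator | None = None,
    n_draws: int = 100_000,
) -> pd.DataFrame:
    """Per-gene multinomial test of favouring counts against the background.

    ``gene_counts`` columns: gene, n_met_fav, n_prim_fav, n_maint.
    ``background`` is the (met, primary, maintained) proportion triple
    from non-driver mutations.  Genes with fewer than ``min_events``
    driver mutations are skipped.  Benjamini-Hochberg q-values are
    computed across the tested genes.
    """
    required = {"gene", "n_met_fav", "n_prim_fav", "n_maint"}
    missing = required - set(gene_counts.columns)
    if missing:
        raise ValueError(f"gene_counts missing columns: {sorted(missing)}")
    bg = np.asarray(background, dtype=float)
    bg = bg / bg.sum()
    rows = []
    for rec in gene_counts.sort_values("gene").itertuples(index=False):
        counts = np.array([rec.n_met_fav, rec.n_prim_fav, rec.n_maint], dtype=int)
        total = int(counts.sum())
        if total < min_events:
            continue
        p = multinomial_test(counts, bg, rng=rng, n_draws=n_draws)
        rows.append(
            {
                "gene": rec.gene,
                "n_met_fav": counts[0],
                "n_prim_fav": counts[1],
                "n_maint": counts[2],
                "n_events": total,
                "bg_met_fav": bg[0],
                "bg_prim_fav": bg[1],
                "bg_maint": bg[2],
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    else:
        out["q_value"] = pd.Series(dtype=float)
    return out


def background_proportions(labels: pd.Series) -> tuple[float, float, float]:
    """(met, primary, maintained) proportions from per-mutation labels."""
    n = len(labels)
    if n == 0:
        raise ValueError("no background mutations")
    return (
        float((labels == MET_FAVOURED).sum()) / n,
        float((labels == PRIMARY_FAVOURED).sum()) / n,
        float((labels == MAINTAINED).sum()) / n,
    )


# ---------------------------------------------------------------------------
# SCNA layer
# ---------------------------------------------------------------------------


def call_scna_event(
    cn: float, ploidy: float, log2_threshold: float = 0.5, eps: float = 0.01
) -> str:
    """Amplified / lost / neutral relative to the sample ploidy.

    Amplified if log2(CN / ploidy) > threshold, lost if
    log2((CN + eps) / ploidy) < -threshold, else neutral.
    """
    if ploidy <= 0:
        raise ValueError("ploidy must be positive")
    if cn < 0:
        raise ValueError("copy number must be non-negative")
    if cn > 0 and math.log2(cn / ploidy) > log2_threshold:
        return AMPLIFIED
    if math.log2((cn + eps) / ploidy) < -log2_threshold:
        return LOST
    return NEUTRAL


def classify_paired_scna(
    gene: str,
    event_type: str,
    primary_calls: list[str],
    met_calls: list[str],
) -> FavourClass | None:
    """Paired favouring of one SCNA event type (amplified or lost) per gene.

    The event is "present" in a sample group when called in at least
    one sample of the group.  Returns None when the event is absent from
    both groups (the tumour is not counted for this gene).
    """
    if event_type not in (AMPLIFIED, LOST):
        raise ValueError(f"event_type must be amplified or lost, got {event_type!r}")
    in_primary = event_type in primary_calls
    in_met = event_type in met_calls
    if not in_primary and not in_met:
        return None
    if in_primary and in_met:
        label = MAINTAINED
    elif in_primary:
        label = PRIMARY_FAVOURED
    else:
        label = MET_FAVOURED
    return FavourClass(entity=gene, label=label)


def paired_scna_test(
    tumour_classes: pd.DataFrame,
    background: tuple[float, float, float],
    min_tumours: int = 5,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-gene multinomial test of paired SCNA favouring counts.

    ``tumour_classes`` columns: gene, label (one row per tumour with an
    event in the gene).  Genes with events in fewer than ``min_tumours``
    tumours are skipped.
    """
    rows = []
    for gene, sub in tumour_classes.groupby("gene", sort=True):
        counts = np.array(
            [
                (sub["label"] == MET_FAVOURED).sum(),
                (sub["label"] == PRIMARY_FAVOURED).sum(),
                (sub["label"] == MAINTAINED).sum(),
            ],
            dtype=int,
        )
        rows.append(
            {
                "gene": gene,
                "n_met_fav": counts[0],
                "n_prim_fav": counts[1],
                "n_maint": counts[2],
                "n_events": int(counts.sum()),
            }
        )
    table = pd.DataFrame(rows)
    return paired_mutation_test(table, background, min_events=min_tumours, rng=rng)


def gscore_difference(
    gistic_met: pd.DataFrame,
    gistic_nonmet: pd.DataFrame,
    gene_coords: pd.DataFrame,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-gene G-score difference between metastasis and non-met cohorts.

    Score tables have columns chrom, start, end, g_score, q (0-based
    half-open segments); ``gene_coords`` has gene, chrom, start, end.
    A gene overlapping one or more segments gets the length-weighted
    mean G-score of the overlaps; a gene falling in a gap gets the mean
    of its two neighbouring segments' scores.  Output is restricted to
    genes significant (q < ``q_threshold``) in the metastasis cohort;
    genes on chromosomes absent from either table are skipped.
    """
    rows = []
    for rec in gene_coords.sort_values("gene").itertuples(index=False):
        met = _gene_score(gistic_met, rec.chrom, rec.start, rec.end)
        nonmet = _gene_score(gistic_nonmet, rec.chrom, rec.start, rec.end)
        if met is None or nonmet is None:
            continue
        score_met, q_met = met
        score_nonmet, _ = nonmet
        if q_met >= q_threshold:
            continue
        rows.append(
            GeneScoreDiff(
                gene=rec.gene,
                g_score_met=score_met,
                g_score_nonmet=score_nonmet,
                gsd=score_met - score_nonmet,
                q_met=q_met,
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])


def _gene_score(
    table: pd.DataFrame, chrom: str, start: int, end: int
) -> tuple[float, float] | None:
    """(G-score, q) for a gene interval; neighbour mean in score gaps."""
    sub = table[table["chrom"].astype(str) == str(chrom)]
    if sub.empty:
        return None
    sub = sub.sort_values("start")
    overlap = np.minimum(sub["end"].to_numpy(), end) - np.maximum(
        sub["start"].to_numpy(), start
    )
    mask = overlap > 0
    if mask.any():
        w = overlap[mask].astype(float)
        scores = sub["g_score"].to_numpy()[mask]
        qs = sub["q"].to_numpy()[mask]
        return float(np.average(scores, weights=w)), float(qs.min())
    left = sub[sub["end"] <= start]
    right = sub[sub["start"] >= end]
    neighbours = []
    qs = []
    if len(left):
        neighbours.append(float(left.iloc[-1]["g_score"]))
        qs.append(float(left.iloc[-1]["q"]))
    if len(right):
        neighbours.append(float(right.iloc[0]["g_score"]))
        qs.append(float(right.iloc[0]["q"]))
    if not neighbours:
        return None
    return float(np.mean(neighbours)), float(min(qs))


# ---------------------------------------------------------------------------
# dN/dS odds ratios
# ---------------------------------------------------------------------------


def dnds_odds_ratio(
    estimates_seeding: pd.DataFrame,
    estimates_nonseeding: pd.DataFrame,
    q_threshold: float = 0.1,
    upper: float = 2.0,
    lower: float = 0.5,
) -> pd.DataFrame:
    """Classify genes by the seeding / non-seeding dN/dS odds ratio.

    Input tables have columns gene, dnds (point estimate, missense +
    truncating combined) and optionally q (global q-value).  The odds
    ratio is dnds_seeding / dnds_nonseeding; OR > 2 is seeding favoured,
    OR < 0.5 primary favoured, in between both.  Genes are reported when
    q < ``q_threshold`` in either input (when q columns are present).
    Zero or undefined denominators yield the label "undetermined".
    """
    left = estimates_seeding.rename(columns={"dnds": "dnds_seeding", "q": "q_seeding"})
    right = estimates_nonseeding.rename(
        columns={"dnds": "dnds_nonseeding", "q": "q_nonseeding"}
    )
    merged = left.merge(right, on="gene", how="inner").sort_values("gene")
    rows = []
    for rec in merged.itertuples(index=False):
        qs = [
            getattr(rec, "q_seeding", np.nan),
            getattr(rec, "q_nonseeding", np.nan),
        ]
        qs = [q for q in qs if q == q]
        if qs and min(qs) >= q_threshold:
            continue
        denom = rec.dnds_nonseeding
        if denom is None or denom != denom or denom <= 0:
            odds, label = None, UNDETERMINED
        else:
            odds = rec.dnds_seeding / denom
            if odds > upper:
                label = SEEDING_FAVOURED
            elif odds < lower:
                label = PRIMARY_FAVOURED
            else:
                label = BOTH_FAVOURED
        rows.append(
            DndsOddsRatio(
                gene=rec.gene,
                dnds_seeding=rec.dnds_seeding,
                dnds_nonseeding=rec.dnds_nonseeding,
                odds_ratio=odds,
                label=label,
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])
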