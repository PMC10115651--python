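"""Readers and writers for the package's table dialects, plus provenance.

Conventions: cluster and mutation tables are TSV; genomic segment files
are BED-like TSV with 0-based half-open coordinates; mutation positions
are 1-based (VCF-like).  All writers sort their keys so outputs are
byte-identical under identical seed and configuration.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import (
    ClusterTree,
    MutationCluster,
    ROOT_MARKER,
    Sample,
    SampleKind,
    TreeError,
    build_tree,
    validate_tree,
)

CLUSTER_COLUMNS = ["case_id", "cluster_id", "parent_id", "n_mutations", "sample_id", "ccf"]
SAMPLE_COLUMNS = ["case_id", "sample_id", "kind"]
TOPOLOGY_COLUMNS = ["case_id", "topology_id", "cluster_id", "parent_id"]
SEGMENT_COLUMNS = ["chrom", "start", "end", "sample_id", "allele"]


# ---------------------------------------------------------------------------
# cluster / sample tables
# ---------------------------------------------------------------------------


def read_cluster_table(
    cluster_path: str | Path,
    sample_path: str | Path,
    topology_path: str | Path | None = None,
    validate: bool = True,
) -> dict[str, ClusterTree]:
    """Load cluster trees (one per case) from the long-format TSV dialect."""
    clusters = pd.read_csv(cluster_path, sep="\t", dtype={"chrom": str})
    samples = pd.read_csv(sample_path, sep="\t")
    for frame, cols, name in (
        (clusters, CLUSTER_COLUMNS, "cluster"),
        (samples, SAMPLE_COLUMNS, "sample"),
    ):
        missing = set(cols) - set(frame.columns)
        if missing:
            raise ValueError(f"{name} table missing columns: {sorted(missing)}")
    dup = clusters.duplicated(subset=["case_id", "cluster_id", "sample_id"])
    if dup.any():
        first = clusters[dup].iloc[0]
        raise ValueError(
            f"duplicate (case, cluster, sample) row: "
            f"({first.case_id}, {first.cluster_id}, {first.sample_id})"
        )
    bad = clusters[(clusters["ccf"] < 0) | (clusters["ccf"] > 2.0)]
    if len(bad):
        first = bad.iloc[0]
        raise ValueError(
            f"CCF outside [0, 2] for case {first.case_id}, cluster "
            f"{first.cluster_id}, sample {first.sample_id}: {first.ccf}"
        )
    topologies: dict[str, list[dict[str, str]]] = {}
    if topology_path is not None:
        topo = pd.read_csv(topology_path, sep="\t")
        missing = set(TOPOLOGY_COLUMNS) - set(topo.columns)
        if missing:
            raise ValueError(f"topology table missing columns: {sorted(missing)}")
        for (case, _tid), sub in topo.groupby(["case_id", "topology_id"], sort=True):
            topologies.setdefault(str(case), []).append(
                {str(r.cluster_id): str(r.parent_id) for r in sub.itertuples()}
            )
    trees: dict[str, ClusterTree] = {}
    for case, sub in clusters.groupby("case_id", sort=True):
        case = str(case)
        sample_sub = samples[samples["case_id"] == case]
        sample_objs = [
            Sample(str(r.sample_id), case, SampleKind(r.kind))
            for r in sample_sub.itertuples()
        ]
        cluster_objs = []
        for cid, crows in sub.groupby("cluster_id", sort=True):
            parents = crows["parent_id"].astype(str).unique()
            n_muts = crows["n_mutations"].unique()
            if len(parents) != 1 or len(n_muts) != 1:
                raise ValueError(
                    f"case {case}, cluster {cid}: inconsistent parent or "
                    "mutation count across rows"
                )
            cluster_objs.append(
                MutationCluster(
                    cluster_id=str(cid),
                    parent_id=str(parents[0]),
                    n_mutations=int(n_muts[0]),
                    ccf={
                        str(r.sample_id): float(r.ccf) for r in crows.itertuples()
                    },
                )
            )
        tree = build_tree(
            case, cluster_objs, sample_objs, alternate_topologies=topologies.get(case)
        )
        if validate:
            hard = [v for v in validate_tree(tree) if not v.startswith("warning:")]
            if hard:
                raise TreeError(f"case {case}: " + "; ".join(hard))
        trees[case] = tree
    return trees


def write_cluster_table(
    trees: dict[str, ClusterTree] | list[ClusterTree],
    cluster_path: str | Path,
    sample_path: str | Path,
) -> None:
    """Write trees back to the long-format TSV dialect (round-trip safe)."""
    if isinstance(trees, dict):
        trees = [trees[k] for k in sorted(trees)]
    cluster_rows = []
    sample_rows = []
    for tree in trees:
        for sid in tree.sample_ids():
            sample_rows.append(
                {
                    "case_id": tree.case_id,
                    "sample_id": sid,
                    "kind": tree.samples[sid].kind.value,
                }
            )
        for cid in sorted(tree.clusters):
            c = tree.clusters[cid]
            for sid in tree.sample_ids():
                cluster_rows.append(
                    {
                        "case_id": tree.case_id,
                        "cluster_id": cid,
                        "parent_id": c.parent_id,
                        "n_mutations": c.n_mutations,
                        "sample_id": sid,
                        "ccf": c.ccf[sid],
                    }
                )
    pd.DataFrame(cluster_rows, columns=CLUSTER_COLUMNS).to_csv(
        cluster_path, sep="\t", index=False
    )
    pd.DataFrame(sample_rows, columns=SAMPLE_COLUMNS).to_csv(
        sample_path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# genomic segments
# ---------------------------------------------------------------------------


def _normalise_chrom(chrom: str) -> str:
    chrom = str(chrom)
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


@dataclass
class SegmentSet:
    """Per-sample genomic segments with point-overlap queries.

    Coordinates are 0-based half-open; chromosome names are normalised
    (leading ``chr`` stripped) on load.
    """

    table: pd.DataFrame  # chrom, start, end, sample_id, allele

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SegmentSet":
        missing = {"chrom", "start", "end", "sample_id"} - set(frame.columns)
        if missing:
            raise ValueError(f"segment table missing columns: {sorted(missing)}")
        frame = frame.copy()
        if "allele" not in frame.columns:
            frame["allele"] = "A"
        bad = frame[frame["start"] >= frame["end"]]
        if len(bad):
            first = bad.iloc[0]
            raise ValueError(
                f"segment with start >= end: {first.chrom}:{first.start}-{first.end}"
            )
        frame["chrom"] = frame["chrom"].map(_normalise_chrom)
        frame = frame.sort_values(["sample_id", "chrom", "start"]).reset_index(drop=True)
        return cls(frame)

    def overlaps(self, sample_id: str, chrom: str, pos0: int) -> bool:
        chrom = _normalise_chrom(chrom)
        sub = self.table[
            (self.table["sample_id"] == sample_id) & (self.table["chrom"] == chrom)
        ]
        return bool(((sub["start"] <= pos0) & (pos0 < sub["end"])).any())

    def overlaps_any_sample(self, chrom: str, pos0: int) -> bool:
        chrom = _normalise_chrom(chrom)
        sub = self.table[self.table["chrom"] == chrom]
        return bool(((sub["start"] <= pos0) & (pos0 < sub["end"])).any())


def read_segments(path: str | Path) -> SegmentSet:
    return SegmentSet.from_frame(pd.read_csv(path, sep="\t", dtype={"chrom": str}))


def merge_segments(frame: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/adjacent same-(sample, chrom, allele) segments."""
    rows = []
    frame = frame.copy()
    frame["chrom"] = frame["chrom"].map(_normalise_chrom)
    for (sid, chrom, allele), sub in frame.groupby(
        ["sample_id", "chrom", "allele"], sort=True
    ):
        sub = sub.sort_values("start")
        current = None
        for rec in sub.itertuples(index=False):
            if current is None:
                current = [rec.start, rec.end]
            elif rec.start <= current[1]:
                current[1] = max(current[1], rec.end)
            else:
                rows.append(
                    {"chrom": chrom, "start": current[0], "end": current[1],
                     "sample_id": sid, "allele": allele}
                )
                current = [rec.start, rec.end]
        if current is not None:
            rows.append(
                {"chrom": chrom, "start": current[0], "end": current[1],
                 "sample_id": sid, "allele": allele}
            )
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def arm_loh_events(
    segments: pd.DataFrame, arm_table: pd.DataFrame, min_fraction: float = 0.75
):
    """Arm-level LOH events from per-sample lost-allele segments.

    ``segments`` columns: chrom, start, end, sample_id, allele (the lost
    allele); ``arm_table`` columns: chrom, arm, start, end.  An event is
    emitted when at least ``min_fraction`` of an arm is covered by
    same-allele loss in a sample.
    """
    from .timing import ArmLOHEvent

    merged = merge_segments(segments)
    arm_table = arm_table.copy()
    arm_table["chrom"] = arm_table["chrom"].map(_normalise_chrom)
    events = []
    for arm_rec in arm_table.sort_values(["chrom", "arm"]).itertuples(index=False):
        arm_len = arm_rec.end - arm_rec.start
        sub = merged[merged["chrom"] == arm_rec.chrom]
        for (sid, allele), rows in sub.groupby(["sample_id", "allele"], sort=True):
            covered = 0
            for seg in rows.itertuples(index=False):
                covered += max(
                    0, min(seg.end, arm_rec.end) - max(seg.start, arm_rec.start)
                )
            fraction = covered / arm_len
            if fraction >= min_fraction:
                events.append(
                    ArmLOHEvent(
                        chrom_arm=f"{arm_rec.chrom}{arm_rec.arm}",
                        lost_allele=str(allele),
                        sample_id=str(sid),
                        fraction_arm_lost=fraction,
                    )
                )
    return events


# ---------------------------------------------------------------------------
# result writers
# ---------------------------------------------------------------------------


def write_clone_proportions(proportions: list, path: str | Path) -> None:
    """MACHINA-compatible labelling TSV (sample, cluster, proportion)."""
    rows = [
        {"sample_id": cp.sample_id, "cluster_id": cid, "proportion": value}
        for cp in proportions
        for cid, value in sorted(cp.proportions.items())
    ]
    pd.DataFrame(rows, columns=["sample_id", "cluster_id", "proportion"]).to_csv(
        path, sep="\t", index=False
    )


def to_newick(tree: ClusterTree) -> str:
    """Newick string of the default topology (cluster ids as labels)."""
    children = tree.children()

    def render(cid: str) -> str:
        kids = children.get(cid, [])
        if not kids:
            return cid
        return "(" + ",".join(render(k) for k in kids) + ")" + cid

    return render(tree.root_id) + ";"


# ---------------------------------------------------------------------------
# provenance
# ---------------------------------------------------------------------------


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_provenance(
    out_dir: str | Path,
    command: str,
    config: dict,
    input_paths: list[str | Path] | None = None,
    seed: int | None = None,
) -> Path:
    """Write the single provenance record of an output directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    record = {
        "command": command,
        "config": config,
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "inputs": {
            str(p): file_digest(p) for p in sorted(map(str, input_paths or []))
        },
        "seed": seed,
        "package_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime()),
    }
    path = out_dir / "provenance.json"
    path.write_text(json.dumps(record, indent=2, sort_keys=True) + "\n")
    return path
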