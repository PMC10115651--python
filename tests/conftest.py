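"""Shared fixtures: small hand-built cluster trees with known answers."""

from __future__ import annotations

import numpy as np
import pytest

from metevol.core import (
    ClusterTree,
    MutationCluster,
    ROOT_MARKER,
    Sample,
    SampleKind,
    build_tree,
    classify_clonality,
)


def make_tree(case_id, cluster_specs, sample_specs, topologies=None) -> ClusterTree:
    """cluster_specs: (cid, parent, n_mut, {sample: ccf}); sample_specs: (sid, kind)."""
    clusters = [
        MutationCluster(cid, parent, n_mut, dict(ccf))
        for cid, parent, n_mut, ccf in cluster_specs
    ]
    samples = [Sample(sid, case_id, SampleKind(kind)) for sid, kind in sample_specs]
    return build_tree(case_id, clusters, samples, alternate_topologies=topologies)


@pytest.fixture
def chain_tree():
    """Root -> A -> B chain; two primary regions, one metastasis.

    A is subclonal in region R2, so the primary-clonal set is the root
    alone; B is the metastasis's dominant clone.
    """
    return make_tree(
        "CASE1",
        [
            ("C1", ROOT_MARKER, 50, {"R1": 1.0, "R2": 1.0, "M1": 1.0}),
            ("C2", "C1", 30, {"R1": 1.0, "R2": 0.5, "M1": 1.0}),
            ("C3", "C2", 20, {"R1": 0.4, "R2": 0.3, "M1": 1.0}),
        ],
        [("R1", "primary_region"), ("R2", "primary_region"),
         ("M1", "recurrence_progression")],
    )


@pytest.fixture
def late_tree():
    """All primary-clonal clusters clonal in the met: late divergence."""
    return make_tree(
        "CASE2",
        [
            ("C1", ROOT_MARKER, 60, {"R1": 1.0, "R2": 1.0, "M1": 1.0}),
            ("C2", "C1", 40, {"R1": 1.0, "R2": 1.0, "M1": 1.0}),
            ("C3", "C2", 10, {"R1": 0.6, "R2": 0.2, "M1": 1.0}),
        ],
        [("R1", "primary_region"), ("R2", "primary_region"),
         ("M1", "primary_LN_satellite")],
    )


@pytest.fixture
def early_tree():
    """A primary-clonal cluster absent from the met: early divergence."""
    return make_tree(
        "CASE3",
        [
            ("C1", ROOT_MARKER, 60, {"R1": 1.0, "R2": 1.0, "M1": 1.0}),
            ("C2", "C1", 40, {"R1": 1.0, "R2": 1.0, "M1": 0.0}),
            ("C3", "C1", 15, {"R1": 0.0, "R2": 0.0, "M1": 0.6}),
        ],
        [("R1", "primary_region"), ("R2", "primary_region"),
         ("M1", "recurrence_progression")],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def matrix_of():
    return lambda tree: classify_clonality(tree)
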