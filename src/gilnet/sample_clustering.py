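"""Knowledge-independent grouping of expression samples by k-means.

Samples (arrays) are the points and probes the coordinates; the compendium
is segregated into k groups minimizing the within-group sum of squares,
and each sufficiently large group later becomes one co-expression network.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from gilnet.expression_io import ExpressionMatrix

__all__ = [
    "ClusterAssignment",
    "GroupManifest",
    "rule_of_thumb_k",
    "kmeans_cluster",
    "partition_compendium",
]


@dataclass
class ClusterAssignment:
    """Sample -> cluster index map from one seeded k-means run."""

    assignment: dict[str, int]
    k: int
    inertia: float
    seed: int

    def members(self, cluster: int) -> list[str]:
        return [s for s, c in self.assignment.items() if c == cluster]


@dataclass
class GroupManifest:
    """Per-cluster membership and whether the group can support a network."""

    groups: dict[int, dict] = field(default_factory=dict)  # idx -> {members, status}
    min_size: int = 25

    def to_json(self) -> str:
        return json.dumps(
            {"min_size": self.min_size, "groups": {str(i): g for i, g in self.groups.items()}},
            indent=2,
        )


def rule_of_thumb_k(n: int) -> int:
    """k = floor(sqrt(n/2)), at least 1 — the common rule-of-thumb cluster count."""
    if n < 2:
        raise ValueError("need at least 2 samples to choose k")
    return max(1, math.floor(math.sqrt(n / 2)))


def kmeans_cluster(
    m: ExpressionMatrix, k: int, seed: int = 0, restarts: int = 10
) -> ClusterAssignment:
    """Lloyd k-means with k-means++ init over ``restarts`` seeded restarts.

    Deterministic given seed; cluster indices are relabelled by first
    appearance in sample order so the labelling itself is stable.
    """
    if k > m.n_samples:
        raise ValueError(f"k={k} exceeds the number of samples ({m.n_samples})")
    if k < 1:
        raise ValueError("k must be positive")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed, algorithm="lloyd")
    labels = km.fit_predict(m.values)
    # stable relabelling: cluster 0 is the first seen along the sample order
    relabel: dict[int, int] = {}
    for lab in labels:
        if lab not in relabel:
            relabel[lab] = len(relabel)
    assignment = {s: relabel[lab] for s, lab in zip(m.sample_ids, labels)}
    return ClusterAssignment(assignment, k, float(km.inertia_), seed)


def partition_compendium(
    m: ExpressionMatrix, a: ClusterAssignment, min_size: int = 25
) -> tuple[list[ExpressionMatrix], GroupManifest]:
    """Split the compendium into one sub-matrix per kept cluster.

    Clusters with fewer than ``min_size`` samples are reported in the
    manifest as ``too_few_arrays`` and yield no sub-matrix; downstream
    each kept sub-matrix is re-passed through normalization and QC.
    """
    missing = [s for s in m.sample_ids if s not in a.assignment]
    if missing:
        raise ValueError(f"assignment does not cover samples: {missing[:5]}")
    manifest = GroupManifest(min_size=min_size)
    groups: list[ExpressionMatrix] = []
    for c in range(a.k):
        members = [s for s in m.sample_ids if a.assignment[s] == c]
        status = "kept" if len(members) >= min_size else "too_few_arrays"
        manifest.groups[c] = {"members": members, "status": status}
        if status == "kept":
            groups.append(m.subset_samples(members))
    return groups, manifest
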