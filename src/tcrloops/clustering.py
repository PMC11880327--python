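"""Greedy threshold clustering of loop distance matrices.

A single pass over items in index order: each still-unassigned item seeds a
new cluster and absorbs every later unassigned item whose distance to the
seed is strictly below the threshold. The result is order-dependent by
construction, so callers fix (and should log) the item order; the first
member of each cluster is its representative.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Optional, Sequence, TypeVar

import numpy as np

from .geometry import DistanceMatrix, pairwise_distance_matrix
from .model import LoopStructure, StructureError

logger = logging.getLogger(__name__)

T = TypeVar("T")


class ClusteringError(StructureError):
    pass


@dataclass
class ClusterAssignment:
    """Ordered clusters of item indices; each cluster's first index is its
    representative (seed). Clusters partition 0..N-1 and every
    non-representative member lies strictly within ``threshold`` of its
    representative."""

    clusters: list[list[int]]
    threshold: float
    ids: list[str] = field(default_factory=list)

    @property
    def n_items(self) -> int:
        return sum(len(c) for c in self.clusters)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def representatives(self) -> list[int]:
        return [c[0] for c in self.clusters]

    def labels(self) -> np.ndarray:
        out = np.empty(self.n_items, dtype=int)
        for label, members in enumerate(self.clusters):
            out[members] = label
        return out

    def validate(self, matrix: Optional[DistanceMatrix] = None) -> None:
        seen = sorted(i for c in self.clusters for i in c)
        if seen != list(range(self.n_items)):
            raise ClusteringError("clusters do not partition the items")
        if matrix is not None:
            for members in self.clusters:
                rep = members[0]
                for j in members[1:]:
                    if not matrix.values[rep, j] < self.threshold:
                        raise ClusteringError(
                            f"member {j} outside radius of representative {rep}"
                        )


@dataclass
class ClusterCensus:
    count: int
    sizes: list[int]
    singleton_fraction: float

    def to_dict(self) -> dict:
        return {
            "count": self.count,
            "sizes": self.sizes,
            "singleton_fraction": self.singleton_fraction,
        }


def greedy_cluster(matrix: DistanceMatrix, tau: float) -> ClusterAssignment:
    """Single-pass greedy threshold clustering at radius ``tau`` (strict <).

    Deterministic for a fixed id order. ``tau = 0`` degenerates to all
    singletons; negative thresholds and invalid matrices are rejected.
    """
    if tau < 0:
        raise ClusteringError(f"threshold must be non-negative, got {tau}")
    matrix.validate()
    values = matrix.values
    n = len(matrix)
    unassigned = np.ones(n, dtype=bool)
    clusters: list[list[int]] = []
    for i in range(n):
        if not unassigned[i]:
            continue
        unassigned[i] = False
        members = [i]
        absorbed = np.nonzero(unassigned & (values[i] < tau))[0]
        absorbed = absorbed[absorbed > i]
        for j in absorbed:
            members.append(int(j))
            unassigned[j] = False
        clusters.append(members)
    return ClusterAssignment(clusters=clusters, threshold=tau, ids=list(matrix.ids))


def cluster_census(assignment: ClusterAssignment) -> ClusterCensus:
    """Cluster count, size distribution and singleton fraction."""
    sizes = [len(c) for c in assignment.clusters]
    n = sum(sizes)
    singletons = sum(1 for s in sizes if s == 1)
    return ClusterCensus(
        count=len(sizes),
        sizes=sorted(sizes, reverse=True),
        singleton_fraction=singletons / n if n else float("nan"),
    )


@dataclass
class VjCoherenceReport:
    """Structural coherence of V/J gene pairings.

    ``per_pair`` maps (V gene, J gene) to the number of structural clusters
    among that pairing's CDR3 loops at the given threshold; only pairings
    with at least ``min_group_size`` loops are counted.
    ``fraction_single_cluster`` is the proportion of counted pairings whose
    loops all fall into one cluster.
    """

    per_pair: dict[tuple[str, str], int]
    min_group_size: int
    threshold: float
    fraction_single_cluster: float

    @property
    def n_pairs(self) -> int:
        return len(self.per_pair)

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "min_group_size": self.min_group_size,
            "fraction_single_cluster": self.fraction_single_cluster,
            "per_pair": {f"{v}|{j}": k for (v, j), k in self.per_pair.items()},
        }


def vj_coherence(
    loops: Sequence[LoopStructure],
    tau: float = 2.0,
    min_group: int = 5,
) -> VjCoherenceReport:
    """Cluster each (V, J) gene group's loops and count distinct structures.

    Groups smaller than ``min_group`` are discarded. Loops without both
    gene labels are rejected. Returns an empty report (NaN fraction) with a
    warning when no group reaches ``min_group``.
    """
    groups: dict[tuple[str, str], list[LoopStructure]] = defaultdict(list)
    for loop in loops:
        if loop.v_gene is None or loop.j_gene is None:
            raise ClusteringError(f"loop {loop.loop_id} lacks V/J gene labels")
        groups[(loop.v_gene, loop.j_gene)].append(loop)

    per_pair: dict[tuple[str, str], int] = {}
    for pair in sorted(groups):
        members = groups[pair]
        if len(members) < min_group:
            continue
        matrix = pairwise_distance_matrix(members)
        assignment = greedy_cluster(matrix, tau)
        per_pair[pair] = assignment.n_clusters
    if not per_pair:
        logger.warning(
            "no V/J pairing reaches min_group=%d; empty coherence report", min_group
        )
        fraction = float("nan")
    else:
        fraction = sum(1 for k in per_pair.values() if k == 1) / len(per_pair)
    return VjCoherenceReport(
        per_pair=per_pair,
        min_group_size=min_group,
        threshold=tau,
        fraction_single_cluster=fraction,
    )


def sample_records(records: Sequence[T], n: int, seed: int) -> list[T]:
    """Uniform sample of ``n`` items without replacement, reproducible by seed."""
    if n > len(records):
        raise ClusteringError(f"cannot sample {n} from {len(records)} records")
    rng = np.random.default_rng(seed)
    indices = rng.choice(len(records), size=n, replace=False)
    return [records[int(i)] for i in indices]
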