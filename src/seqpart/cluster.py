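"""Single-linkage clustering of the sub-epsilon graph, plus Hobohm 1.

With a minimum-neighborhood size of one, density clustering degenerates to
single linkage: clusters are exactly the connected components of the graph
whose edges are the pairs closer than epsilon. The implementation is a
union-find over the edge list, which produces the identical partition in
near-linear time. Hobohm 1 is an optional greedy redundancy pre-clustering
for very large inputs: each sequence joins the first earlier representative
within a distance threshold or founds a new one.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Optional

from .distances import Measure, SparseDistanceGraph, distance
from .io import SequenceRecord
from .sketch import KmerSketch

logger = logging.getLogger(__name__)


@dataclass
class Cluster:
    cluster_id: int
    member_ids: list[str]
    size: int
    label_counts: dict[str, int]
    member_labels: dict[str, Optional[str]]
    representative_id: Optional[str] = None


@dataclass
class ClusterSet:
    """Disjoint clusters covering all sequence IDs."""

    clusters: list[Cluster]
    n_sequences: int

    def fold_ready_sizes(self) -> list[int]:
        return [c.size for c in self.clusters]

    def cluster_of(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in self.clusters:
            for sid in c.member_ids:
                out[sid] = c.cluster_id
        return out


class UnionFind:
    """Disjoint-set forest with path compression and union by size."""

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))
        self.size = [1] * n

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        if self.size[ra] < self.size[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.size[ra] += self.size[rb]


def _build_cluster_set(groups: list[list[int]],
                       records: list[SequenceRecord],
                       representatives: Optional[list[int]] = None
                       ) -> ClusterSet:
    """Groups of record indices -> ClusterSet with deterministic numbering
    (cluster 0 holds the smallest input index)."""
    groups = sorted(groups, key=min)
    clusters = []
    for cid, idxs in enumerate(groups):
        members = [records[i] for i in sorted(idxs)]
        label_counts = Counter(r.label for r in members if r.label is not None)
        rep = None
        if representatives is not None:
            rep = records[representatives[cid]].id
        clusters.append(
            Cluster(
                cluster_id=cid,
                member_ids=[r.id for r in members],
                size=len(members),
                label_counts=dict(label_counts),
                member_labels={r.id: r.label for r in members},
                representative_id=rep,
            )
        )
    return ClusterSet(clusters=clusters, n_sequences=len(records))


def dbscan_min1(graph: SparseDistanceGraph,
                records: list[SequenceRecord]) -> ClusterSet:
    """Connected components of the sub-epsilon graph as clusters.

    Isolated vertices become singleton clusters; cluster IDs are assigned
    0..C-1 in order of each cluster's smallest member input index. No two
    sequences in different clusters share a stored edge, hence (for a graph
    built without inversion) every cross-cluster pair is at distance >=
    epsilon.
    """
    n = graph.n
    if n != len(records):
        raise ValueError(f"graph has {n} vertices but {len(records)} records")
    uf = UnionFind(n)
    for i, j, _ in graph.edges:
        if not (0 <= i < n and 0 <= j < n):
            raise ValueError(f"edge ({i}, {j}) references an invalid index")
        uf.union(i, j)
    components: dict[int, list[int]] = {}
    for v in range(n):
        components.setdefault(uf.find(v), []).append(v)
    return _build_cluster_set(list(components.values()), records)


def hobohm1(
    records: list[SequenceRecord],
    sketches: list[KmerSketch],
    measure: Measure | str,
    threshold: float,
    order: str = "length_desc",
) -> ClusterSet:
    """Greedy one-pass redundancy clustering.

    Sequences are processed longest-first by default (classic choice: long
    sequences make better representatives; ties keep input order) or in
    input order. Each sequence is absorbed by the FIRST representative at
    distance < threshold, else founds a new representative. Every absorbed
    member is within threshold of its representative, but members of
    different clusters are not guaranteed to be threshold-separated.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    if order not in ("length_desc", "input"):
        raise ValueError(f"unknown processing order '{order}'")
    idx = list(range(len(records)))
    if order == "length_desc":
        idx.sort(key=lambda i: (-len(records[i].residues), i))
    rep_indices: list[int] = []
    groups: list[list[int]] = []
    for i in idx:
        placed = False
        for gi, rep in enumerate(rep_indices):
            if distance(measure, sketches[i], sketches[rep]) < threshold:
                groups[gi].append(i)
                placed = True
                break
        if not placed:
            rep_indices.append(i)
            groups.append([i])
    # keep representative association through the min-index reordering
    paired = sorted(zip(groups, rep_indices), key=lambda gr: min(gr[0]))
    groups = [g for g, _ in paired]
    reps = [r for _, r in paired]
    logger.info("Hobohm 1: %d representatives for %d sequences",
                len(reps), len(records))
    return _build_cluster_set(groups, records, representatives=reps)


def merge_preclusters(pre: ClusterSet, rep_clusters: ClusterSet,
                      records: list[SequenceRecord]) -> ClusterSet:
    """Combine Hobohm pre-clusters with a clustering of their
    representatives: each final cluster is the union of a representative
    cluster with all members absorbed by its representatives."""
    index_of = {r.id: i for i, r in enumerate(records)}
    absorbed: dict[str, list[int]] = {
        c.representative_id: [index_of[m] for m in c.member_ids]
        for c in pre.clusters
    }
    groups = []
    for rc in rep_clusters.clusters:
        members: list[int] = []
        for rep_id in rc.member_ids:
            members.extend(absorbed[rep_id])
        groups.append(members)
    return _build_cluster_set(groups, records)


def write_cluster_table(cluster_set: ClusterSet, path) -> None:
    """TSV dump (sequence_id, cluster_id, representative_id-or-empty)."""
    with open(path, "w") as fh:
        fh.write("sequence_id\tcluster_id\trepresentative_id\n")
        for c in cluster_set.clusters:
            rep = c.representative_id or ""
            for sid in c.member_ids:
                fh.write(f"{sid}\t{c.cluster_id}\t{rep}\n")
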