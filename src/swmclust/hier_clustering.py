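"""Sparse-graph average-link clustering and adaptive dendrogram partition.

Pairwise fiber distances at or below a cutoff are turned into an affinity
graph with edge weights ``a_ij = exp(-d_ij / sigma2)`` (``sigma2`` is the
similarity scale in mm, default 60).  Agglomeration repeatedly merges the
pair of clusters with the highest current affinity and updates affinities to
the rest by the average-linkage criterion, restricted to edges that exist in
the graph.  Elements with no edge at all stay singleton roots; a graph with
N elements and nC unconnected ones yields exactly N - nC merges.

The dendrogram is then cut adaptively: walking breadth-first from each root,
a node whose descendant fibers have maximum pairwise d_ME at or below
``d_clmax`` becomes a cluster; otherwise its children are examined.  Finally
only clusters drawing on at least a fraction of the subject group (75% in
the default configuration) are kept as reproducible bundles.
"""

from __future__ import annotations

import heapq
import json
import math
from collections import deque
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .fiber_metrics import SparseDistanceSet, pairwise_d_me

__all__ = [
    "AffinityGraph",
    "Dendrogram",
    "Partition",
    "build_affinity_graph",
    "average_link_dendrogram",
    "adaptive_partition",
    "reproducibility_filter",
    "reproducibility_cutoff",
]


@dataclass
class AffinityGraph:
    """Sparse affinity graph over fibers: a_ij = exp(-d_ij / sigma2)."""

    i: np.ndarray
    j: np.ndarray
    a: np.ndarray
    sigma2: float
    n_elements: int

    def __post_init__(self) -> None:
        self.i = np.asarray(self.i, dtype=np.int64)
        self.j = np.asarray(self.j, dtype=np.int64)
        self.a = np.asarray(self.a, dtype=np.float64)
        if len(self.a) and (self.a.min() <= 0.0 or self.a.max() > 1.0):
            raise ValueError("affinities must lie in (0, 1]")

    def __len__(self) -> int:
        return len(self.a)

    @property
    def n_unconnected(self) -> int:
        touched = np.unique(np.concatenate([self.i, self.j]))
        return self.n_elements - len(touched)

    @property
    def n_components(self) -> int:
        """Connected components, isolated elements included.

        Agglomeration produces exactly ``n_elements - n_components`` merges:
        clusters without a shared edge can never fuse, so each component
        (and each isolated element) ends as one dendrogram root.
        """
        from scipy.sparse import coo_matrix
        from scipy.sparse.csgraph import connected_components

        m = coo_matrix(
            (np.ones(len(self.a)), (self.i, self.j)),
            shape=(self.n_elements, self.n_elements),
        )
        n, _ = connected_components(m, directed=False)
        return int(n)


def build_affinity_graph(sd: SparseDistanceSet, sigma2: float = 60.0) -> AffinityGraph:
    """Exponential affinity per stored pair; sigma2 <= 0 is rejected."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    return AffinityGraph(
        i=sd.i.copy(),
        j=sd.j.copy(),
        a=np.exp(-sd.d / sigma2),
        sigma2=sigma2,
        n_elements=sd.n_elements,
    )


@dataclass
class Dendrogram:
    """Binary merge forest over graph elements.

    ``merges`` lists ``(node_id, left, right, affinity)`` in merge order;
    leaf ids are 0..n_leaves-1 and internal ids continue from n_leaves, so
    children always precede their parents.  ``roots`` holds one id per
    connected component (singletons included).
    """

    n_leaves: int
    merges: list[tuple[int, int, int, float]] = field(default_factory=list)
    roots: list[int] = field(default_factory=list)

    def children(self) -> dict[int, tuple[int, int]]:
        return {m[0]: (m[1], m[2]) for m in self.merges}

    def leaf_sets(self) -> dict[int, np.ndarray]:
        """Leaf ids under every node (leaves map to themselves)."""
        out: dict[int, np.ndarray] = {
            i: np.array([i], dtype=np.int64) for i in range(self.n_leaves)
        }
        for node, left, right, _ in self.merges:
            out[node] = np.concatenate([out[left], out[right]])
        return out

    def to_text(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# n_leaves={self.n_leaves} roots={','.join(map(str, self.roots))}\n")
            for node, left, right, aff in self.merges:
                fh.write(f"{node} {left} {right} {aff:.12g}\n")

    @classmethod
    def from_text(cls, path) -> "Dendrogram":
        with open(path) as fh:
            header = fh.readline().lstrip("#").split()
        meta = dict(kv.split("=") for kv in header)
        merges = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    continue
                node, left, right, aff = line.split()
                merges.append((int(node), int(left), int(right), float(aff)))
        roots = [int(r) for r in meta["roots"].split(",") if r]
        return cls(n_leaves=int(meta["n_leaves"]), merges=merges, roots=roots)


def average_link_dendrogram(g: AffinityGraph) -> Dendrogram:
    """Agglomerate the affinity graph by repeated best-pair merging.

    At each step the cluster pair with maximal affinity is merged (ties go to
    the lexicographically lowest id pair).  The merged cluster's affinity to
    a neighbour is the size-weighted mean of its children's affinities to
    that neighbour, over the child edges that exist; on a complete graph this
    is exactly UPGMA.  Unconnected elements remain singleton roots.
    """
    n = g.n_elements
    adj: list[dict[int, float] | None] = [dict() for _ in range(n)]
    for i, j, a in zip(g.i, g.j, g.a):
        adj[int(i)][int(j)] = float(a)
        adj[int(j)][int(i)] = float(a)
    size = [1] * n
    heap: list[tuple[float, int, int]] = [
        (-float(a), int(i), int(j)) for i, j, a in zip(g.i, g.j, g.a)
    ]
    heapq.heapify(heap)
    merges: list[tuple[int, int, int, float]] = []
    next_id = n
    active = set(range(n))

    while heap:
        neg_a, u, v = heapq.heappop(heap)
        if u >= len(adj) or v >= len(adj):
            continue
        au, av = adj[u], adj[v]
        if au is None or av is None:
            continue
        if au.get(v) != -neg_a:  # stale entry
            continue
        # merge u and v into a new cluster
        new = next_id
        next_id += 1
        merges.append((new, u, v, -neg_a))
        su, sv = size[u], size[v]
        merged: dict[int, float] = {}
        for x, ax in au.items():
            if x != v:
                merged[x] = ax
        for x, ax in av.items():
            if x == u:
                continue
            if x in merged:
                merged[x] = (su * merged[x] + sv * ax) / (su + sv)
            else:
                merged[x] = ax
        # retire children, install the new cluster
        for x in merged:
            nbr = adj[x]
            nbr.pop(u, None)
            nbr.pop(v, None)
            nbr[new] = merged[x]
            lo, hi = (x, new) if x < new else (new, x)
            heapq.heappush(heap, (-merged[x], lo, hi))
        adj[u] = None
        adj[v] = None
        adj.append(merged)
        size.append(su + sv)
        active.discard(u)
        active.discard(v)
        active.add(new)

    roots = sorted(active)
    return Dendrogram(n_leaves=n, merges=merges, roots=roots)


@dataclass
class Partition:
    """Disjoint leaf-id clusters cut from a dendrogram at ``d_clmax``."""

    clusters: list[np.ndarray]
    d_clmax: float

    def __len__(self) -> int:
        return len(self.clusters)

    def to_json(self, path) -> None:
        payload = {
            "d_clmax": self.d_clmax,
            "clusters": [sorted(int(x) for x in c) for c in self.clusters],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "Partition":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            clusters=[np.asarray(c, dtype=np.int64) for c in payload["clusters"]],
            d_clmax=float(payload["d_clmax"]),
        )


def _node_max_distances(
    dg: Dendrogram, fibers: Sequence[np.ndarray]
) -> dict[int, float]:
    """Max pairwise d_ME under every node, bottom-up with memoization.

    Each leaf pair is evaluated exactly once, at its lowest common ancestor,
    so the total work equals one all-pairs pass per connected component.
    """
    stacked = np.asarray(fibers, dtype=np.float64)
    leaves = dg.leaf_sets()
    md: dict[int, float] = {i: 0.0 for i in range(dg.n_leaves)}
    for node, left, right, _ in dg.merges:
        cross = pairwise_d_me(stacked[leaves[left]], stacked[leaves[right]])
        md[node] = max(md[left], md[right], float(cross.max()))
    return md


def adaptive_partition(
    dg: Dendrogram, fibers: Sequence[np.ndarray], d_clmax: float = 30.0
) -> Partition:
    """Cut the dendrogram into the largest nodes with spread <= ``d_clmax``.

    Breadth-first from each root: a node whose descendant fibers have
    maximum pairwise d_ME at or below the bound is emitted whole; otherwise
    its children enter the queue.  Singleton leaves (including unconnected
    elements) are emitted as singleton clusters, keeping the partition total.
    """
    if len(fibers) != dg.n_leaves:
        raise ValueError("fibers must index the dendrogram leaves")
    md = _node_max_distances(dg, fibers)
    leaves = dg.leaf_sets()
    children = dg.children()
    clusters: list[np.ndarray] = []
    queue = deque(dg.roots)
    while queue:
        node = queue.popleft()
        if md[node] <= d_clmax:
            clusters.append(np.sort(leaves[node]))
        else:
            left, right = children[node]
            queue.append(left)
            queue.append(right)
    return Partition(clusters=clusters, d_clmax=d_clmax)


def reproducibility_cutoff(n_subjects: int, min_frac: float = 0.75) -> int:
    """Smallest integer >= min_frac * n_subjects (e.g. 37 subjects -> 28)."""
    if not 0 < min_frac <= 1:
        raise ValueError("min_frac must be in (0, 1]")
    return math.ceil(round(min_frac * n_subjects, 9))


def reproducibility_filter(
    p: Partition,
    subject_of: Mapping[int, str] | Sequence[str],
    n_subjects: int,
    min_frac: float = 0.75,
) -> Partition:
    """Keep clusters represented in at least ``min_frac`` of the subjects.

    ``subject_of`` maps each leaf id to its subject; a missing leaf raises.
    """
    cutoff = reproducibility_cutoff(n_subjects, min_frac)
    kept = []
    for cluster in p.clusters:
        subjects = set()
        for leaf in cluster:
            leaf = int(leaf)
            try:
                subjects.add(subject_of[leaf])
            except (KeyError, IndexError) as exc:
                raise KeyError(f"leaf {leaf} has no subject mapping") from exc
        if len(subjects) >= cutoff:
            kept.append(cluster)
    return Partition(clusters=kept, d_clmax=p.d_clmax)
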