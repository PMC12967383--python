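"""Agglomerative hierarchical clustering with average linkage.

Starting from every series in its own cluster, the pair of clusters with
the smallest average linkage

    d_A(Q, R) = 1 / (|Q| |R|) * sum over X in Q, Y in R of D(X, Y)

is merged, and the process repeats until one cluster remains; cutting the
merge sequence when exactly k clusters are left yields the k-cluster
partition.  Cuts at successive k are nested by construction.

The linkage of every candidate pair is recomputed *definitionally* from
the original distance matrix at each step, not via Lance-Williams update
recurrences.  This is O(n^3)-ish but panels here hold ~10-20 curves, and
it makes the defining average the literal contract of the code: the merge
chosen at each step is brute-force-minimal by construction.

Ties (two pairs sharing the minimal d_A) are broken deterministically by
the smallest member index in input label order, then the second index.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    ClusterCountError,
    DegenerateMatrixError,
    OverlapError,
    UnknownLabelError,
)

__all__ = [
    "DistanceMatrix",
    "MergeTree",
    "ClusterAssignment",
    "average_linkage",
    "agglomerate",
    "cut",
    "to_newick",
    "assignments_to_records",
]

log = logging.getLogger(__name__)

SYMMETRY_ATOL = 1e-12


@dataclass
class DistanceMatrix:
    """Symmetric pairwise proximity matrix with zero diagonal.

    Negative entries are tolerated (they can arise under non-default
    proximity kernels) but logged.
    """

    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("distance matrix labels must be unique")
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if not np.allclose(self.values, self.values.T, atol=SYMMETRY_ATOL, rtol=0):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix diagonal must be exactly zero")
        if np.any(self.values < 0):
            log.info(
                "distance matrix contains %d negative entries (non-default kernel?)",
                int(np.sum(self.values < 0) // 2),
            )
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def __len__(self) -> int:
        return len(self.labels)

    def entry(self, a: str, b: str) -> float:
        try:
            return float(self.values[self._index[a], self._index[b]])
        except KeyError as exc:
            raise UnknownLabelError(f"label {exc.args[0]!r} not in matrix") from None


@dataclass(frozen=True)
class Merge:
    """One agglomeration step: clusters ``a`` and ``b`` joined at linkage
    ``height`` into cluster ``new_id``.  Leaves are ids 0..n-1 in input
    order; internal clusters get ids n, n+1, ... in merge order."""

    a: int
    b: int
    height: float
    new_id: int


@dataclass
class MergeTree:
    """Full agglomeration history; cuttable at any 1 <= k <= n."""

    leaf_labels: list[str]
    merges: list[Merge] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.leaf_labels)

    def heights(self) -> list[float]:
        return [m.height for m in self.merges]

    def members(self, cluster_id: int) -> list[int]:
        """Leaf indices under a cluster id, in ascending order."""
        if cluster_id < self.n:
            return [cluster_id]
        merge = self.merges[cluster_id - self.n]
        return sorted(self.members(merge.a) + self.members(merge.b))


def average_linkage(
    q_members: set[str] | frozenset[str],
    r_members: set[str] | frozenset[str],
    dm: DistanceMatrix,
) -> float:
    """Mean of all |Q|*|R| cross-pair distances between two disjoint clusters."""
    q = frozenset(q_members)
    r = frozenset(r_members)
    if not q or not r:
        raise ValueError("cluster member sets must be non-empty")
    if q & r:
        raise OverlapError(f"clusters overlap on {sorted(q & r)!r}")
    unknown = (q | r) - set(dm.labels)
    if unknown:
        raise UnknownLabelError(f"labels {sorted(unknown)!r} not in matrix")
    total = 0.0
    for x in q:
        for y in r:
            total += dm.entry(x, y)
    return total / (len(q) * len(r))


def agglomerate(dm: DistanceMatrix) -> MergeTree:
    """Merge the closest cluster pair (smallest average linkage) until one
    cluster remains, recording every step.

    At each step every candidate pair's d_A is recomputed from the original
    matrix, so the merged pair attains the global minimum by construction.
    """
    n = len(dm)
    if n < 2:
        raise DegenerateMatrixError(f"need at least 2 items to cluster, got {n}")

    tree = MergeTree(leaf_labels=list(dm.labels))
    # active: cluster_id -> sorted tuple of leaf indices
    active: dict[int, tuple[int, ...]] = {i: (i,) for i in range(n)}
    next_id = n
    V = dm.values

    for _ in range(n - 1):
        best = None  # (height, min_leaf_a, min_leaf_b, id_a, id_b)
        ids = sorted(active)
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                ia, ib = ids[ai], ids[bi]
                la, lb = active[ia], active[ib]
                h = float(np.mean(V[np.ix_(la, lb)]))
                # tie-break: smallest member leaf index, then the other's
                key = (h, min(la[0], lb[0]), max(la[0], lb[0]))
                if best is None or key < best[:3]:
                    best = (*key, ia, ib)
        h, _, _, ia, ib = best
        tree.merges.append(Merge(a=ia, b=ib, height=h, new_id=next_id))
        active[next_id] = tuple(sorted(active.pop(ia) + active.pop(ib)))
        next_id += 1
    return tree


@dataclass
class ClusterAssignment:
    """Partition into k clusters: site label -> cluster index in 1..k.

    Cluster indices follow the order of each cluster's first leaf in the
    input label order, so output files are reproducible and diff cleanly.
    """

    k: int
    mapping: dict[str, int]

    def groups(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for site, c in self.mapping.items():
            out.setdefault(c, []).append(site)
        return out


def cut(tree: MergeTree, k: int) -> ClusterAssignment:
    """Stop the merge sequence when exactly k clusters remain."""
    n = tree.n
    if not 1 <= k <= n:
        raise ClusterCountError(f"k must be in [1, {n}], got {k}")
    active: dict[int, tuple[int, ...]] = {i: (i,) for i in range(n)}
    for m in tree.merges[: n - k]:
        active[m.new_id] = tuple(sorted(active.pop(m.a) + active.pop(m.b)))
    # index clusters by their first leaf in input order
    clusters = sorted(active.values(), key=lambda leaves: leaves[0])
    mapping: dict[str, int] = {}
    for ci, leaves in enumerate(clusters, start=1):
        for leaf in leaves:
            mapping[tree.leaf_labels[leaf]] = ci
    return ClusterAssignment(k=k, mapping=mapping)


_NEWICK_UNSAFE = re.compile(r"[\s(),:;\[\]']")


def _newick_label(label: str) -> str:
    if _NEWICK_UNSAFE.search(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(tree: MergeTree) -> str:
    """Render the merge tree as a Newick string with branch lengths.

    Node heights follow the ultrametric dendrogram convention: a cluster
    merged at linkage height h sits at height h/2, leaves at 0, and each
    branch length is the parent-child height difference.  A two-leaf tree
    merged at h therefore has both leaf branches of length h/2.
    """
    n = tree.n

    def height(cid: int) -> float:
        return 0.0 if cid < n else tree.merges[cid - n].height / 2.0

    def render(cid: int, parent_h: float) -> str:
        bl = parent_h - height(cid)
        if cid < n:
            return f"{_newick_label(tree.leaf_labels[cid])}:{bl:.12g}"
        m = tree.merges[cid - n]
        h = height(cid)
        return f"({render(m.a, h)},{render(m.b, h)}):{bl:.12g}"

    root = tree.merges[-1]
    root_h = height(root.new_id)
    return f"({render(root.a, root_h)},{render(root.b, root_h)});"


def assignments_to_records(assignments: list[ClusterAssignment]) -> list[dict]:
    """Flatten assignments into (site, k, cluster_index) rows for CSV/JSON."""
    rows = []
    for a in assignments:
        for site in sorted(a.mapping):
            rows.append({"site": site, "k": a.k, "cluster_index": a.mapping[site]})
    return rows
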