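"""Distance-based phylogeny: p-distance matrices, neighbor-joining and
nonparametric bootstrap.

The neighbor-joining implementation follows the Saitou-Nei Q-criterion with
a deterministic tie-break by label order.  Negative branch lengths are
clamped to zero for display (the raw value is retained on the node); the
unrooted tree is serialized with a trifurcating root at the final join.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

GAP_CHARS = set("-.")


@dataclass
class Node:
    """Tree node; ``length`` is the branch to the parent (clamped >= 0)."""

    label: str | None = None
    children: list["Node"] = field(default_factory=list)
    length: float = 0.0
    raw_length: float = 0.0
    support: int | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    matrix: np.ndarray  # symmetric, zero diagonal, non-negative

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match label count")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(m < 0):
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "matrix", m)


@dataclass
class PhyloTree:
    root: Node
    n_replicates: int | None = None  # bootstrap replicates behind supports

    def leaves(self) -> list[str]:
        return self.root.leaves()

    def newick(self, supports: bool = False) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                return f"{node.label}:{node.length:.6g}"
            inner = ",".join(fmt(c) for c in node.children)
            lab = ""
            if supports and node.support is not None:
                lab = str(node.support)
            return f"({inner}){lab}:{node.length:.6g}"
        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits, each canonicalized to its smaller side."""
        all_leaves = frozenset(self.leaves())
        splits: set[frozenset[str]] = set()
        def walk(node: Node):
            for c in node.children:
                side = frozenset(c.leaves())
                other = all_leaves - side
                if len(side) >= 2 and len(other) >= 2:
                    canon = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
                    splits.add(canon)
                walk(c)
        walk(self.root)
        return splits


def _rows_to_array(msa) -> tuple[list[str], np.ndarray]:
    """Accept an MSA object (labels/rows attributes) or a list of (label, row)."""
    if hasattr(msa, "labels") and hasattr(msa, "rows"):
        labels, rows = list(msa.labels), list(msa.rows)
    else:
        labels, rows = [p[0] for p in msa], [p[1] for p in msa]
    if len({len(r) for r in rows}) != 1:
        raise ValueError("alignment rows differ in length")
    arr = np.array([list(r.upper()) for r in rows])
    return labels, arr


def p_distance(msa) -> DistanceMatrix:
    """Mismatch fraction per pair with pairwise deletion of gapped columns."""
    labels, arr = _rows_to_array(msa)
    n = len(labels)
    if n < 3:
        raise ValueError("need at least 3 rows")
    ok = ~np.isin(arr, list(GAP_CHARS))
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ok[i] & ok[j]
            comp = int(both.sum())
            if comp == 0:
                raise ValueError(f"no comparable columns between "
                                 f"{labels[i]!r} and {labels[j]!r}")
            mism = int((arr[i, both] != arr[j, both]).sum())
            d[i, j] = d[j, i] = mism / comp
    return DistanceMatrix(labels=tuple(labels), matrix=d)


def nj(dist: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining; deterministic, ties broken by label order."""
    labels = list(dist.labels)
    n = len(labels)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    nodes = [Node(label=lab) for lab in labels]
    order = [min(nd.leaves()) for nd in nodes]  # tie-break key per cluster
    d = dist.matrix.copy()
    active = list(range(n))

    def clamp(node: Node, raw: float):
        node.raw_length = raw
        if raw < 0:
            warnings.warn(f"negative NJ branch length {raw:.4g} clamped to 0",
                          stacklevel=3)
        node.length = max(raw, 0.0)

    while len(active) > 3:
        r = len(active)
        sub = d[np.ix_(active, active)]
        total = sub.sum(axis=1)
        q = (r - 2) * sub - total[:, None] - total[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        best = None
        for a in range(r):
            for b in range(a + 1, r):
                if q[a, b] <= qmin + 1e-12:
                    key = tuple(sorted((order[active[a]], order[active[b]])))
                    if best is None or key < best[0]:
                        best = (key, a, b)
        _, a, b = best
        i, j = active[a], active[b]
        dij = d[i, j]
        li = 0.5 * dij + (total[a] - total[b]) / (2 * (r - 2))
        lj = dij - li
        parent = Node()
        clamp(nodes[i], li)
        clamp(nodes[j], lj)
        parent.children = [nodes[i], nodes[j]]
        # distances from the new node to every other active node
        new_row = 0.5 * (d[i, :] + d[j, :] - dij)
        k = len(nodes)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[k, :k] = new_row[:k]
        d[:k, k] = new_row[:k]
        nodes.append(parent)
        order.append(min(order[i], order[j]))
        active = [x for x in active if x not in (i, j)] + [k]

    # final trifurcation: three-point formulas
    i, j, k = active
    root = Node()
    clamp(nodes[i], 0.5 * (d[i, j] + d[i, k] - d[j, k]))
    clamp(nodes[j], 0.5 * (d[i, j] + d[j, k] - d[i, k]))
    clamp(nodes[k], 0.5 * (d[i, k] + d[j, k] - d[i, j]))
    root.children = [nodes[i], nodes[j], nodes[k]]
    return PhyloTree(root=root)


def bootstrap(msa, n: int = 1000, seed: int = 0) -> PhyloTree:
    """NJ tree on the full alignment, internal edges annotated with the
    number of column-resampled replicates containing the same bipartition."""
    if n < 1:
        raise ValueError("need at least one replicate")
    labels, arr = _rows_to_array(msa)
    tree = nj(p_distance(list(zip(labels, ["".join(r) for r in arr]))))
    counts: dict[frozenset[str], int] = {bp: 0 for bp in tree.bipartitions()}
    rng = np.random.default_rng(seed)
    ncol = arr.shape[1]
    for _ in range(n):
        cols = rng.integers(0, ncol, size=ncol)
        rep = arr[:, cols]
        rep_msa = list(zip(labels, ["".join(r) for r in rep]))
        try:
            rep_tree = nj(p_distance(rep_msa))
        except ValueError:
            continue  # replicate with an incomparable pair contributes nothing
        for bp in rep_tree.bipartitions():
            if bp in counts:
                counts[bp] += 1

    all_leaves = frozenset(labels)
    def annotate(node: Node):
        for c in node.children:
            if not c.is_leaf:
                side = frozenset(c.leaves())
                other = all_leaves - side
                if len(side) >= 2 and len(other) >= 2:
                    canon = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
                    c.support = counts.get(canon, 0)
            annotate(c)
    annotate(tree.root)
    tree.n_replicates = n
    return tree


def distance_to_tsv(dist: DistanceMatrix) -> str:
    lines = ["\t" + "\t".join(dist.labels)]
    for lab, row in zip(dist.labels, dist.matrix):
        lines.append(lab + "\t" + "\t".join(f"{x:.6f}" for x in row))
    return "\n".join(lines) + "\n"
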