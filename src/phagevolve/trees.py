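"""Distance matrices and neighbor-joining trees.

Shared by the phenotypic (Canberra) and genotypic (Euclidean) analyses.
The NJ implementation is the classic Saitou-Nei agglomeration with two
conventions pinned down for reproducibility:

* ties on the Q criterion are broken by the lexicographically smallest pair
  of representative labels (each cluster is represented by the smallest leaf
  label beneath it), so results are identical across platforms;
* negative branch lengths are clamped to zero with the deficit transferred
  to the sibling edge of the same join, preserving the distance between the
  two joined nodes (clamps are recorded on the tree object).

Trees are unrooted internally; rooting on an outgroup bisects the edge
leading to the outgroup leaf.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DistanceMatrix", "Tree", "neighbor_joining"]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with ordered labels."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        if (self.d < -1e-12).any():
            raise ValueError("negative distances")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="population")

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float))


class Tree:
    """Unrooted tree with branch lengths and an optional root placement.

    Stored as an adjacency map ``node -> {neighbor: branch_length}``; leaves
    are the original labels, internal nodes carry synthetic ``_n*`` ids.
    """

    def __init__(self, adj: dict[str, dict[str, float]], leaves: list[str],
                 root: str | None = None, n_clamped: int = 0) -> None:
        self.adj = adj
        self.leaf_names = sorted(leaves)
        self.root = root if root is not None else self._default_root()
        self.n_clamped = n_clamped

    def _default_root(self) -> str:
        internal = [n for n in self.adj if n not in self.leaf_names]
        return sorted(internal)[0] if internal else self.leaf_names[0]

    # -- structure queries --------------------------------------------------

    def _subtree_leaves(self, node: str, parent: str | None) -> frozenset[str]:
        if node in self.leaf_names and node != self.root:
            return frozenset([node])
        out: set[str] = set()
        if node in self.leaf_names:
            out.add(node)
        for nbr in self.adj[node]:
            if nbr != parent:
                out |= self._subtree_leaves(nbr, node)
        return frozenset(out)

    def clades(self) -> set[frozenset[str]]:
        """Leaf sets of all subtrees hanging below the root."""
        out: set[frozenset[str]] = set()

        def walk(node: str, parent: str | None) -> frozenset[str]:
            kids = [n for n in self.adj[node] if n != parent]
            if not kids:
                s = frozenset([node])
            else:
                s = frozenset(itertools.chain.from_iterable(
                    walk(k, node) for k in kids))
                if node in self.leaf_names:
                    s |= {node}
            out.add(s)
            return s

        walk(self.root, None)
        return out

    def is_clade(self, leafset) -> bool:
        return frozenset(leafset) in self.clades()

    def bipartitions(self) -> set[frozenset[str]]:
        """Nontrivial splits of the unrooted topology, canonical side only
        (the side not containing the smallest leaf label)."""
        anchor = min(self.leaf_names)
        n = len(self.leaf_names)
        out: set[frozenset[str]] = set()
        for a in self.adj:
            for b in self.adj[a]:
                if a < b:
                    side = self._subtree_leaves(b, a) if anchor not in \
                        self._subtree_leaves(b, a) else self._subtree_leaves(a, b)
                    if 1 < len(side) < n - 1:
                        out.add(side)
        return out

    def rf_distance(self, other: "Tree") -> int:
        if set(self.leaf_names) != set(other.leaf_names):
            raise ValueError("leaf sets differ")
        return len(self.bipartitions() ^ other.bipartitions())

    def leaf_path_distances(self) -> pd.DataFrame:
        """All leaf-to-leaf path lengths (the tree metric this tree induces)."""
        leaves = self.leaf_names
        mat = pd.DataFrame(0.0, index=leaves, columns=leaves)
        for src in leaves:
            dist = {src: 0.0}
            stack = [src]
            while stack:
                node = stack.pop()
                for nbr, ln in self.adj[node].items():
                    if nbr not in dist:
                        dist[nbr] = dist[node] + ln
                        stack.append(nbr)
            for leaf in leaves:
                mat.loc[src, leaf] = dist[leaf]
        return mat

    # -- rooting & serialization --------------------------------------------

    def rooted_on(self, outgroup: str) -> "Tree":
        """New tree rooted on the outgroup leaf's edge (edge bisected)."""
        if outgroup not in self.leaf_names:
            raise ValueError(f"outgroup {outgroup!r} is not a leaf")
        (nbr, ln), = self.adj[outgroup].items()
        adj = {k: dict(v) for k, v in self.adj.items()}
        del adj[outgroup][nbr]
        del adj[nbr][outgroup]
        root = "_root"
        adj[root] = {outgroup: ln / 2.0, nbr: ln / 2.0}
        adj[outgroup][root] = ln / 2.0
        adj[nbr][root] = ln / 2.0
        return Tree(adj, self.leaf_names, root=root, n_clamped=self.n_clamped)

    def _min_leaf(self, node: str, parent: str | None) -> str:
        return min(self._subtree_leaves(node, parent) | (
            {node} if node in self.leaf_names else set()))

    def to_newick(self) -> str:
        def fmt(node: str, parent: str | None) -> str:
            kids = sorted(
                (n for n in self.adj[node] if n != parent),
                key=lambda k: self._min_leaf(k, node),
            )
            label = node if node in self.leaf_names else ""
            if not kids:
                return label
            inner = ",".join(
                f"{fmt(k, node)}:{self.adj[node][k]:.10g}" for k in kids)
            return f"({inner}){label}"

        return fmt(self.root, None) + ";"

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")


def neighbor_joining(dm: DistanceMatrix, outgroup: str | None = None) -> Tree:
    """Saitou-Nei neighbor joining; exact on additive distance matrices.

    With an ``outgroup`` label the returned tree is rooted on the edge
    leading to that leaf; otherwise it keeps a deterministic internal root.
    """
    labels = list(dm.labels)
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 taxa")
    if outgroup is not None and outgroup not in labels:
        raise ValueError(f"outgroup {outgroup!r} not among labels")

    adj: dict[str, dict[str, float]] = {lab: {} for lab in labels}
    n_clamped = 0

    if n == 2:
        d = float(dm.d[0, 1])
        a, b = labels
        mid = "_n1"
        adj[mid] = {a: d / 2.0, b: d / 2.0}
        adj[a][mid] = d / 2.0
        adj[b][mid] = d / 2.0
        tree = Tree(adj, labels, root=mid)
        return tree.rooted_on(outgroup) if outgroup else tree

    active = list(labels)                       # node ids
    rep = {lab: lab for lab in labels}          # smallest leaf beneath
    D = {a: {b: float(dm.d[i, j]) for j, b in enumerate(labels)}
         for i, a in enumerate(labels)}
    next_id = 1

    while len(active) > 2:
        m = len(active)
        r = {a: sum(D[a][b] for b in active if b != a) for a in active}
        best = None
        best_pair = None
        for a, b in itertools.combinations(active, 2):
            q = (m - 2) * D[a][b] - r[a] - r[b]
            key = tuple(sorted((rep[a], rep[b])))
            if best is None or q < best[0] - 1e-15 or (
                    abs(q - best[0]) <= 1e-15 and key < best[1]):
                best = (q, key)
                best_pair = (a, b)
        a, b = best_pair
        dab = D[a][b]
        la = dab / 2.0 + (r[a] - r[b]) / (2.0 * (m - 2))
        lb = dab - la
        # clamp negatives, transferring the deficit to the sibling edge so
        # the a-b path length is preserved
        if la < 0.0:
            la, lb = 0.0, dab
            n_clamped += 1
        elif lb < 0.0:
            la, lb = dab, 0.0
            n_clamped += 1
        new = f"_n{next_id}"
        next_id += 1
        adj[new] = {a: la, b: lb}
        adj[a][new] = la
        adj[b][new] = lb
        D[new] = {}
        for c in active:
            if c in (a, b):
                continue
            dc = 0.5 * (D[a][c] + D[b][c] - dab)
            D[new][c] = dc
            D[c][new] = dc
        active = [c for c in active if c not in (a, b)] + [new]
        rep[new] = min(rep[a], rep[b])

    a, b = active
    d = max(D[a][b], 0.0)
    # final join: a single edge between the last two nodes (at least one of
    # which is internal for n >= 3, so no unary nodes appear in the output)
    adj[a][b] = d
    adj[b][a] = d
    root = a if a not in labels else b

    tree = Tree(adj, labels, root=root, n_clamped=n_clamped)
    return tree.rooted_on(outgroup) if outgroup else tree
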