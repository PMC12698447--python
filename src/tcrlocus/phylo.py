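"""Distance-based trees for short gene segments: Jukes-Cantor distances,
BIONJ agglomeration and midpoint rooting, with minimal Newick I/O.

BIONJ (Gascuel 1997) is neighbor joining with variance-weighted reductions:
at each step the pair minimizing the NJ Q-criterion is joined (ties broken on
the lowest index pair, making the result deterministic) and the new node's
distances are a variance-weighted average of its children's. Jukes-Cantor
distance d = -(3/4) ln(1 - (4/3) p) with p the mismatch fraction over shared
ungapped sites (pairwise deletion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np


@dataclass
class TreeNode:
    label: Optional[str] = None
    children: list = field(default_factory=list)  # list[(TreeNode, length)]

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return sorted(n.label for n in self.leaves())


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def validate(self) -> None:
        m = self.matrix
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.all(np.isfinite(m)):
            raise ValueError("non-finite distances")
        if not np.allclose(m, m.T):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("non-zero diagonal")
        if np.any(m < -1e-12):
            raise ValueError("negative distances")


def jc_distance(sequences: dict[str, str] | Sequence[tuple[str, str]]) -> DistanceMatrix:
    """Jukes-Cantor distance matrix from equal-length aligned sequences.

    Gap handling is pairwise deletion: each pair is compared over the sites
    where neither sequence has a gap. p >= 0.75 (formula saturation) or zero
    shared sites raise ValueError.
    """
    items = list(sequences.items()) if isinstance(sequences, dict) else list(sequences)
    if len(items) < 2:
        raise ValueError("need at least two sequences")
    labels = [k for k, _ in items]
    seqs = [v.upper() for _, v in items]
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("sequences must have equal aligned length")
    n = len(seqs)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = mism = 0
            for a, b in zip(seqs[i], seqs[j]):
                if a in "-." or b in "-.":
                    continue
                shared += 1
                if a != b:
                    mism += 1
            if shared == 0:
                raise ValueError(f"no shared ungapped sites for {labels[i]}/{labels[j]}")
            p = mism / shared
            if p >= 0.75:
                raise ValueError(
                    f"saturated pair {labels[i]}/{labels[j]} (p={p:.3f} >= 0.75)")
            m[i, j] = m[j, i] = -0.75 * math.log(1.0 - 4.0 * p / 3.0)
    return DistanceMatrix(labels=labels, matrix=m)


def bionj(dm: DistanceMatrix) -> TreeNode:
    """BIONJ tree from a distance matrix; returns an unrooted tree represented
    with a trifurcating root (for >=3 taxa)."""
    dm.validate()
    n = len(dm.labels)
    if n < 3:
        raise ValueError("BIONJ needs at least 3 taxa")
    nodes = [TreeNode(label=lab) for lab in dm.labels]
    D = dm.matrix.astype(float).copy()
    V = D.copy()
    active = list(range(n))

    while len(active) > 3:
        r = len(active)
        S = {i: sum(D[i, k] for k in active if k != i) for i in active}
        best = None
        best_pair = None
        for ai in range(r):
            for aj in range(ai + 1, r):
                i, j = active[ai], active[aj]
                q = (r - 2) * D[i, j] - S[i] - S[j]
                if best is None or q < best - 1e-15:
                    best = q
                    best_pair = (i, j)
        i, j = best_pair
        b_i = 0.5 * D[i, j] + (S[i] - S[j]) / (2.0 * (r - 2))
        b_j = D[i, j] - b_i
        b_i, b_j = max(b_i, 0.0), max(b_j, 0.0)
        if V[i, j] > 1e-12:
            lam = 0.5 + sum(V[j, k] - V[i, k] for k in active
                            if k != i and k != j) / (2.0 * (r - 2) * V[i, j])
            lam = min(1.0, max(0.0, lam))
        else:
            lam = 0.5
        u = TreeNode(children=[(nodes[i], b_i), (nodes[j], b_j)])
        # grow matrices by one row/col for the new node
        m = D.shape[0]
        D = np.pad(D, ((0, 1), (0, 1)))
        V = np.pad(V, ((0, 1), (0, 1)))
        for k in active:
            if k == i or k == j:
                continue
            D[m, k] = D[k, m] = lam * (D[i, k] - b_i) + (1 - lam) * (D[j, k] - b_j)
            V[m, k] = V[k, m] = lam * V[i, k] + (1 - lam) * V[j, k] \
                - lam * (1 - lam) * V[i, j]
        nodes.append(u)
        active = [k for k in active if k not in (i, j)] + [m]

    x, y, z = active
    b_x = 0.5 * (D[x, y] + D[x, z] - D[y, z])
    b_y = 0.5 * (D[x, y] + D[y, z] - D[x, z])
    b_z = 0.5 * (D[x, z] + D[y, z] - D[x, y])
    return TreeNode(children=[(nodes[x], max(b_x, 0.0)),
                              (nodes[y], max(b_y, 0.0)),
                              (nodes[z], max(b_z, 0.0))])


# ---------------------------------------------------------------------------
# midpoint rooting


def _adjacency(tree: TreeNode):
    nodes = []
    adj: dict[int, list[tuple[int, float]]] = {}

    def visit(node: TreeNode) -> int:
        idx = len(nodes)
        nodes.append(node)
        adj[idx] = []
        for child, bl in node.children:
            cidx = visit(child)
            adj[idx].append((cidx, float(bl)))
            adj[cidx].append((idx, float(bl)))
        return idx

    visit(tree)
    return nodes, adj


def _farthest(adj, start: int, leaf_set: set[int]):
    dist = {start: 0.0}
    parent = {start: None}
    stack = [start]
    while stack:
        u = stack.pop()
        for v, w in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + w
                parent[v] = u
                stack.append(v)
    best = max((d, u) for u, d in dist.items() if u in leaf_set)
    d, u = best
    path = [u]
    while parent[u] is not None:
        u = parent[u]
        path.append(u)
    return d, list(reversed(path)), dist


def path_lengths(tree: TreeNode) -> dict[tuple[str, str], float]:
    """Leaf-to-leaf path lengths (keys are sorted label pairs)."""
    nodes, adj = _adjacency(tree)
    leaves = [i for i, nd in enumerate(nodes) if nd.is_leaf()]
    out = {}
    for i in leaves:
        dist = {i: 0.0}
        stack = [i]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for j in leaves:
            if j == i:
                continue
            key = tuple(sorted((nodes[i].label, nodes[j].label)))
            out[key] = dist[j]
    return out


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Root at the midpoint of the longest leaf-to-leaf path.

    Total path lengths are preserved; re-rooting a midpoint-rooted tree is a
    fixed point. A tree with zero total branch length is an error.
    """
    nodes, adj = _adjacency(tree)
    leaf_set = {i for i, nd in enumerate(nodes) if nd.is_leaf()}
    if len(leaf_set) < 2:
        raise ValueError("midpoint rooting needs at least two leaves")
    a = min(leaf_set)
    _, path_a, _ = _farthest(adj, a, leaf_set)
    u = path_a[-1]  # farthest leaf from an arbitrary leaf: one diameter end
    diam, path, _ = _farthest(adj, u, leaf_set)
    if diam <= 0:
        raise ValueError("tree has zero total branch length")
    half = diam / 2.0
    # walk the path from u until the midpoint
    acc = 0.0
    for idx in range(len(path) - 1):
        x, y = path[idx], path[idx + 1]
        w = next(wt for v, wt in adj[x] if v == y)
        if acc + w >= half - 1e-12:
            offset = half - acc
            return _reroot_on_edge(nodes, adj, x, y, offset)
        acc += w
    raise RuntimeError("midpoint not found on diameter path")  # pragma: no cover


def _reroot_on_edge(nodes, adj, x: int, y: int, offset: float) -> TreeNode:
    """New root on edge (x, y) at ``offset`` from x."""
    def build(u: int, parent: int) -> TreeNode:
        nd = nodes[u]
        out = TreeNode(label=nd.label)
        for v, w in adj[u]:
            if v == parent:
                continue
            out.children.append((build(v, u), w))
        return out

    w_xy = next(wt for v, wt in adj[x] if v == y)
    eps = 1e-12
    if offset <= eps:  # midpoint on node x
        return build(x, -1)
    if offset >= w_xy - eps:  # midpoint on node y
        return build(y, -1)
    left = build(x, y)
    right = build(y, x)
    return TreeNode(children=[(left, offset), (right, w_xy - offset)])


# ---------------------------------------------------------------------------
# Newick I/O


def to_newick(tree: TreeNode) -> str:
    def fmt(node: TreeNode) -> str:
        if node.is_leaf():
            return node.label or ""
        inner = ",".join(f"{fmt(c)}:{bl:.10g}" for c, bl in node.children)
        return f"({inner}){node.label or ''}"

    return fmt(tree) + ";"


def parse_newick(text: str) -> TreeNode:
    text = text.strip()
    if not text.endswith(";"):
        raise ValueError("newick string must end with ';'")
    pos = 0

    def parse_node() -> tuple[TreeNode, float]:
        nonlocal pos
        node = TreeNode()
        if text[pos] == "(":
            pos += 1
            while True:
                child, bl = parse_node()
                node.children.append((child, bl))
                if text[pos] == ",":
                    pos += 1
                    continue
                if text[pos] == ")":
                    pos += 1
                    break
        # label
        start = pos
        while pos < len(text) and text[pos] not in ":,();":
            pos += 1
        label = text[start:pos].strip()
        if label:
            node.label = label
        bl = 0.0
        if pos < len(text) and text[pos] == ":":
            pos += 1
            start = pos
            while pos < len(text) and text[pos] not in ",();":
                pos += 1
            bl = float(text[start:pos])
        return node, bl

    tree, _ = parse_node()
    if text[pos:] != ";":
        raise ValueError("trailing characters in newick string")
    return tree


def topologies_equal(a: TreeNode, b: TreeNode) -> bool:
    """Unrooted topological equality via leaf bipartitions."""
    return _bipartitions(a) == _bipartitions(b)


def _bipartitions(tree: TreeNode) -> set[frozenset]:
    all_leaves = frozenset(n.label for n in tree.leaves())
    parts = set()

    def visit(node: TreeNode) -> frozenset:
        if node.is_leaf():
            return frozenset([node.label])
        below = frozenset()
        for child, _ in node.children:
            below |= visit(child)
        if 1 < len(below) < len(all_leaves) - 1:
            parts.add(min(below, all_leaves - below,
                          key=lambda s: (len(s), tuple(sorted(s)))))
        return below

    visit(tree)
    return parts
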