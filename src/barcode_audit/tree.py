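"""Neighbor-joining trees, midpoint rooting, and species monophyly calls.

Trees are held as :class:`skbio.TreeNode` objects (newick I/O comes from
scikit-bio).  Neighbor joining is implemented here rather than delegated so
that tie-breaking is fully specified — all ties are resolved
lexicographically on specimen ids, which makes tree construction
bit-reproducible across runs and input orderings.

Monophyly is assessed on a rooted tree: a species is *monophyletic* when
some clade contains exactly its specimens, *paraphyletic* when the
non-conspecific leaves under its MRCA themselves form a single clade, and
*polyphyletic* otherwise.  Species with a single specimen are *singleton*.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
from skbio import TreeNode

from .distance import DistanceMatrix

__all__ = [
    "MonophylyStatus",
    "neighbor_joining",
    "midpoint_root",
    "classify_species_monophyly",
    "leaf_distances",
    "write_newick",
    "read_newick",
]


@dataclass(frozen=True)
class MonophylyStatus:
    species_label: str
    status: str  # monophyletic | paraphyletic | polyphyletic | singleton
    intruding_ids: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# Neighbor joining


def neighbor_joining(matrix: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor joining with the Studier–Keppler criterion.

    At each step the pair minimising Q(i,j) = (n-2)·d(i,j) - R(i) - R(j) is
    joined; exact ties are broken by the lexicographically smallest sorted
    pair of node labels, where an internal node is labelled by the smallest
    specimen id beneath it.  Branch lengths follow the standard NJ formulas
    and are retained even when negative.  The result is unrooted, returned
    with a trifurcating root node.
    """
    m = len(matrix)
    if m < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if np.isnan(matrix.d).any():
        bad = np.argwhere(np.isnan(matrix.d))[0]
        raise ValueError(
            f"undefined distance between {matrix.ids[bad[0]]!r} and {matrix.ids[bad[1]]!r}"
        )

    nodes: list[TreeNode] = [TreeNode(name=sid) for sid in matrix.ids]
    labels: list[str] = list(matrix.ids)
    D = matrix.d.copy().astype(float)

    while len(nodes) > 3:
        n = len(nodes)
        R = D.sum(axis=1)
        Q = (n - 2) * D - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cand = np.argwhere(Q == qmin)
        best = None
        for i, j in cand:
            if i == j:
                continue
            i, j = (int(i), int(j)) if i < j else (int(j), int(i))
            key = tuple(sorted((labels[i], labels[j])))
            if best is None or key < best[0]:
                best = (key, i, j)
        assert best is not None
        _, i, j = best
        dij = D[i, j]
        limb_i = 0.5 * dij + (R[i] - R[j]) / (2.0 * (n - 2))
        limb_j = dij - limb_i
        parent = TreeNode()
        a, b = nodes[i], nodes[j]
        a.length, b.length = float(limb_i), float(limb_j)
        parent.append(a)
        parent.append(b)

        new_d = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [k for k in range(n) if k not in (i, j)]
        D = np.vstack([D[keep][:, keep], new_d[keep][None, :]])
        D = np.hstack([D, np.append(new_d[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]
        labels = [labels[k] for k in keep] + [min(labels[i], labels[j])]

    # final 3-node star: closed-form limb lengths
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    lengths = (
        0.5 * (d01 + d02 - d12),
        0.5 * (d01 + d12 - d02),
        0.5 * (d02 + d12 - d01),
    )
    root = TreeNode()
    for node, L in sorted(
        zip(nodes, lengths), key=lambda t: _min_leaf_name(t[0])
    ):
        node.length = float(L)
        root.append(node)
    return root


def _min_leaf_name(node: TreeNode) -> str:
    if node.is_tip():
        return node.name
    return min(t.name for t in node.tips())


# ---------------------------------------------------------------------------
# Generic undirected view and rerooting


def _adjacency(tree: TreeNode) -> tuple[dict[int, list[tuple[int, float]]], dict[int, str]]:
    """Undirected weighted adjacency over node ids, plus leaf names."""
    adj: dict[int, list[tuple[int, float]]] = {}
    names: dict[int, str] = {}
    for node in tree.traverse(include_self=True):
        adj.setdefault(id(node), [])
        if node.is_tip():
            names[id(node)] = node.name
        for child in node.children:
            w = float(child.length or 0.0)
            adj[id(node)].append((id(child), w))
            adj.setdefault(id(child), []).append((id(node), w))
    return adj, names


def leaf_distances(tree: TreeNode) -> dict[tuple[str, str], float]:
    """Path lengths between every unordered pair of leaves."""
    adj, names = _adjacency(tree)
    out: dict[tuple[str, str], float] = {}
    for start, start_name in names.items():
        dist = {start: 0.0}
        stack = [start]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for other, other_name in names.items():
            if start_name < other_name:
                out[(start_name, other_name)] = dist[other]
    return out


def _build_rooted(
    adj: Mapping[int, list[tuple[int, float]]],
    names: Mapping[int, str],
    root_id: int,
) -> TreeNode:
    """Rebuild a TreeNode tree from adjacency, rooted at ``root_id``."""

    def rec(u: int, parent: int | None) -> TreeNode:
        node = TreeNode(name=names.get(u))
        for v, w in sorted(adj[u], key=lambda t: t[0]):
            if parent is not None and v == parent:
                continue
            child = rec(v, u)
            child.length = w
            node.append(child)
        return node

    return rec(root_id, None)


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Root an unrooted tree at the midpoint of its longest leaf-leaf path.

    The diameter pair is chosen lexicographically among exact ties.  A tree
    whose diameter is zero is rooted on the edge adjacent to the
    lexicographically first leaf.
    """
    adj, names = _adjacency(tree)
    if len(names) < 2:
        raise ValueError("midpoint rooting needs at least 2 leaves")
    by_name = {v: k for k, v in names.items()}

    # all-pairs leaf distances with predecessor tracking from each leaf
    dists = leaf_distances(tree)
    diameter = max(dists.values())
    if diameter <= 0.0:
        first = min(names.values())
        u = by_name[first]
        v = adj[u][0][0]
        return _root_on_edge(adj, names, u, v, 0.0)

    pair = min(p for p, dd in dists.items() if dd == diameter)
    src, dst = by_name[pair[0]], by_name[pair[1]]

    # explicit path src -> dst
    prev: dict[int, int] = {}
    dist = {src: 0.0}
    stack = [src]
    while stack:
        u = stack.pop()
        for v, w in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + w
                prev[v] = u
                stack.append(v)
    path = [dst]
    while path[-1] != src:
        path.append(prev[path[-1]])
    path.reverse()  # from src (lexicographically smaller leaf) to dst

    half = diameter / 2.0
    for a, b in zip(path, path[1:]):
        if dist[a] <= half <= dist[b]:
            if math.isclose(dist[a], half):
                return _build_rooted(adj, names, a)
            if math.isclose(dist[b], half):
                return _build_rooted(adj, names, b)
            return _root_on_edge(adj, names, a, b, half - dist[a])
    raise AssertionError("midpoint not found on diameter path")


def _root_on_edge(
    adj: Mapping[int, list[tuple[int, float]]],
    names: Mapping[int, str],
    u: int,
    v: int,
    dist_from_u: float,
) -> TreeNode:
    """Split edge (u, v) with a new root at ``dist_from_u`` from u."""
    w = next(wt for nb, wt in adj[u] if nb == v)
    new_id = -1  # ids from id() are positive; -1 is free
    adj2 = {k: [t for t in vs if not _is_edge(k, t, u, v)] for k, vs in adj.items()}
    adj2[new_id] = [(u, dist_from_u), (v, w - dist_from_u)]
    adj2[u].append((new_id, dist_from_u))
    adj2[v].append((new_id, w - dist_from_u))
    return _build_rooted(adj2, names, new_id)


def _is_edge(k: int, entry: tuple[int, float], u: int, v: int) -> bool:
    nb = entry[0]
    return (k == u and nb == v) or (k == v and nb == u)


# ---------------------------------------------------------------------------
# Monophyly


def classify_species_monophyly(
    rooted_tree: TreeNode, species_of: Mapping[str, str]
) -> list[MonophylyStatus]:
    """Classify every species represented on the tree (sorted by label)."""
    leaf_names = [t.name for t in rooted_tree.tips()]
    missing = [n for n in leaf_names if n not in species_of]
    if missing:
        raise ValueError(f"species map does not cover leaves: {missing[:5]}")

    clades: set[frozenset[str]] = set()
    tipsets: dict[int, frozenset[str]] = {}
    for node in rooted_tree.postorder(include_self=True):
        if node.is_tip():
            tipsets[id(node)] = frozenset([node.name])
        else:
            tipsets[id(node)] = frozenset().union(
                *(tipsets[id(c)] for c in node.children)
            )
        clades.add(tipsets[id(node)])

    by_species: dict[str, set[str]] = {}
    for leaf in leaf_names:
        by_species.setdefault(species_of[leaf], set()).add(leaf)

    out = []
    for species in sorted(by_species):
        L = frozenset(by_species[species])
        if len(L) == 1:
            out.append(MonophylyStatus(species, "singleton"))
            continue
        if L in clades:
            out.append(MonophylyStatus(species, "monophyletic"))
            continue
        mrca = rooted_tree.lca(sorted(L))
        under = tipsets[id(mrca)]
        intruders = frozenset(under - L)
        status = "paraphyletic" if intruders in clades else "polyphyletic"
        out.append(MonophylyStatus(species, status, tuple(sorted(intruders))))
    return out


# ---------------------------------------------------------------------------
# Newick I/O


def write_newick(tree: TreeNode, path: str | Path | None = None) -> str:
    buf = io.StringIO()
    tree.write(buf, format="newick")
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def read_newick(source: str | Path) -> TreeNode:
    """Parse newick from a path or a literal newick string."""
    if isinstance(source, Path) or (isinstance(source, str) and not source.rstrip().endswith(";")):
        return TreeNode.read(str(source), format="newick")
    return TreeNode.read(io.StringIO(source), format="newick")
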