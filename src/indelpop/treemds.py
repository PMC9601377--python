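"""Neighbor-joining trees and SMACOF multidimensional scaling.

Neighbor joining (Saitou & Nei) greedily joins the taxon pair minimizing the
Q-criterion, with rate-corrected branch lengths; ties are broken by the
lowest (i, j) pair in input label order, and negative branch lengths are
clamped to zero with the deficit transferred to the sister branch
(Kuhner–Felsenstein) so leaf-to-leaf path lengths are preserved.  The result
is a binary unrooted tree that recovers any additive distance matrix
exactly.

SMACOF minimizes normalized stress-1 by iterated Guttman transforms from a
deterministic classical-scaling (Torgerson) start, so the ordination is
reproducible without seeds; the stress sequence is non-increasing by the
majorization argument.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

from .types import DistanceMatrix, Tree, ValidationError


def neighbor_joining(m: DistanceMatrix) -> Tree:
    """Build the neighbor-joining tree for a distance matrix (>= 3 taxa)."""
    k = m.size
    if k < 3:
        raise ValidationError("neighbor joining needs at least three taxa")
    if not np.all(np.isfinite(m.d)):
        raise ValidationError("non-finite distances")

    tree = Tree()
    active: list[int] = []  # node ids, in input label order then join order
    for label in m.labels:
        active.append(tree.add_node(label))
    dist: dict[tuple[int, int], float] = {}
    for i in range(k):
        for j in range(i + 1, k):
            dist[(active[i], active[j])] = float(m.d[i, j])

    def d(u: int, v: int) -> float:
        return dist[(u, v)] if (u, v) in dist else dist[(v, u)]

    while len(active) > 3:
        r = len(active)
        net = {u: sum(d(u, v) for v in active if v != u) for u in active}
        best, best_q = None, np.inf
        for a in range(r):
            for b in range(a + 1, r):
                u, v = active[a], active[b]
                q = (r - 2) * d(u, v) - net[u] - net[v]
                if q < best_q - 1e-12:
                    best, best_q = (a, b), q
        a, b = best
        u, v = active[a], active[b]
        duv = d(u, v)
        lu = duv / 2.0 + (net[u] - net[v]) / (2.0 * (r - 2))
        lv = duv - lu
        # clamp a negative branch to zero, moving the deficit to the sister
        if lu < 0:
            lv += lu
            lu = 0.0
        if lv < 0:
            lu += lv
            lv = 0.0
        new = tree.add_node()
        tree.add_edge(u, new, max(lu, 0.0))
        tree.add_edge(v, new, max(lv, 0.0))
        for w in active:
            if w == u or w == v:
                continue
            dist[(new, w)] = 0.5 * (d(u, w) + d(v, w) - duv)
        active = [w for w in active if w not in (u, v)] + [new]

    # final three-way join: branch lengths solve the three path equations
    u, v, w = active
    center = tree.add_node()
    lu = (d(u, v) + d(u, w) - d(v, w)) / 2.0
    lv = (d(u, v) + d(v, w) - d(u, w)) / 2.0
    lw = (d(u, w) + d(v, w) - d(u, v)) / 2.0
    tree.add_edge(u, center, max(lu, 0.0))
    tree.add_edge(v, center, max(lv, 0.0))
    tree.add_edge(w, center, max(lw, 0.0))
    tree.validate(labels=list(m.labels))
    return tree


def _min_leaf(tree: Tree, node: int, parent: int) -> str:
    """Lexicographically smallest leaf label in the subtree away from parent."""
    if node in tree.leaf_name:
        return tree.leaf_name[node]
    return min(
        _min_leaf(tree, child, node)
        for child in tree.neighbors(node)
        if child != parent
    )


def to_newick(tree: Tree, precision: int = 6) -> str:
    """Serialize an unrooted tree as Newick with deterministic child order.

    The tree is written from the internal node adjacent to the smallest leaf
    label; at every level children are ordered by their smallest descendant
    leaf label, so equal trees produce identical strings.
    """
    smallest = min(tree.leaf_name.values())
    leaf_node = tree.leaves[smallest]
    root = next(iter(tree.neighbors(leaf_node)))

    def render(node: int, parent: int) -> str:
        if node in tree.leaf_name:
            return f"{tree.leaf_name[node]}:{tree.neighbors(node)[parent]:.{precision}f}"
        parts = sorted(
            (
                (_min_leaf(tree, child, node), render(child, node))
                for child in tree.neighbors(node)
                if child != parent
            ),
        )
        inner = ",".join(p[1] for p in parts)
        if parent == -1:
            return f"({inner})"
        return f"({inner}):{tree.neighbors(node)[parent]:.{precision}f}"

    return render(root, -1) + ";"


def from_newick(text: str) -> Tree:
    """Parse a Newick string into an unrooted :class:`~indelpop.types.Tree`.

    A degree-2 root (rooted binary input) is suppressed by merging its two
    incident edges, so round trips through :func:`to_newick` preserve the
    unrooted topology and branch lengths.
    """
    dtree = dendropy.Tree.get(data=text, schema="newick")
    tree = Tree()
    node_map: dict = {}
    for node in dtree.preorder_node_iter():
        name = node.taxon.label if node.taxon is not None else None
        node_map[node] = tree.add_node(name)
        if node.parent_node is not None:
            length = node.edge.length if node.edge.length is not None else 0.0
            tree.add_edge(node_map[node.parent_node], node_map[node], float(length))
    # suppress a degree-2 root left by rooted input
    root = node_map[dtree.seed_node]
    if tree.degree(root) == 2 and root not in tree.leaf_name:
        (a, la), (b, lb) = tree.neighbors(root).items()
        del tree._adj[root]
        del tree._adj[a][root]
        del tree._adj[b][root]
        tree.add_edge(a, b, la + lb)
    return tree


@dataclass(frozen=True)
class MDSResult:
    """A 2-D (or k-D) ordination with its normalized stress-1."""

    labels: tuple[str, ...]
    coords: np.ndarray
    stress: float
    n_iter: int


def _stress1(delta: np.ndarray, x: np.ndarray) -> float:
    dcfg = _config_distances(x)
    iu = np.triu_indices(len(x), k=1)
    num = np.sum((delta[iu] - dcfg[iu]) ** 2)
    den = np.sum(delta[iu] ** 2)
    return float(np.sqrt(num / den)) if den > 0 else 0.0


def _config_distances(x: np.ndarray) -> np.ndarray:
    diff = x[:, None, :] - x[None, :, :]
    return np.sqrt(np.sum(diff**2, axis=-1))


def torgerson(m: DistanceMatrix, dim: int = 2) -> np.ndarray:
    """Classical scaling: spectral embedding of the double-centered squared
    distances (the deterministic SMACOF start)."""
    d2 = m.d**2
    k = m.size
    j = np.eye(k) - np.ones((k, k)) / k
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:dim]
    lam = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(lam)


def smacof_mds(
    m: DistanceMatrix,
    dim: int = 2,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    init: np.ndarray | None = None,
) -> MDSResult:
    """Stress-majorization MDS via the Guttman transform.

    Iterates until the stress decrease falls below ``tol`` or ``max_iter``
    is reached; returns centered coordinates and the final normalized
    stress-1.  An all-zero input collapses every point to the origin with
    zero stress.
    """
    if dim < 1:
        raise ValidationError("dim must be >= 1")
    delta = m.d
    k = m.size
    if np.all(delta == 0):
        return MDSResult(tuple(m.labels), np.zeros((k, dim)), 0.0, 0)

    x = torgerson(m, dim) if init is None else np.asarray(init, dtype=float).copy()
    stress = _stress1(delta, x)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        dcfg = _config_distances(x)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dcfg > 0, delta / dcfg, 0.0)
        np.fill_diagonal(ratio, 0.0)
        b = -ratio
        np.fill_diagonal(b, ratio.sum(axis=1))
        x_new = (b @ x) / k
        stress_new = _stress1(delta, x_new)
        if stress_new > stress + 1e-12:
            raise AssertionError("SMACOF stress increased")
        x = x_new
        if stress - stress_new < tol:
            stress = stress_new
            break
        stress = stress_new
    x = x - x.mean(axis=0)
    return MDSResult(tuple(m.labels), x, stress, n_iter)


def write_mds_coordinates(result: MDSResult, path) -> None:
    """Delimited coordinate table with the stress in a header comment."""
    with open(path, "w") as fh:
        fh.write(f"# stress1={result.stress:.8f} n_iter={result.n_iter}\n")
        fh.write("label," + ",".join(f"dim{i + 1}" for i in range(result.coords.shape[1])) + "\n")
        for label, row in zip(result.labels, result.coords):
            fh.write(label + "," + ",".join(f"{v:.8f}" for v in row) + "\n")
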