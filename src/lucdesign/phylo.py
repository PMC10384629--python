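"""Distance-based phylogenetics: identity distances, neighbor joining, Newick.

Pairwise identity is computed from the in-package global aligner
(matching columns over total alignment columns, gap columns included by
default) and converted to the distance 1 - identity. Trees are built with
the Saitou–Nei neighbor-joining algorithm with a deterministic tie-break,
so results are bit-reproducible. Negative branch lengths — a known NJ
artifact on non-additive matrices — are clamped to zero and logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np

from .align import ScoringScheme, global_align
from .errors import ValidationError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple
    d: np.ndarray

    def __post_init__(self):
        labels = tuple(self.labels)
        object.__setattr__(self, "labels", labels)
        d = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "d", d)
        n = len(labels)
        if len(set(labels)) != n:
            raise ValidationError("duplicate labels in distance matrix")
        if d.shape != (n, n):
            raise ValidationError(f"distance matrix shape {d.shape} != ({n}, {n})")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValidationError("distance matrix must be symmetric")
        if np.any(np.diag(d) != 0):
            raise ValidationError("distance matrix diagonal must be zero")
        if np.any(d < 0):
            raise ValidationError("distances must be non-negative")

    def to_tsv(self) -> str:
        lines = ["\t" + "\t".join(self.labels)]
        for lab, row in zip(self.labels, self.d):
            lines.append(lab + "\t" + "\t".join(f"{x:.6f}" for x in row))
        return "\n".join(lines) + "\n"


def identity_distance_matrix(
    records: Sequence,
    scheme: ScoringScheme | None = None,
    gap_columns_in_denominator: bool = True,
) -> DistanceMatrix:
    """Pairwise 1 - identity distances from global alignments."""
    labels = [r.id for r in records]
    if len(labels) != len(set(labels)):
        raise ValidationError("duplicate record ids")
    if len(records) < 2:
        raise ValidationError("need at least two records")
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aln = global_align(records[i].seq, records[j].seq, scheme)
            if gap_columns_in_denominator:
                ident = aln.identity
            else:
                cols = sum(
                    1 for x, y in zip(aln.row_a, aln.row_b) if x != "-" and y != "-"
                )
                ident = aln.matches / cols if cols else 0.0
            d[i, j] = d[j, i] = 1.0 - ident
    return DistanceMatrix(tuple(labels), d)


@dataclass(frozen=True)
class PhyloTree:
    """Unrooted tree; leaves carry labels, internal nodes are anonymous."""

    graph: nx.Graph
    leaves: tuple

    def __post_init__(self):
        for leaf in self.leaves:
            if leaf not in self.graph:
                raise ValidationError(f"leaf {leaf!r} missing from graph")

    def branch_length(self, u, v) -> float:
        return self.graph.edges[u, v]["length"]

    def leaf_distance(self, a: str, b: str) -> float:
        return nx.shortest_path_length(self.graph, a, b, weight="length")

    def distance_matrix(self, labels: Sequence | None = None) -> DistanceMatrix:
        labels = tuple(labels or sorted(self.leaves))
        n = len(labels)
        d = np.zeros((n, n))
        for i in range(n):
            lengths = nx.shortest_path_length(self.graph, labels[i], weight="length")
            for j in range(n):
                d[i, j] = lengths[labels[j]]
        np.fill_diagonal(d, 0.0)
        d = 0.5 * (d + d.T)  # kill float asymmetry from path summation order
        return DistanceMatrix(labels, d)


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q criterion are resolved toward the lexicographically
    smallest pair of cluster keys (a cluster's key is its smallest leaf
    label). Negative branch lengths are clamped to zero with a warning.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValidationError("neighbor joining needs at least 3 taxa")
    g = nx.Graph()
    # active clusters: node id in graph, sort key, row in working matrix
    nodes = list(dm.labels)
    keys = list(dm.labels)
    D = dm.d.copy()
    g.add_nodes_from(nodes)
    internal_count = 0

    def clamp(x: float, context: str) -> float:
        if x < 0:
            log.warning("negative NJ branch length %.3g at %s clamped to 0", x, context)
            return 0.0
        return x

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * D[i, j] - r[i] - r[j]
                pair_key = tuple(sorted((keys[i], keys[j])))
                cand = (q, pair_key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        bi = clamp(0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2)), f"join({keys[i]},{keys[j]})")
        bj = clamp(D[i, j] - bi, f"join({keys[i]},{keys[j]})")
        internal_count += 1
        new = f"_nj{internal_count}"
        g.add_edge(nodes[i], new, length=bi)
        g.add_edge(nodes[j], new, length=bj)
        newrow = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D = np.vstack([D[keep][:, keep], newrow[keep]])
        D = np.column_stack([D, np.append(newrow[keep], 0.0)])
        new_key = min(keys[i], keys[j])
        nodes = [nodes[k] for k in keep] + [new]
        keys = [keys[k] for k in keep] + [new_key]

    # final three clusters join at one internal node (closed form)
    d12, d13, d23 = D[0, 1], D[0, 2], D[1, 2]
    internal_count += 1
    centre = f"_nj{internal_count}"
    b = (
        clamp(0.5 * (d12 + d13 - d23), "final"),
        clamp(0.5 * (d12 + d23 - d13), "final"),
        clamp(0.5 * (d13 + d23 - d12), "final"),
    )
    for node, length in zip(nodes, b):
        g.add_edge(node, centre, length=length)
    return PhyloTree(g, tuple(dm.labels))


# ---------------------------------------------------------------------------
# Newick


def _newick_label(label: str) -> str:
    if any(c in label for c in " \t(),:;'[]"):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: PhyloTree, precision: int = 10) -> str:
    """Newick text with branch lengths, rooted for writing at an internal
    node adjacent to the lexicographically smallest leaf."""
    g = tree.graph
    start_leaf = min(tree.leaves)
    root = next(iter(g.neighbors(start_leaf)))

    def render(node, parent) -> str:
        children = [v for v in g.neighbors(node) if v != parent]
        if not children:
            return _newick_label(str(node))
        inner = ",".join(
            f"{render(c, node)}:{g.edges[node, c]['length']:.{precision}g}" for c in children
        )
        return f"({inner})"

    return render(root, None) + ";"


def is_monophyletic(tree: PhyloTree, labels: Sequence) -> bool:
    """True if some edge separates exactly ``labels`` from the other leaves."""
    want = set(labels)
    if not want <= set(tree.leaves):
        raise ValidationError("labels are not all leaves of the tree")
    g = tree.graph
    leafset = set(tree.leaves)
    for u, v in g.edges:
        h = g.copy()
        h.remove_edge(u, v)
        side = set(nx.node_connected_component(h, u)) & leafset
        if side == want or (leafset - side) == want:
            return True
    return False


# ---------------------------------------------------------------------------
# Synthetic additive trees (oracle inputs for NJ checking)


def random_additive_tree(
    labels: Sequence, rng: np.random.Generator, length_range: tuple = (0.1, 1.0)
) -> PhyloTree:
    """Random unrooted binary tree with uniform branch lengths.

    NJ is exact on the additive distance matrix of such a tree, which
    makes these trees independent ground truth for the implementation.
    """
    labels = list(labels)
    if len(labels) < 3:
        raise ValidationError("need at least 3 leaves")
    lo, hi = length_range

    def blen() -> float:
        return float(rng.uniform(lo, hi))

    g = nx.Graph()
    centre = "_t1"
    counter = [1]
    for lab in labels[:3]:
        g.add_edge(lab, centre, length=blen())
    for lab in labels[3:]:
        edges = sorted(g.edges, key=str)
        u, v = edges[rng.integers(len(edges))]
        length = g.edges[u, v]["length"]
        split = float(rng.uniform(0.2, 0.8))
        counter[0] += 1
        mid = f"_t{counter[0]}"
        g.remove_edge(u, v)
        g.add_edge(u, mid, length=length * split)
        g.add_edge(mid, v, length=length * (1 - split))
        g.add_edge(mid, lab, length=blen())
    return PhyloTree(g, tuple(labels))
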