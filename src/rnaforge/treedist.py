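"""Ordered tree edit distance between shape trees (Zhang-Shasha).

The distance is the minimum total cost of node insertions, deletions and
relabelings transforming one ordered tree into the other while preserving
sibling order and ancestry.  The production algorithm is the Zhang-Shasha
keyroot dynamic programme (O(n1*n2*min(depth,leaves)^2)); an exponential
memoized forest-distance recursion lives in the test suite as the
independent oracle.

The default cost model mirrors the weighted coarse-grain convention:
deleting or inserting a node costs its weight; relabeling two nodes of the
same type costs the absolute weight difference, and of different types the
sum of the weights.  Roots always match (``relabel(R, R) = 0``), so the
distance from any shape to the bare root equals the total weight of its
non-root nodes.  For unweighted trees every weight is 1 and the model
degenerates to unit costs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

from .shape import ShapiroTree


@dataclass(frozen=True)
class EditCosts:
    """Cost model for tree edits; ``relabel`` must be symmetric and zero on
    identical labels."""

    indel: Callable[[ShapiroTree], float]
    relabel: Callable[[ShapiroTree, ShapiroTree], float]


def default_costs() -> EditCosts:
    """The weighted Shapiro-style cost model described in the module docs."""

    def indel(n: ShapiroTree) -> float:
        return float(n.weight)

    def relabel(a: ShapiroTree, b: ShapiroTree) -> float:
        if a.label == b.label:
            return float(abs(a.weight - b.weight))
        return float(a.weight + b.weight)

    return EditCosts(indel=indel, relabel=relabel)


def _postorder(root: ShapiroTree):
    """Postorder node list and, for each node, the index of its leftmost leaf."""
    nodes: list[ShapiroTree] = []
    lml: list[int] = []

    def visit(node: ShapiroTree) -> int:
        first = None
        for c in node.children:
            idx = visit(c)
            if first is None:
                first = lml[idx]
        nodes.append(node)
        lml.append(first if first is not None else len(nodes) - 1)
        return len(nodes) - 1

    visit(root)
    return nodes, lml


def _keyroots(lml: list[int]) -> list[int]:
    seen: dict[int, int] = {}
    for i, l in enumerate(lml):
        seen[l] = i  # last (highest) node with this leftmost leaf
    return sorted(seen.values())


def tree_edit_distance(
    a: ShapiroTree, b: ShapiroTree, costs: EditCosts | None = None
) -> float:
    """Minimum-cost edit distance between two ordered trees."""
    if costs is None:
        costs = default_costs()
    an, al = _postorder(a)
    bn, bl = _postorder(b)
    na, nb = len(an), len(bn)
    akr, bkr = _keyroots(al), _keyroots(bl)

    td = [[0.0] * nb for _ in range(na)]

    for i in akr:
        for j in bkr:
            # forest distance over subforests rooted at keyroots i, j
            li, lj = al[i], bl[j]
            m, n = i - li + 2, j - lj + 2
            fd = [[0.0] * n for _ in range(m)]
            for x in range(1, m):
                fd[x][0] = fd[x - 1][0] + costs.indel(an[li + x - 1])
            for y in range(1, n):
                fd[0][y] = fd[0][y - 1] + costs.indel(bn[lj + y - 1])
            for x in range(1, m):
                for y in range(1, n):
                    u, v = li + x - 1, lj + y - 1
                    if al[u] == li and bl[v] == lj:
                        fd[x][y] = min(
                            fd[x - 1][y] + costs.indel(an[u]),
                            fd[x][y - 1] + costs.indel(bn[v]),
                            fd[x - 1][y - 1] + costs.relabel(an[u], bn[v]),
                        )
                        td[u][v] = fd[x][y]
                    else:
                        fd[x][y] = min(
                            fd[x - 1][y] + costs.indel(an[u]),
                            fd[x][y - 1] + costs.indel(bn[v]),
                            fd[al[u] - li][bl[v] - lj] + td[u][v],
                        )
    return td[na - 1][nb - 1]


def shape_distance(
    a: ShapiroTree, b: ShapiroTree, costs: EditCosts | None = None
) -> float:
    """Alias for :func:`tree_edit_distance` (reads better at call sites)."""
    return tree_edit_distance(a, b, costs)
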