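"""Coarse-grained (Shapiro) shape representation of a secondary structure.

A structure is abstracted to an ordered, labelled, weighted tree over the
node types

=====  =============================================================
``R``  virtual root (the exterior loop)
``E``  a run of unpaired external bases (weight = run length)
``S``  a maximal helix (weight = number of stacked pairs)
``H``  a hairpin loop (weight = number of unpaired bases)
``B``  a bulge — unpaired bases on exactly one strand between helices
``I``  an interior loop — unpaired bases on both strands
``M``  a multiloop, >= 3 emanating helices (weight = unpaired bases,
       possibly 0)
=====  =============================================================

Two structures that differ only in helix lengths and loop sizes but share
the motif topology have identical unweighted shape strings; the weighted
variant additionally records motif sizes.  The canonical linear rendering
places children 5'->3' and ends in ``R``, e.g. ``((H3)S3)R`` for a
three-pair hairpin.  ViennaRNA's ``b2shapiro`` dialect differs slightly
(the whole string is wrapped in one extra pair of parentheses and all
external unpaired bases are pooled into a single trailing ``E`` node); the
test suite cross-checks against it where the dialects coincide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .structures import PairTable


class ShapiroError(ValueError):
    """Malformed shape string."""


NODE_TYPES = frozenset("RESHBIM")


@dataclass(frozen=True)
class ShapiroTree:
    """A node of the ordered shape tree (the root has label ``R``)."""

    label: str
    weight: int = 1
    children: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if self.label not in NODE_TYPES:
            raise ShapiroError(f"unknown node type {self.label!r}")
        if self.weight < 0:
            raise ShapiroError("node weight must be >= 0")
        object.__setattr__(self, "children", tuple(self.children))

    def nodes(self):
        """All nodes in postorder (children left-to-right, then self)."""
        for c in self.children:
            yield from c.nodes()
        yield self

    def __len__(self) -> int:
        return sum(1 for _ in self.nodes())


def to_shapiro(pt: PairTable, weighted: bool = True) -> ShapiroTree:
    """Decompose a structure into its coarse-grained shape tree.

    With ``weighted=False`` every weight is set to 1, so that only the
    motif topology is retained.
    """
    partner = pt.partner
    n = pt.length

    def helix(i: int, j: int) -> ShapiroTree:
        # maximal stack of pairs (i+k, j-k); any unpaired base or branching
        # terminates it (no lonely-pair smoothing)
        h = 0
        while (
            i + h < j - h
            and partner[i + h] == j - h
        ):
            h += 1
        a, b = i + h, j - h  # enclosed region (inclusive)
        branches = []
        unpaired = 0
        k = a
        while k <= b:
            if partner[k] > k:
                branches.append((k, partner[k]))
                k = partner[k] + 1
            else:
                unpaired += 1
                k += 1
        if not branches:
            loop = ShapiroTree("H", b - a + 1)
        elif len(branches) == 1:
            (c, d) = branches[0]
            left, right = c - a, b - d
            label = "I" if (left > 0 and right > 0) else "B"
            loop = ShapiroTree(label, unpaired, (helix(c, d),))
        else:
            loop = ShapiroTree(
                "M", unpaired, tuple(helix(c, d) for c, d in branches)
            )
        return ShapiroTree("S", h, (loop,))

    children = []
    run = 0
    k = 0
    while k < n:
        if partner[k] > k:
            if run:
                children.append(ShapiroTree("E", run))
                run = 0
            children.append(helix(k, partner[k]))
            k = partner[k] + 1
        else:
            run += 1
            k += 1
    if run:
        children.append(ShapiroTree("E", run))
    tree = ShapiroTree("R", 0, tuple(children))
    if not weighted:
        tree = strip_weights(tree)
    return tree


def strip_weights(t: ShapiroTree) -> ShapiroTree:
    """Copy of the tree with every weight set to 1 (root keeps 0)."""
    w = 0 if t.label == "R" else 1
    return ShapiroTree(t.label, w, tuple(strip_weights(c) for c in t.children))


def shapiro_to_string(t: ShapiroTree, weights: bool = True) -> str:
    """Canonical linear rendering, e.g. ``((H3)S3)R``; root carries no weight."""

    def render(node: ShapiroTree) -> str:
        inner = "".join(render(c) for c in node.children)
        w = str(node.weight) if weights else ""
        return f"({inner}{node.label}{w})"

    body = "".join(render(c) for c in t.children)
    return body + "R"


def parse_shapiro(text: str) -> ShapiroTree:
    """Parse a linear shape string back into a tree.

    Inverts :func:`shapiro_to_string`; missing weights default to 1.
    Raises :class:`ShapiroError` with the offending index on malformed input.
    """
    s = text.strip()
    pos = 0

    def fail(msg: str):
        raise ShapiroError(f"{msg} at position {pos + 1} in {s!r}")

    def parse_node() -> ShapiroTree:
        nonlocal pos
        if pos >= len(s) or s[pos] != "(":
            fail("expected '('")
        pos += 1
        children = []
        while pos < len(s) and s[pos] == "(":
            children.append(parse_node())
        if pos >= len(s) or s[pos] not in NODE_TYPES or s[pos] == "R":
            fail("expected node label")
        label = s[pos]
        pos += 1
        digits = ""
        while pos < len(s) and s[pos].isdigit():
            digits += s[pos]
            pos += 1
        if pos >= len(s) or s[pos] != ")":
            fail("expected ')'")
        pos += 1
        return ShapiroTree(label, int(digits) if digits else 1, tuple(children))

    children = []
    while pos < len(s) and s[pos] == "(":
        children.append(parse_node())
    if pos >= len(s) or s[pos] != "R":
        fail("expected 'R'")
    pos += 1
    if pos != len(s):
        fail("trailing characters")
    return ShapiroTree("R", 0, tuple(children))
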