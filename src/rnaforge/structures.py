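"""Dot-bracket secondary structures: parsing, rendering, validation, distances.

A secondary structure is held as a :class:`PairTable` — the sequence length
plus the set of base pairs ``(i, j)`` with ``i < j`` (0-based).  Structures
are pseudoknot-free by construction (single bracket alphabet) and must
respect the minimum hairpin size of three unpaired bases, which matches the
constraint of every folding backend so that no target is unattainable by
construction.  All user-facing reports are 1-based; everything here is
0-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import cached_property

RNA_ALPHABET = "ACGU"

#: the six canonical (Watson-Crick + wobble) pairs
CANONICAL_PAIRS = frozenset(
    [("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")]
)

#: minimum number of unpaired bases enclosed by an innermost pair
MIN_HAIRPIN = 3


class StructureError(ValueError):
    """Malformed or invalid secondary structure or sequence."""


def clean_sequence(seq: str) -> str:
    """Normalise an RNA sequence: uppercase, DNA ``T`` -> ``U`` (with a warning).

    Raises :class:`StructureError` on any residue outside ``{A, C, G, U}``
    after normalisation.
    """
    s = seq.strip().upper()
    if "T" in s:
        warnings.warn("sequence contains T; converting to U", stacklevel=2)
        s = s.replace("T", "U")
    for idx, ch in enumerate(s):
        if ch not in RNA_ALPHABET:
            raise StructureError(f"illegal residue {ch!r} at position {idx + 1}")
    if not s:
        raise StructureError("empty sequence")
    return s


@dataclass(frozen=True)
class PairTable:
    """A pseudoknot-free secondary structure: length + set of 0-based pairs."""

    length: int
    pairs: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "pairs", frozenset(self.pairs))
        self._validate()

    def _validate(self) -> None:
        if self.length < 1:
            raise StructureError("structure length must be >= 1")
        seen = set()
        for i, j in self.pairs:
            if not (0 <= i < j < self.length):
                raise StructureError(f"pair ({i}, {j}) out of range or misordered")
            if j - i <= MIN_HAIRPIN:
                raise StructureError(
                    f"pair ({i}, {j}) closes a hairpin loop of fewer than "
                    f"{MIN_HAIRPIN} bases"
                )
            if i in seen or j in seen:
                raise StructureError(f"position in pair ({i}, {j}) is paired twice")
            seen.add(i)
            seen.add(j)
        plist = sorted(self.pairs)
        for a in range(len(plist)):
            i, j = plist[a]
            for b in range(a + 1, len(plist)):
                k, l = plist[b]
                if k > j:
                    break
                if not (i < k and l < j):  # k > i always (sorted, i distinct)
                    raise StructureError(
                        f"pairs ({i}, {j}) and ({k}, {l}) cross (pseudoknot)"
                    )

    @classmethod
    def _trusted(cls, length: int, pairs: frozenset) -> "PairTable":
        """Construct without validation — only for pair sets produced by
        code that guarantees the invariants (e.g. a folding traceback)."""
        obj = object.__new__(cls)
        object.__setattr__(obj, "length", length)
        object.__setattr__(obj, "pairs", pairs)
        return obj

    @cached_property
    def partner(self) -> tuple:
        """partner[i] = j if (i, j) or (j, i) is a pair, else -1."""
        p = [-1] * self.length
        for i, j in self.pairs:
            p[i] = j
            p[j] = i
        return tuple(p)

    def __len__(self) -> int:
        return self.length


def parse_dotbracket(text: str) -> PairTable:
    """Parse a dot-bracket string into a :class:`PairTable`.

    Accepts only ``.``, ``(`` and ``)``.  Raises :class:`StructureError` on
    unbalanced brackets (naming the first offending index, 1-based), illegal
    characters, or a hairpin loop smaller than :data:`MIN_HAIRPIN`.
    """
    s = text.strip()
    if not s:
        raise StructureError("empty structure")
    stack: list[int] = []
    pairs = set()
    for idx, ch in enumerate(s):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            if not stack:
                raise StructureError(f"unbalanced ')' at position {idx + 1}")
            pairs.add((stack.pop(), idx))
        elif ch != ".":
            raise StructureError(f"illegal character {ch!r} at position {idx + 1}")
    if stack:
        raise StructureError(f"unbalanced '(' at position {stack[0] + 1}")
    return PairTable(length=len(s), pairs=frozenset(pairs))


def render_dotbracket(pt: PairTable) -> str:
    """Render a :class:`PairTable` back to its dot-bracket string."""
    chars = ["."] * pt.length
    for i, j in pt.pairs:
        chars[i] = "("
        chars[j] = ")"
    return "".join(chars)


def bp_distance(a: PairTable, b: PairTable) -> int:
    """Base-pair distance: size of the symmetric difference of the pair sets.

    A metric on structures of equal length.  Raises on a length mismatch.
    """
    if a.length != b.length:
        raise StructureError(
            f"length mismatch: {a.length} vs {b.length}"
        )
    return len(a.pairs ^ b.pairs)


def compatible(seq: str, pt: PairTable) -> bool:
    """True iff every paired position holds one of the six canonical pairs."""
    if len(seq) != pt.length:
        raise StructureError(
            f"sequence length {len(seq)} != structure length {pt.length}"
        )
    return all((seq[i], seq[j]) in CANONICAL_PAIRS for i, j in pt.pairs)
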