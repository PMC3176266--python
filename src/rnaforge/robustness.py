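"""Mutational robustness (neutrality) of an RNA sequence.

The neutrality of a sequence of length L is the average, over all 3L
single-point mutants m, of the structural similarity between the wild-type
minimum-free-energy structure S0 and the mutant structure Sm:

    eta = (1 / 3L) * sum_m [ 1 - d_bp(S0, Sm) / L ]

where d_bp is the base-pair distance.  Normalising by L (not by the number
of pairs) keeps the value in [0, 1] for every structure including the open
chain; eta = 1 means every mutant folds to exactly S0.  All 3L mutants are
evaluated exhaustively — with fold caching this stays tractable for the
~100-nt sequences the designer handles — so the value is deterministic for
a fixed backend.
"""

from __future__ import annotations

from typing import NamedTuple

from .backends import FoldBackend
from .structures import RNA_ALPHABET, bp_distance, clean_sequence


class NeutralityValue(NamedTuple):
    value: float  # in [0, 1]
    mutants_evaluated: int  # always 3 * L


def point_mutants(seq: str):
    """All 3L single-point mutants, in (position, residue-order) order."""
    for i, orig in enumerate(seq):
        for base in RNA_ALPHABET:
            if base != orig:
                yield seq[:i] + base + seq[i + 1 :]


def neutrality(seq: str, backend: FoldBackend) -> NeutralityValue:
    """Exhaustive single-point-mutant neutrality of ``seq`` under ``backend``."""
    seq = clean_sequence(seq)
    L = len(seq)
    s0 = backend.fold(seq).structure
    total = 0.0
    count = 0
    for m in point_mutants(seq):
        sm = backend.fold(m).structure
        total += 1.0 - bp_distance(s0, sm) / L
        count += 1
    return NeutralityValue(total / count, count)
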