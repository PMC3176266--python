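"""Dynamic-programming kernel of the toy folding backend.

Energy model: each stack of two adjacent base pairs (i, j), (i+1, j-1)
contributes ``-(bond(i,j) + bond(i+1,j-1)) / 2`` pseudo-kcal/mol, with bond
strengths GC=3, AU=2, GU=1; loops and unpaired bases are free.  Constraints:
minimum hairpin of 3 unpaired bases, no isolated (lonely) pairs — every
helix holds at least two stacked pairs.  The open chain has energy 0.

Recurrences over a sequence s[0..n-1]:

  V[i, j]   best energy with (i, j) the outermost pair of a helix of h >= 2
            pairs; after h pairs the enclosed region is either a hairpin
            (>= 3 unpaired, energy 0) or any structure containing a pair
            (Wp).
  Wp[i, j]  best energy of a structure on [i, j] containing at least one
            pair: skip i, or pair i with some c (V[i, c]) plus the best of
            the remainder.

All stack energies are negative, so the unconstrained optimum is
``min(0, Wp[0, n-1])``.  Values are multiples of 0.5 and therefore exact in
floating point, which makes the equality tests in the traceback safe.
"""

from __future__ import annotations

import numpy as np
from numba import njit

INF = 1e18

#: bond strengths, indexed by base codes A=0, C=1, G=2, U=3
BOND = np.zeros((4, 4), dtype=np.float64)
BOND[0, 3] = BOND[3, 0] = 2.0  # AU
BOND[1, 2] = BOND[2, 1] = 3.0  # CG
BOND[2, 3] = BOND[3, 2] = 1.0  # GU

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}


def encode(seq: str) -> np.ndarray:
    return np.array([_CODE[c] for c in seq], dtype=np.int8)


@njit(cache=True)
def _fill(codes, bond):  # pragma: no cover - exercised via fold()
    n = codes.shape[0]
    V = np.full((n, n), INF)
    Wp = np.full((n, n), INF)
    for span in range(6, n):  # j - i; smallest helix+hairpin needs span 6
        for i in range(n - span):
            j = i + span
            # --- V[i, j]: helix starting with pair (i, j) -----------------
            if bond[codes[i], codes[j]] > 0.0:
                best = INF
                stacks = 0.0
                h = 1
                while True:
                    p, q = i + h, j - h
                    if p >= q or bond[codes[p], codes[q]] == 0.0:
                        break
                    stacks += -(
                        bond[codes[p - 1], codes[q + 1]]
                        + bond[codes[p], codes[q]]
                    ) / 2.0
                    h += 1
                    a, b = i + h, j - h
                    if b - a + 1 >= 3:
                        if stacks < best:
                            best = stacks
                    if a <= b and Wp[a, b] < INF / 2:
                        cand = stacks + Wp[a, b]
                        if cand < best:
                            best = cand
                V[i, j] = best
            # --- Wp[i, j]: at least one pair somewhere in [i, j] ----------
            best = Wp[i + 1, j] if i + 1 <= j else INF
            for c in range(i + 6, j + 1):
                if V[i, c] < INF / 2:
                    rest = 0.0
                    if c + 1 <= j and Wp[c + 1, j] < INF / 2 and Wp[c + 1, j] < 0.0:
                        rest = Wp[c + 1, j]
                    cand = V[i, c] + rest
                    if cand < best:
                        best = cand
            Wp[i, j] = best
    return V, Wp


@njit(cache=True)
def _traceback(codes, bond, V, Wp):  # pragma: no cover - exercised via fold()
    n = codes.shape[0]
    partner = np.full(n, -1, dtype=np.int64)
    if n < 7 or Wp[0, n - 1] >= 0.0:
        return partner, 0.0
    energy = Wp[0, n - 1]
    # explicit work stack of (kind, i, j): kind 0 -> Wp, 1 -> V
    stack_kind = np.empty(2 * n, dtype=np.int64)
    stack_i = np.empty(2 * n, dtype=np.int64)
    stack_j = np.empty(2 * n, dtype=np.int64)
    top = 0
    stack_kind[top], stack_i[top], stack_j[top] = 0, 0, n - 1
    top += 1
    while top > 0:
        top -= 1
        kind, i, j = stack_kind[top], stack_i[top], stack_j[top]
        if kind == 0:
            target = Wp[i, j]
            # prefer pairing i (checked in ascending partner order)
            matched = False
            for c in range(i + 6, j + 1):
                if V[i, c] < INF / 2:
                    rest = 0.0
                    rest_used = False
                    if c + 1 <= j and Wp[c + 1, j] < 0.0:
                        rest = Wp[c + 1, j]
                        rest_used = True
                    if V[i, c] + rest == target:
                        stack_kind[top], stack_i[top], stack_j[top] = 1, i, c
                        top += 1
                        if rest_used:
                            stack_kind[top], stack_i[top], stack_j[top] = (
                                0,
                                c + 1,
                                j,
                            )
                            top += 1
                        matched = True
                        break
            if not matched:
                # i left unpaired
                stack_kind[top], stack_i[top], stack_j[top] = 0, i + 1, j
                top += 1
        else:
            target = V[i, j]
            stacks = 0.0
            h = 1
            done = False
            while not done:
                p, q = i + h, j - h
                if p >= q or bond[codes[p], codes[q]] == 0.0:
                    break
                stacks += -(
                    bond[codes[p - 1], codes[q + 1]] + bond[codes[p], codes[q]]
                ) / 2.0
                h += 1
                a, b = i + h, j - h
                if b - a + 1 >= 3 and stacks == target:
                    for k in range(h):
                        partner[i + k] = j - k
                        partner[j - k] = i + k
                    done = True
                    break
                if a <= b and Wp[a, b] < INF / 2 and stacks + Wp[a, b] == target:
                    for k in range(h):
                        partner[i + k] = j - k
                        partner[j - k] = i + k
                    stack_kind[top], stack_i[top], stack_j[top] = 0, a, b
                    top += 1
                    done = True
                    break
    return partner, energy


def fold(seq: str):
    """Fold a sequence; returns ``(partner_array, energy)``."""
    codes = encode(seq)
    if codes.shape[0] < 7:
        return np.full(codes.shape[0], -1, dtype=np.int64), 0.0
    V, Wp = _fill(codes, BOND)
    return _traceback(codes, BOND, V, Wp)
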