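"""Independent oracles for the test suite.

Everything here is deliberately naive — exhaustive enumeration and direct
recursion — and shares no code path with the production implementations it
checks.
"""

from __future__ import annotations

from functools import lru_cache

from rnaforge.shape import ShapiroTree
from rnaforge.structures import PairTable, bp_distance

_BOND = {
    ("A", "U"): 2.0, ("U", "A"): 2.0,
    ("C", "G"): 3.0, ("G", "C"): 3.0,
    ("G", "U"): 1.0, ("U", "G"): 1.0,
}

MIN_HAIRPIN = 3


def enumerate_structures(seq: str):
    """All valid pair sets for ``seq``: canonical pairs only, non-crossing,
    hairpin >= 3, and no lonely pairs (every helix >= 2 stacked pairs)."""

    @lru_cache(maxsize=None)
    def enum(i: int, j: int):
        # all non-crossing pair sets on s[i..j] (lonely pairs filtered later)
        if j - i < MIN_HAIRPIN + 1:
            return [frozenset()]
        out = list(enum(i + 1, j))
        for c in range(i + MIN_HAIRPIN + 1, j + 1):
            if (seq[i], seq[c]) in _BOND:
                for inner in enum(i + 1, c - 1):
                    for rest in enum(c + 1, j):
                        out.append(frozenset({(i, c)}) | inner | rest)
        return out

    def no_lonely(pairs: frozenset) -> bool:
        return all(
            (i + 1, j - 1) in pairs or (i - 1, j + 1) in pairs
            for i, j in pairs
        )

    n = len(seq)
    structures = [p for p in enum(0, n - 1) if no_lonely(p)]
    enum.cache_clear()
    return structures


def toy_energy(seq: str, pairs) -> float:
    """Stacking-sum energy of a structure under the toy bond table."""
    pairset = set(pairs)
    e = 0.0
    for i, j in pairset:
        if (i + 1, j - 1) in pairset:
            e -= (_BOND[(seq[i], seq[j])] + _BOND[(seq[i + 1], seq[j - 1])]) / 2.0
    return e


def brute_fold(seq: str):
    """(minimum energy, list of minimising pair sets) by full enumeration."""
    best = 0.0
    argmin = [frozenset()]
    for pairs in enumerate_structures(seq):
        e = toy_energy(seq, pairs)
        if e < best:
            best, argmin = e, [pairs]
        elif e == best and pairs not in argmin:
            argmin.append(pairs)
    return best, argmin


def brute_neutrality(seq: str) -> float:
    """Exhaustive-enumeration neutrality; requires every fold (wild type and
    all mutants) to have a unique minimum-energy structure."""
    L = len(seq)
    _, s0_list = brute_fold(seq)
    assert len(s0_list) == 1, "ambiguous wild-type fold"
    s0 = PairTable(L, s0_list[0])
    total = 0.0
    count = 0
    for i in range(L):
        for base in "ACGU":
            if base == seq[i]:
                continue
            m = seq[:i] + base + seq[i + 1 :]
            _, sm_list = brute_fold(m)
            assert len(sm_list) == 1, f"ambiguous fold for mutant {m}"
            total += 1.0 - bp_distance(s0, PairTable(L, sm_list[0])) / L
            count += 1
    return total / count


def all_folds_unique(seq: str) -> bool:
    """True iff the wild type and every point mutant have a unique minimum."""
    if len(brute_fold(seq)[1]) != 1:
        return False
    for i in range(len(seq)):
        for base in "ACGU":
            if base == seq[i]:
                continue
            if len(brute_fold(seq[:i] + base + seq[i + 1 :])[1]) != 1:
                return False
    return True


def forest_distance(f1: tuple, f2: tuple, costs) -> float:
    """Memoized recursive edit distance between ordered forests."""
    memo: dict = {}

    def subtree_cost(t: ShapiroTree) -> float:
        return costs.indel(t) + sum(subtree_cost(c) for c in t.children)

    def fd(a: tuple, b: tuple) -> float:
        if not a and not b:
            return 0.0
        key = (a, b)
        if key in memo:
            return memo[key]
        if not a:
            r = sum(subtree_cost(t) for t in b)
        elif not b:
            r = sum(subtree_cost(t) for t in a)
        else:
            t1, t2 = a[-1], b[-1]
            r = min(
                fd(a[:-1] + t1.children, b) + costs.indel(t1),
                fd(a, b[:-1] + t2.children) + costs.indel(t2),
                fd(a[:-1], b[:-1])
                + fd(t1.children, t2.children)
                + costs.relabel(t1, t2),
            )
        memo[key] = r
        return r

    return fd(tuple(f1), tuple(f2))


def tree_distance_oracle(a: ShapiroTree, b: ShapiroTree, costs) -> float:
    return forest_distance((a,), (b,), costs)


def random_tree(rng, max_nodes: int = 6) -> ShapiroTree:
    """A random ordered labelled weighted tree rooted at R."""
    n_nodes = int(rng.integers(1, max_nodes))  # non-root nodes

    def build(budget: int) -> tuple[ShapiroTree, int]:
        label = "ESHBIM"[rng.integers(6)]
        weight = int(rng.integers(0, 6))
        budget -= 1
        children = []
        while budget > 0 and rng.random() < 0.5:
            child, budget = build(budget)
            children.append(child)
        return ShapiroTree(label, weight, tuple(children)), budget

    children = []
    budget = n_nodes
    while budget > 0:
        child, budget = build(budget)
        children.append(child)
    return ShapiroTree("R", 0, tuple(children))
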