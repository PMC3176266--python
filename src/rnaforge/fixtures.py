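"""Seeded generation of valid random target structures.

Targets come in three topology classes — a plain hairpin, a two-helix stem
interrupted by a bulge or interior loop, and a three-way multiloop — which
between them exercise every Shapiro node type.  All emitted structures are
valid by construction: balanced, minimum hairpin of 3, no lonely pairs.
"""

from __future__ import annotations

import numpy as np

from .structures import PairTable, parse_dotbracket

TOPOLOGIES = ("hairpin", "bulged", "multiloop")

# minimum length budget per topology (helices of 2, loops of 3, 1-base gaps)
_MIN_LEN = {"hairpin": 7, "bulged": 12, "multiloop": 18}


def _split(total: int, parts: int, rng: np.random.Generator) -> list[int]:
    """Random composition of ``total`` into ``parts`` non-negative integers."""
    if parts == 1:
        return [total]
    cuts = sorted(int(c) for c in rng.integers(0, total + 1, size=parts - 1))
    out = []
    prev = 0
    for c in cuts + [total]:
        out.append(c - prev)
        prev = c
    return out


def _hairpin(h: int, loop: int) -> str:
    return "(" * h + "." * loop + ")" * h


def gen_structure(
    length: int,
    topology: str = "hairpin",
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> PairTable:
    """Generate a random valid structure of the requested topology class.

    Deterministic for a fixed seed/generator.  Raises ``ValueError`` when
    the length cannot accommodate the topology (e.g. a multiloop needs at
    least 18 nt).
    """
    if topology not in TOPOLOGIES:
        raise ValueError(f"unknown topology {topology!r}; choose from {TOPOLOGIES}")
    if length < _MIN_LEN[topology]:
        raise ValueError(
            f"length {length} too short for a {topology} (need >= "
            f"{_MIN_LEN[topology]})"
        )
    if rng is None:
        rng = np.random.default_rng(seed)

    if topology == "hairpin":
        budget = length - 7  # helix 2 + loop 3 + slack
        extra_h, extra_loop, ext = _split(budget, 3, rng)
        h, loop = 2 + extra_h // 2, 3 + extra_loop + extra_h % 2
        e5, e3 = _split(ext, 2, rng)
        db = "." * e5 + _hairpin(h, loop) + "." * e3
    elif topology == "bulged":
        # outer helix h1, gap (bulge or interior), inner helix h2, loop
        budget = length - 12
        extras = _split(budget, 5, rng)
        h1 = 2 + extras[0] // 2
        h2 = 2 + extras[1] // 2
        loop = 3 + extras[2] + extras[0] % 2 + extras[1] % 2
        gap = 1 + extras[3]
        ext = extras[4]
        interior = gap >= 2 and rng.integers(2) == 0
        if interior:
            g5 = 1 + int(rng.integers(gap - 1))
            g3 = gap - g5
        elif rng.integers(2) == 0:
            g5, g3 = gap, 0
        else:
            g5, g3 = 0, gap
        e5, e3 = _split(ext, 2, rng)
        db = (
            "." * e5
            + "(" * h1
            + "." * g5
            + _hairpin(h2, loop)
            + "." * g3
            + ")" * h1
            + "." * e3
        )
    else:  # multiloop
        budget = length - 18
        extras = _split(budget, 7, rng)
        h0 = 2 + extras[0] // 2
        h1 = 2 + extras[1] // 2
        h2 = 2 + extras[2] // 2
        loop1 = 3 + extras[3] + extras[1] % 2
        loop2 = 3 + extras[4] + extras[2] % 2
        spacers = _split(extras[5] + extras[6] + extras[0] % 2, 3, rng)
        e5, e3 = 0, 0
        db = (
            "." * e5
            + "(" * h0
            + "." * spacers[0]
            + _hairpin(h1, loop1)
            + "." * spacers[1]
            + _hairpin(h2, loop2)
            + "." * spacers[2]
            + ")" * h0
            + "." * e3
        )
    assert len(db) == length, (len(db), length, topology)
    return parse_dotbracket(db)
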