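"""Pluggable minimum-free-energy folding backends.

Every other component queries thermodynamics exclusively through this
interface, so the design algorithm is agnostic to the engine:

* ``"vienna"`` — ViennaRNA's ``RNAfold`` through its Python bindings; the
  production engine with the full Turner nearest-neighbour model.
* ``"toy"`` — a Nussinov-style stacking DP (see :mod:`rnaforge._toyfold`)
  with a fixed small bond table, minimum hairpin 3 and no lonely pairs.
  It is hermetic and fast, which keeps the test suite independent of any
  external install, and it is exhaustively verifiable at small lengths.

Folds are memoized per backend instance: neutrality evaluation refolds
thousands of near-duplicate sequences, so the cache is load-bearing.
"""

from __future__ import annotations

from typing import NamedTuple

from .structures import PairTable, clean_sequence, parse_dotbracket


class FoldResult(NamedTuple):
    structure: PairTable
    dG: float  # kcal/mol; 0 for the open chain


class BackendError(RuntimeError):
    """A folding backend is unavailable or misconfigured."""


_ACGU = frozenset("ACGU")


def _ACGU_ONLY(seq: str) -> bool:
    return not (set(seq) - _ACGU)


class FoldBackend:
    """Base class: caching fold wrapper around a concrete engine."""

    def __init__(self):
        self._cache: dict[str, FoldResult] = {}

    def fold(self, seq: str) -> FoldResult:
        res = self._cache.get(seq)
        if res is None:
            if not _ACGU_ONLY(seq):
                seq_clean = clean_sequence(seq)
                res = self.fold(seq_clean)
            else:
                res = self._fold(seq)
            self._cache[seq] = res
        return res

    def _fold(self, seq: str) -> FoldResult:  # pragma: no cover - abstract
        raise NotImplementedError

    def backend_info(self) -> str:  # pragma: no cover - abstract
        raise NotImplementedError


class ToyBackend(FoldBackend):
    """Stacking-energy Nussinov DP in pseudo-kcal/mol."""

    def _fold(self, seq: str) -> FoldResult:
        from . import _toyfold

        partner, energy = _toyfold.fold(seq)
        pairs = frozenset(
            (i, int(j)) for i, j in enumerate(partner) if j > i
        )
        # the traceback guarantees all PairTable invariants
        return FoldResult(PairTable._trusted(len(seq), pairs), float(energy))

    def backend_info(self) -> str:
        return "toy-nussinov/1.0, min-hairpin=3, no-lonely-pairs"


class ViennaBackend(FoldBackend):
    """RNAfold at default temperature and dangle settings."""

    def __init__(self):
        super().__init__()
        try:
            import RNA
        except ImportError as exc:  # pragma: no cover
            raise BackendError(
                "ViennaRNA Python bindings not found; install the "
                "viennarna package or select --backend toy"
            ) from exc
        self._RNA = RNA

    def _fold(self, seq: str) -> FoldResult:
        structure, dG = self._RNA.fold(seq)
        return FoldResult(parse_dotbracket(structure), float(dG))

    def backend_info(self) -> str:
        return f"viennarna/{self._RNA.__version__}, default parameters"


_BACKENDS = {"toy": ToyBackend, "vienna": ViennaBackend}


def get_backend(name: str) -> FoldBackend:
    """Instantiate a backend by name (``"toy"`` or ``"vienna"``)."""
    try:
        cls = _BACKENDS[name]
    except KeyError:
        raise BackendError(
            f"unknown backend {name!r}; choose from {sorted(_BACKENDS)}"
        ) from None
    return cls()
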