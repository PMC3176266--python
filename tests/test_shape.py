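import numpy as np
import pytest
from hypothesis import given, strategies as st

from rnaforge.fixtures import TOPOLOGIES, gen_structure
from rnaforge.shape import (
    ShapiroError,
    ShapiroTree,
    parse_shapiro,
    shapiro_to_string,
    to_shapiro,
)
from rnaforge.structures import parse_dotbracket


def shape_str(db: str, weighted: bool = True) -> str:
    return shapiro_to_string(
        to_shapiro(parse_dotbracket(db), weighted=weighted), weights=weighted
    )


class TestToShapiro:
    @pytest.mark.parametrize(
        "db,expected",
        [
            ("(((...)))", "((H3)S3)R"),
            ("((.((...))))", "((((H3)S2)B1)S2)R"),
            ("...", "(E3)R"),
            ("((((....))))", "((H4)S4)R"),
            # interior loop: unpaired on both strands
            ("((..((...))..))", "((((H3)S2)I4)S2)R"),
            # multiloop with three unpaired bases
            ("((.((...)).((...)).))", "((((H3)S2)((H3)S2)M3)S2)R"),
            # multiloop with no unpaired bases at all
            ("((((...))((...))))", "((((H3)S2)((H3)S2)M0)S2)R"),
            # external runs stay separate per-run
            ("..(((...)))..", "(E2)((H3)S3)(E2)R"),
            ("(((...)))(((...)))", "((H3)S3)((H3)S3)R"),
        ],
    )
    def test_decomposition(self, db, expected):
        assert shape_str(db) == expected

    def test_unweighted_drops_sizes(self):
        assert shape_str("(((...)))", weighted=False) == "((H)S)R"

    def test_same_topology_same_unweighted_shape(self):
        # differs in helix lengths and loop sizes only
        assert shape_str("((.((...))))", weighted=False) == shape_str(
            "(((..(((....))))))", weighted=False
        )
        assert shape_str("(((...)))", weighted=False) == shape_str(
            "((((((.......))))))", weighted=False
        )

    @given(st.integers(0, 2_000))
    def test_weights_account_for_every_position(self, seed):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(20, 70))
        topo = TOPOLOGIES[seed % 3]
        pt = gen_structure(L, topo, rng=rng)
        total = 0
        for node in to_shapiro(pt).nodes():
            total += 2 * node.weight if node.label == "S" else node.weight
        assert total == L


class TestLinearForm:
    def test_parse_inverts_rendering(self):
        for db in ["(((...)))", "((.((...))))", "...", "..((((...))))"]:
            t = to_shapiro(parse_dotbracket(db))
            assert parse_shapiro(shapiro_to_string(t)) == t

    def test_unweighted_parse_defaults_weights_to_one(self):
        t = parse_shapiro("((H)S)R")
        assert t == ShapiroTree("R", 0, (ShapiroTree("S", 1, (ShapiroTree("H", 1),)),))

    def test_bare_root(self):
        assert shapiro_to_string(ShapiroTree("R", 0)) == "R"
        assert parse_shapiro("R") == ShapiroTree("R", 0)

    @pytest.mark.parametrize("text", ["((H3S3)R", "((H3)S3)", "((H3)S3)RX", "((Q3)S3)R"])
    def test_malformed_strings_rejected(self, text):
        with pytest.raises(ShapiroError):
            parse_shapiro(text)


class TestViennaDialect:
    """Cross-check against ViennaRNA's b2shapiro where the dialects coincide.

    Vienna wraps its string in one extra pair of parentheses and pools all
    external unpaired bases into a single trailing E node, so the
    comparison samples structures without external bases.
    """

    def test_matches_vienna_on_internal_structures(self):
        RNA = pytest.importorskip("RNA")
        rng = np.random.default_rng(42)
        checked = 0
        for k in range(40):
            topo = TOPOLOGIES[k % 3]
            pt = gen_structure(int(rng.integers(20, 60)), topo, rng=rng)
            from rnaforge.structures import render_dotbracket

            db = render_dotbracket(pt)
            if "." in (db[0], db[-1]):
                continue  # external bases: dialects intentionally differ
            ours = shapiro_to_string(to_shapiro(pt))
            vienna = RNA.b2Shapiro(db).strip()
            assert vienna == f"({ours})"
            checked += 1
        assert checked >= 10
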