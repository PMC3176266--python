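import numpy as np
import pytest
from hypothesis import given, strategies as st

from rnaforge.fixtures import TOPOLOGIES, gen_structure
from rnaforge.structures import (
    PairTable,
    StructureError,
    bp_distance,
    clean_sequence,
    compatible,
    parse_dotbracket,
    render_dotbracket,
)


class TestParse:
    @pytest.mark.parametrize(
        "text,pairs,length",
        [
            ("((...))", {(0, 6), (1, 5)}, 7),
            (".......", set(), 7),
            ("(...)", {(0, 4)}, 5),
            ("..((...))..", {(2, 8), (3, 7)}, 11),
        ],
    )
    def test_examples(self, text, pairs, length):
        pt = parse_dotbracket(text)
        assert pt.pairs == frozenset(pairs)
        assert pt.length == length

    @pytest.mark.parametrize(
        "text", ["(()", "())", "(((...)", "", "((x..))", "(..)", "(.)"]
    )
    def test_rejects_malformed(self, text):
        # unbalanced brackets, illegal characters, undersized hairpins
        with pytest.raises(StructureError):
            parse_dotbracket(text)

    def test_error_names_offending_index(self):
        with pytest.raises(StructureError, match="position 1"):
            parse_dotbracket("(((..))")

    @given(st.integers(0, 10_000))
    def test_round_trip_on_generated_structures(self, seed):
        rng = np.random.default_rng(seed)
        topo = TOPOLOGIES[seed % 3]
        pt = gen_structure(int(rng.integers(20, 60)), topo, rng=rng)
        assert parse_dotbracket(render_dotbracket(pt)) == pt

    def test_crossing_pairs_rejected_by_pairtable(self):
        with pytest.raises(StructureError, match="cross"):
            PairTable(12, {(0, 6), (2, 10)})


class TestBpDistance:
    def test_identity_and_hand_counted_examples(self):
        a = parse_dotbracket("((...))")
        assert bp_distance(a, a) == 0
        assert bp_distance(a, parse_dotbracket("(.....)")) == 1
        assert bp_distance(a, parse_dotbracket(".......")) == 2

    def test_length_mismatch_raises(self):
        with pytest.raises(StructureError):
            bp_distance(parse_dotbracket("....."), parse_dotbracket("...."))

    @given(st.integers(0, 500))
    def test_metric_properties_on_random_triples(self, seed):
        rng = np.random.default_rng(seed)
        L = 40
        a, b, c = (
            gen_structure(L, TOPOLOGIES[int(rng.integers(3))], rng=rng)
            for _ in range(3)
        )
        dab, dba = bp_distance(a, b), bp_distance(b, a)
        assert dab == dba >= 0
        assert (dab == 0) == (a.pairs == b.pairs)
        assert bp_distance(a, c) <= dab + bp_distance(b, c)


class TestSequences:
    def test_compatible_gc_and_wobble(self):
        pt = parse_dotbracket("(((...)))")
        assert compatible("GGGAAACCC", pt)
        assert not compatible("AAAAAAAAA", pt)
        assert compatible("GAGAAAUUC", pt)  # GC, AU, GU

    def test_compatible_length_mismatch(self):
        with pytest.raises(StructureError):
            compatible("AAAA", parse_dotbracket("....."))

    def test_t_converted_to_u_with_warning(self):
        with pytest.warns(UserWarning, match="T"):
            assert clean_sequence("acgt") == "ACGU"

    def test_illegal_residue_rejected(self):
        with pytest.raises(StructureError, match="X"):
            clean_sequence("ACGX")
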