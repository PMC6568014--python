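"""Alphabets, state sets, matrix parsing and recoding policies."""

import pytest

from inappfitch import (Alphabet, column_from_tokens, expand_missing,
                        parse_matrix, recode_neomorphic, write_nexus,
                        write_tnt)
from inappfitch.errors import DimensionError, MatrixParseError
from inappfitch.statesets import matrix_from_rows

TAIL_TAXA = [f"t{i}" for i in range(8)]

TAIL_NEXUS = """#NEXUS
BEGIN DATA;
DIMENSIONS NTAX=8 NCHAR=5;
FORMAT SYMBOLS="012" MISSING=? GAP=-;
MATRIX
t0 0--0{01}
t1 0--00
t2 0--00
t3 10111
t4 10000
t5 11111
t6 12000
t7 1???0
;
END;
"""

TAIL_TNT = """xread
'tail hierarchy'
5 8
t0 0--0[01]
t1 0--00
t2 0--00
t3 10111
t4 10000
t5 11111
t6 12000
t7 1???0
;
proc /;
"""


def masks(column):
    return [column.states[t].mask for t in sorted(column.states)]


@pytest.mark.parametrize("text,dialect", [(TAIL_NEXUS, "nexus"),
                                          (TAIL_TNT, "tnt")])
def test_parse_tail_hierarchy(text, dialect):
    mat = parse_matrix(text, dialect)
    assert mat.taxa == tuple(TAIL_TAXA)
    assert mat.n_characters == 5
    # tail colour column: - - - 0 0 1 2 ? over symbols 0,1,2
    colour = mat.columns[1]
    assert colour.alphabet.applicable_symbols == ("0", "1", "2")
    inapp = colour.alphabet.inapplicable_bit
    got = [colour.states[t].mask for t in TAIL_TAXA]
    assert got == [inapp, inapp, inapp, 1, 1, 2, 4, 0]
    assert colour.states["t7"].is_missing
    assert colour.n_inapplicable == 3
    # polymorphism token in the last column of t0
    poly = mat.columns[4].states["t0"]
    assert set(poly.alphabet.symbols(poly.mask)) == {"0", "1"}


def test_parse_minimal_and_polymorphism():
    mat = matrix_from_rows(["A", "B"], ["0", "1"])
    col = mat.columns[0]
    assert col.states["A"].mask == 1 and col.states["B"].mask == 2
    col2 = column_from_tokens(["A", "B"], ["01", "1"])
    assert col2.states["A"].mask == 0b11


def test_row_length_mismatch():
    bad = TAIL_TNT.replace("t1 0--0", "t1 0--")
    with pytest.raises(DimensionError):
        parse_matrix(bad, "tnt")


def test_undeclared_symbol_rejected():
    alpha = Alphabet(("0", "1"))
    with pytest.raises(MatrixParseError):
        column_from_tokens(["A", "B"], ["0", "2"], alpha)


def test_alphabet_invariants():
    with pytest.raises(MatrixParseError):
        Alphabet(())
    with pytest.raises(MatrixParseError):
        Alphabet(("0", "-"))
    with pytest.raises(MatrixParseError):
        Alphabet(("0",), inapplicable_symbol="?", missing_symbol="?")


@pytest.mark.parametrize("policy,expected_extra", [
    ("all_states", True), ("applicable_only", False)])
def test_expand_missing_policies(policy, expected_extra):
    col = column_from_tokens(list("AB"), ["?", "0"],
                             Alphabet(("0", "1")))
    out = expand_missing(col, policy)
    s = out.states["A"]
    assert not s.is_missing
    assert s.mask & out.alphabet.full_applicable == 0b11
    assert s.has_inapplicable is expected_extra
    # idempotent and identity on clean columns
    assert expand_missing(out, policy) is out
    clean = column_from_tokens(list("AB"), ["0", "1"])
    assert expand_missing(clean, policy) is clean


def test_recode_neomorphic_tail_eyespot():
    taxa = TAIL_TAXA
    col = column_from_tokens(taxa, ["-", "-", "-", "1", "0", "1", "0", "?"])
    out = recode_neomorphic(col, "0")
    assert [out.states[t].token() for t in taxa] == \
        ["0", "0", "0", "1", "0", "1", "0", "?"]
    assert out.n_inapplicable == 0
    # identity without inapplicables; forced constant when all inapplicable
    assert recode_neomorphic(out, "0").states == out.states
    allgap = column_from_tokens(list("ABC"), ["-", "-", "-"],
                                Alphabet(("0", "1")))
    forced = recode_neomorphic(allgap, "0")
    assert all(s.mask == 1 for s in forced.states.values())
    with pytest.raises(MatrixParseError):
        recode_neomorphic(col, "9")


@pytest.mark.parametrize("writer,dialect", [(write_nexus, "nexus"),
                                            (write_tnt, "tnt")])
def test_round_trip(writer, dialect):
    mat = parse_matrix(TAIL_NEXUS, "nexus")
    back = parse_matrix(writer(mat), dialect)
    assert back.taxa == mat.taxa
    for a, b in zip(mat.columns, back.columns):
        assert a.alphabet == b.alphabet
        assert {t: s.mask for t, s in a.states.items()} == \
            {t: s.mask for t, s in b.states.items()}
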