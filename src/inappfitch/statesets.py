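"""Character alphabets, state sets and matrices for discrete morphology.

A character's states are held as bit masks: one bit per applicable symbol
plus a distinguished bit for the inapplicable ("gap", ``-``) state.  The
inapplicable token means a character *logically cannot* be observed in a
taxon (tail colour in a tailless animal) and is kept distinct from missing
data (``?``), which merely means "not observed".  Missing cells are carried
as an explicit marker until :func:`expand_missing` replaces them with the
polymorphism they stand for.

NEXUS reading is delegated to dendropy; the TNT ``xread`` dialect is parsed
here directly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

from .errors import DimensionError, MatrixParseError

__all__ = [
    "Alphabet",
    "StateSet",
    "CharacterColumn",
    "Matrix",
    "column_from_tokens",
    "parse_matrix",
    "expand_missing",
    "recode_neomorphic",
    "write_nexus",
    "write_tnt",
]


@dataclass(frozen=True)
class Alphabet:
    """Symbol table of one character.

    ``applicable_symbols`` are the observable states; ``inapplicable_symbol``
    marks logical inapplicability and ``missing_symbol`` marks unknown cells.
    """

    applicable_symbols: tuple[str, ...]
    inapplicable_symbol: str = "-"
    missing_symbol: str = "?"

    def __post_init__(self) -> None:
        if not self.applicable_symbols:
            raise MatrixParseError("alphabet needs at least one applicable symbol")
        if len(set(self.applicable_symbols)) != len(self.applicable_symbols):
            raise MatrixParseError("duplicate applicable symbols")
        special = {self.inapplicable_symbol, self.missing_symbol}
        if len(special) != 2 or special & set(self.applicable_symbols):
            raise MatrixParseError(
                "applicable, inapplicable and missing symbols must be distinct"
            )
        if len(self.applicable_symbols) > 32:
            raise MatrixParseError("at most 32 applicable states supported")

    @property
    def n_states(self) -> int:
        return len(self.applicable_symbols)

    @property
    def inapplicable_bit(self) -> int:
        return 1 << self.n_states

    @property
    def full_applicable(self) -> int:
        return (1 << self.n_states) - 1

    @property
    def full(self) -> int:
        return self.full_applicable | self.inapplicable_bit

    def bit(self, symbol: str) -> int:
        """Mask bit of a single token (applicable or inapplicable)."""
        if symbol == self.inapplicable_symbol:
            return self.inapplicable_bit
        try:
            return 1 << self.applicable_symbols.index(symbol)
        except ValueError:
            raise MatrixParseError(f"undeclared symbol {symbol!r}") from None

    def symbols(self, mask: int) -> list[str]:
        """Tokens present in ``mask``, applicable first."""
        out = [s for i, s in enumerate(self.applicable_symbols) if mask >> i & 1]
        if mask & self.inapplicable_bit:
            out.append(self.inapplicable_symbol)
        return out


@dataclass(frozen=True)
class StateSet:
    """Set of states one taxon may hold for one character.

    ``mask == 0`` is the *missing marker*: the cell was ``?`` and has not
    been expanded yet.  After :func:`expand_missing` every mask is nonempty.
    """

    alphabet: Alphabet
    mask: int

    @property
    def is_missing(self) -> bool:
        return self.mask == 0

    @property
    def has_applicable(self) -> bool:
        return bool(self.mask & self.alphabet.full_applicable)

    @property
    def has_inapplicable(self) -> bool:
        return bool(self.mask & self.alphabet.inapplicable_bit)

    @property
    def is_inapplicable_singleton(self) -> bool:
        return self.mask == self.alphabet.inapplicable_bit

    def token(self) -> str:
        """Render as a matrix token (``?``, single symbol, or ``{..}``)."""
        if self.is_missing:
            return self.alphabet.missing_symbol
        syms = self.alphabet.symbols(self.mask)
        if self.mask == self.alphabet.full:
            return self.alphabet.missing_symbol  # fully ambiguous == unknown
        return syms[0] if len(syms) == 1 else "{" + "".join(syms) + "}"


@dataclass(frozen=True)
class CharacterColumn:
    """One character: a taxon -> :class:`StateSet` mapping plus its alphabet."""

    states: Mapping[str, StateSet]
    alphabet: Alphabet
    label: str | None = None

    @property
    def n_inapplicable(self) -> int:
        """Taxa whose set is exactly the inapplicable singleton."""
        return sum(1 for s in self.states.values() if s.is_inapplicable_singleton)

    @property
    def has_missing(self) -> bool:
        return any(s.is_missing for s in self.states.values())

    def mask(self, taxon: str) -> int:
        return self.states[taxon].mask


@dataclass(frozen=True)
class Matrix:
    """Taxa x characters collection; all columns share the taxon list."""

    taxa: tuple[str, ...]
    columns: tuple[CharacterColumn, ...]

    def __post_init__(self) -> None:
        if len(set(self.taxa)) != len(self.taxa):
            raise DimensionError("duplicate taxon labels")
        for j, col in enumerate(self.columns):
            if set(col.states) != set(self.taxa):
                raise DimensionError(f"column {j} does not cover the taxon list")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_characters(self) -> int:
        return len(self.columns)

    def row_tokens(self, taxon: str) -> list[str]:
        return [col.states[taxon].token() for col in self.columns]


# ---------------------------------------------------------------------------
# construction from tokens

_TOKEN_RE = re.compile(r"\(([^)]*)\)|\{([^}]*)\}|\[([^\]]*)\]|(\S)")


def _split_tokens(row: str) -> list[str]:
    """Split a matrix row into cell tokens; grouped cells keep their members."""
    out = []
    for m in _TOKEN_RE.finditer(row):
        grp = m.group(1) or m.group(2) or m.group(3)
        out.append(grp.replace(" ", "") if grp is not None else m.group(4))
    return out


def column_from_tokens(
    taxa: Sequence[str],
    tokens: Sequence[str],
    alphabet: Alphabet | None = None,
    label: str | None = None,
) -> CharacterColumn:
    """Build one character from per-taxon tokens (``"0"``, ``"-"``, ``"?"``,
    ``"01"`` for a polymorphism).

    When no alphabet is given it is inferred from the observed symbols of
    this column, so that missing expansion later uses "all possible states"
    of the character itself.
    """
    if len(taxa) != len(tokens):
        raise DimensionError("one token per taxon required")
    inapp, miss = "-", "?"
    if alphabet is not None:
        inapp, miss = alphabet.inapplicable_symbol, alphabet.missing_symbol
    if alphabet is None:
        observed = sorted(
            {c for tok in tokens for c in tok if c not in (inapp, miss)}
        )
        alphabet = Alphabet(tuple(observed) if observed else ("0",), inapp, miss)
    states = {}
    for taxon, tok in zip(taxa, tokens):
        if tok == miss:
            states[taxon] = StateSet(alphabet, 0)
            continue
        mask = 0
        for c in tok:
            if c == miss:
                raise MatrixParseError(
                    f"{miss!r} inside a polymorphism (taxon {taxon!r})"
                )
            mask |= alphabet.bit(c)
        states[taxon] = StateSet(alphabet, mask)
    return CharacterColumn(states, alphabet, label)


def matrix_from_rows(taxa: Sequence[str], rows: Sequence[str]) -> Matrix:
    """Build a matrix from one token string per taxon (test/CLI helper)."""
    token_rows = [_split_tokens(r) for r in rows]
    nchar = {len(r) for r in token_rows}
    if len(nchar) != 1:
        raise DimensionError("rows of unequal length")
    cols = []
    for j in range(nchar.pop()):
        cols.append(column_from_tokens(taxa, [r[j] for r in token_rows]))
    return Matrix(tuple(taxa), tuple(cols))


# ---------------------------------------------------------------------------
# parsing

def parse_matrix(text: str, dialect: str = "nexus") -> Matrix:
    """Parse NEXUS or TNT character-matrix text into a :class:`Matrix`.

    Per-character alphabets are taken from the symbols observed in each
    column; ``(..)``, ``{..}`` and ``[..]`` groups all become multi-state
    sets; ``?`` becomes the missing marker pending expansion.
    """
    if dialect == "nexus":
        taxa, rows, inapp, miss = _read_nexus(text)
    elif dialect == "tnt":
        taxa, rows, inapp, miss = _read_tnt(text)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if len({len(r) for r in rows}) > 1:
        raise DimensionError("rows of unequal length")
    cols = []
    for j in range(len(rows[0])):
        tokens = [r[j] for r in rows]
        observed = sorted({c for tok in tokens for c in tok if c not in (inapp, miss)})
        alpha = Alphabet(tuple(observed) if observed else ("0",), inapp, miss)
        cols.append(column_from_tokens(taxa, tokens, alpha))
    return Matrix(tuple(taxa), tuple(cols))


def _read_nexus(text: str):
    import dendropy

    try:
        dmat = dendropy.StandardCharacterMatrix.get(data=text, schema="nexus")
    except Exception as exc:  # dendropy raises several error classes
        raise MatrixParseError(f"NEXUS parse failed: {exc}") from exc
    taxa, rows = [], []
    declared = None
    for taxon in dmat:
        seq = dmat[taxon]
        toks = []
        for cell in seq:
            fund = sorted(s.symbol for s in cell.fundamental_states)
            if declared is None and cell.symbol == "?":
                declared = set(fund)
            toks.append(cell)
        taxa.append(taxon.label)
        rows.append(toks)
    # convert dendropy cells to plain tokens: missing iff the cell covers the
    # whole declared alphabet (gap included), which is how NEXUS defines "?"
    out_rows = []
    for toks in rows:
        row = []
        for cell in toks:
            fund = sorted(s.symbol for s in cell.fundamental_states)
            if cell.symbol == "?" or (declared is not None and set(fund) >= declared):
                row.append("?")
            elif cell.symbol is not None:
                row.append(cell.symbol)
            else:
                row.append("".join(fund))
        out_rows.append(row)
    return taxa, out_rows, "-", "?"


def _read_tnt(text: str):
    """Parse a TNT ``xread`` block (the common discrete-morphology subset)."""
    m = re.search(r"xread\b(.*?);", text, flags=re.S | re.I)
    if not m:
        raise MatrixParseError("no xread block found")
    body = m.group(1)
    body = re.sub(r"'[^']*'", " ", body)  # strip quoted title
    parts = body.split()
    if len(parts) < 2:
        raise MatrixParseError("xread needs nchar and ntax")
    try:
        nchar, ntax = int(parts[0]), int(parts[1])
    except ValueError as exc:
        raise MatrixParseError("xread nchar/ntax not integers") from exc
    fields = parts[2:]
    if len(fields) % 2:
        raise MatrixParseError("unpaired taxon/row fields in xread")
    taxa, rows = [], []
    for i in range(0, len(fields), 2):
        taxa.append(fields[i])
        toks = _split_tokens(fields[i + 1])
        if len(toks) != nchar:
            raise DimensionError(
                f"taxon {fields[i]!r}: {len(toks)} cells, expected {nchar}"
            )
        rows.append(toks)
    if len(taxa) != ntax:
        raise DimensionError(f"{len(taxa)} taxa read, {ntax} declared")
    return taxa, rows, "-", "?"


# ---------------------------------------------------------------------------
# policies

def expand_missing(column: CharacterColumn, policy: str = "all_states") -> CharacterColumn:
    """Replace missing markers by the polymorphism they stand for.

    ``all_states``: unknown means any state, applicable or inapplicable.
    ``applicable_only``: unknown, but from the applicable states.
    Idempotent; a column without missing markers is returned unchanged.
    """
    if policy not in ("all_states", "applicable_only"):
        raise ValueError(f"unknown policy {policy!r}")
    if not column.has_missing:
        return column
    alpha = column.alphabet
    full = alpha.full if policy == "all_states" else alpha.full_applicable
    states = {
        t: (StateSet(alpha, full) if s.is_missing else s)
        for t, s in column.states.items()
    }
    return CharacterColumn(states, alpha, column.label)


def recode_neomorphic(column: CharacterColumn, nonderived_symbol: str) -> CharacterColumn:
    """Additive-binary recoding of a neomorphic dependent character.

    Every inapplicable singleton becomes the presumed nonderived state
    (typically "absent"), so absence of the principal structure and absence
    of the subordinate structure are scored alike.
    """
    alpha = column.alphabet
    if nonderived_symbol not in alpha.applicable_symbols:
        raise MatrixParseError(
            f"nonderived symbol {nonderived_symbol!r} not in alphabet"
        )
    bit = alpha.bit(nonderived_symbol)
    states = {
        t: (StateSet(alpha, bit) if s.is_inapplicable_singleton else s)
        for t, s in column.states.items()
    }
    return CharacterColumn(states, alpha, column.label)


# ---------------------------------------------------------------------------
# serialization

def _all_symbols(matrix: Matrix) -> list[str]:
    syms: list[str] = []
    for col in matrix.columns:
        for s in col.alphabet.applicable_symbols:
            if s not in syms:
                syms.append(s)
    return sorted(syms)


def write_nexus(matrix: Matrix) -> str:
    syms = "".join(_all_symbols(matrix))
    width = max(len(t) for t in matrix.taxa) + 2
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_characters};",
        f'FORMAT SYMBOLS="{syms}" MISSING=? GAP=-;',
        "MATRIX",
    ]
    for t in matrix.taxa:
        row = "".join(
            tok if len(tok) == 1 else "{" + tok.strip("{}") + "}"
            for tok in matrix.row_tokens(t)
        )
        lines.append(f"{t:<{width}}{row}")
    lines += [";", "END;", ""]
    return "\n".join(lines)


def write_tnt(matrix: Matrix) -> str:
    width = max(len(t) for t in matrix.taxa) + 2
    lines = ["xread", f"{matrix.n_characters} {matrix.n_taxa}"]
    for t in matrix.taxa:
        row = "".join(
            tok if len(tok) == 1 else "[" + tok.strip("{}") + "]"
            for tok in matrix.row_tokens(t)
        )
        lines.append(f"{t:<{width}}{row}")
    lines += [";", "proc /;", ""]
    return "\n".join(lines)
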