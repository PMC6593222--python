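"""Sample-metadata ingest, Porter-stem full-text index, where-clause search.

Metadata arrive as a QIIME-mapping-style tab-delimited table: header row,
first column the sample identifier, remaining columns variables.  Values
are stored verbatim as strings; typing happens at query time (see
:mod:`biomdex.where`).  Values matching the missing-value vocabulary are
dropped at ingest rather than stored.

Every stored value is additionally tokenised and Porter-stemmed into the
full-text index: stem -> set of samples carrying a value with that stem,
both globally and per variable.  Numeric values contribute no stems (pure
numerals are dropped by the tokenizer), so the stem index is effectively an
index over categorical/free-text values.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from . import porter
from .kvstore import KeyValueBackend, SEPARATOR, StoreKey
from .where import (
    Clause,
    WhereSyntaxError,
    clause_variables,
    evaluate_clause,
    parse_where,
)

_SAMPLES_KEY = StoreKey("metadata", "samples", "all")
_VARIABLES_KEY = StoreKey("metadata", "variables", "all")

#: values treated as "missing" and dropped at ingest (case-insensitive);
#: common QIIME-style metadata practice.
MISSING_MARKERS = frozenset({
    "", "na", "n/a", "nan", "none", "unknown", "not applicable",
})
MISSING_PREFIX = "missing:"


class MetadataError(Exception):
    """Raised for malformed metadata tables or queries."""


@dataclass(frozen=True)
class IngestSummary:
    samples: int
    variables: int
    values_dropped_missing: int


def is_missing(value: str) -> bool:
    v = value.strip().lower()
    return v in MISSING_MARKERS or v.startswith(MISSING_PREFIX)


# ---------------------------------------------------------------------------
# tokenizing / stemming
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(r"[a-z0-9]+")


def stem_text(value: str) -> list[str]:
    """Tokenise and stem a metadata value.

    Lowercase; split on runs of non-alphanumeric characters; drop tokens
    shorter than 2 characters and purely numeric tokens (so "pH 7" yields
    just ``ph``); Porter-stem each survivor; deduplicate preserving first
    occurrence.
    """
    out: list[str] = []
    seen: set[str] = set()
    for token in _TOKEN_RE.findall(value.lower()):
        if len(token) < 2 or token.isdigit():
            continue
        stemmed = porter.stem(token)
        if stemmed not in seen:
            seen.add(stemmed)
            out.append(stemmed)
    return out


def _stem_key(stem: str) -> StoreKey:
    return StoreKey("metadata", "stem", stem)


def _variable_stem_key(variable: str, stem: str) -> StoreKey:
    # tab cannot occur in TSV-sourced variable names, so it is a safe joiner
    return StoreKey("metadata", "stem-variable", f"{variable}\t{stem}")


# ---------------------------------------------------------------------------
# ingest
# ---------------------------------------------------------------------------

def _rows_from_source(source) -> list[list[str]]:
    if isinstance(source, (str, Path)):
        text = Path(source).read_text(encoding="utf-8")
        return list(csv.reader(io.StringIO(text), delimiter="\t"))
    return list(csv.reader(iter(source), delimiter="\t"))


def ingest_metadata(
    store: KeyValueBackend, source: str | Path | Iterable[str]
) -> IngestSummary:
    """Ingest a sample-metadata TSV (path or iterable of lines).

    One record is stored per row; missing-marker values are dropped and
    counted; the stem index is updated for every stored value.  Re-ingesting
    an identical table leaves the store unchanged.
    """
    rows = _rows_from_source(source)
    if not rows:
        raise MetadataError("metadata table is empty (no header row)")
    header = rows[0]
    if len(header) < 1:
        raise MetadataError("metadata header row is empty")
    variables = [v.strip() for v in header[1:]]
    for variable in variables:
        if not variable:
            raise MetadataError("metadata header contains an empty "
                                "variable name")
        if SEPARATOR in variable or "\t" in variable:
            raise MetadataError(
                f"variable name {variable!r} contains a reserved character")
    if len(set(variables)) != len(variables):
        raise MetadataError("duplicate variable names in header")

    seen_samples: set[str] = set()
    dropped = 0
    parsed: list[tuple[str, dict[str, str]]] = []
    for lineno, row in enumerate(rows[1:], start=2):
        if not row or (len(row) == 1 and not row[0].strip()):
            continue
        if len(row) != len(header):
            raise MetadataError(
                f"line {lineno}: expected {len(header)} columns, "
                f"got {len(row)}")
        sample = row[0].strip()
        if not sample:
            raise MetadataError(f"line {lineno}: empty sample identifier")
        if SEPARATOR in sample:
            raise MetadataError(
                f"line {lineno}: sample id {sample!r} contains the reserved "
                f"separator")
        if sample in seen_samples:
            raise MetadataError(
                f"line {lineno}: duplicate sample id {sample!r}")
        seen_samples.add(sample)
        values: dict[str, str] = {}
        for variable, raw in zip(variables, row[1:]):
            if is_missing(raw):
                dropped += 1
            else:
                values[variable] = raw
        parsed.append((sample, values))

    for sample, values in parsed:
        store.set_add(_SAMPLES_KEY, [sample])
        if values:
            store.record_put(StoreKey("metadata", "record", sample), values)
        store.set_add(_VARIABLES_KEY, list(values))
        for variable, value in values.items():
            for stemmed in stem_text(value):
                store.set_add(_stem_key(stemmed), [sample])
                store.set_add(_variable_stem_key(variable, stemmed), [sample])
    return IngestSummary(
        samples=len(parsed),
        variables=len(variables),
        values_dropped_missing=dropped,
    )


def metadata_samples(store: KeyValueBackend) -> set[str]:
    """All samples with an ingested metadata row."""
    return store.set_members(_SAMPLES_KEY)


def metadata_variables(store: KeyValueBackend) -> set[str]:
    """All variables observed with at least one non-missing value."""
    return store.set_members(_VARIABLES_KEY)


def get_record(
    store: KeyValueBackend,
    sample: str,
    variables: Sequence[str] | None = None,
) -> dict[str, str | None]:
    """A sample's stored values; missing/dropped variables map to None."""
    return store.record_get(StoreKey("metadata", "record", sample), variables)


def stem_samples(
    store: KeyValueBackend, stem: str, variable: str | None = None
) -> set[str]:
    """Samples whose metadata contain ``stem`` (optionally in one variable)."""
    if variable is None:
        return store.set_members(_stem_key(stem))
    return store.set_members(_variable_stem_key(variable, stem))


# ---------------------------------------------------------------------------
# full-text stem-set algebra
# ---------------------------------------------------------------------------
# expression := clause (('|' | '-') clause)*        union / left-fold diff
# clause     := factor ('&' factor)*                intersection (tighter)
# factor     := WORD | "quoted phrase" | '(' expression ')'
# Every stem of a multi-stem term (phrase or hyphenated word) is intersected.

_FT_OPERATORS = {"&", "|", "-", "−", "(", ")"}


def _fulltext_tokens(text: str) -> list[tuple[str, str, int]]:
    tokens: list[tuple[str, str, int]] = []
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c.isspace():
            i += 1
            continue
        if c in _FT_OPERATORS:
            tokens.append(("op", "-" if c == "−" else c, i))
            i += 1
            continue
        if c in "'\"":
            j = text.find(c, i + 1)
            if j < 0:
                raise MetadataError(
                    f"unterminated quote (at position {i})")
            tokens.append(("term", text[i + 1:j], i))
            i = j + 1
            continue
        j = i
        while j < n and not text[j].isspace() and text[j] not in _FT_OPERATORS \
                and text[j] not in "'\"":
            j += 1
        tokens.append(("term", text[i:j], i))
        i = j
    return tokens


class _FulltextParser:
    def __init__(self, store, text: str, variable: str | None):
        self.store = store
        self.variable = variable
        self.tokens = _fulltext_tokens(text)
        self.pos = 0
        self.length = len(text)

    def _peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def _next(self):
        tok = self._peek()
        if tok is None:
            raise MetadataError(
                f"unexpected end of expression (at position {self.length})")
        self.pos += 1
        return tok

    def parse(self) -> set[str]:
        result = self._expression()
        trailing = self._peek()
        if trailing is not None:
            raise MetadataError(
                f"unexpected {trailing[1]!r} (at position {trailing[2]})")
        return result

    def _expression(self) -> set[str]:
        result = self._clause()
        while True:
            tok = self._peek()
            if tok and tok[0] == "op" and tok[1] in "|-":
                self._next()
                rhs = self._clause()
                result = result | rhs if tok[1] == "|" else result - rhs
            else:
                return result

    def _clause(self) -> set[str]:
        result = self._factor()
        while True:
            tok = self._peek()
            if tok and tok[0] == "op" and tok[1] == "&":
                self._next()
                result &= self._factor()
            else:
                return result

    def _factor(self) -> set[str]:
        kind, value, pos = self._next()
        if kind == "op" and value == "(":
            inner = self._expression()
            kind, value, pos = self._next()
            if not (kind == "op" and value == ")"):
                raise MetadataError(f"expected ')' (at position {pos})")
            return inner
        if kind == "op":
            raise MetadataError(
                f"expected a search term, got {value!r} (at position {pos})")
        stems = stem_text(value)
        if not stems:
            return set()
        result = stem_samples(self.store, stems[0], self.variable)
        for stemmed in stems[1:]:
            result &= stem_samples(self.store, stemmed, self.variable)
        return result


def search_fulltext(
    store: KeyValueBackend, expression: str, variable: str | None = None
) -> set[str]:
    """Evaluate a stem-set algebra expression against the full-text index.

    Terms are stemmed before lookup, so any inflection of a word finds the
    samples indexed under its stem; stems never seen evaluate to the empty
    set.  With ``variable`` the lookups are restricted to that variable's
    sub-index.
    """
    return _FulltextParser(store, expression, variable).parse()


# ---------------------------------------------------------------------------
# where clauses
# ---------------------------------------------------------------------------

def evaluate_where(
    store: KeyValueBackend,
    clause: str | Clause,
    universe: set[str] | None = None,
) -> set[str]:
    """Samples (within ``universe``) whose metadata satisfy ``clause``.

    ``universe`` defaults to every sample with metadata.  Samples whose
    relevant values are missing, or non-coercible under an ordering
    operator, are excluded rather than raising.
    """
    tree = parse_where(clause)
    variables = sorted(clause_variables(tree))
    if not variables:  # unreachable through the parser; defensive
        raise WhereSyntaxError("clause references no variable", 0)
    candidates = metadata_samples(store) if universe is None else universe
    hits: set[str] = set()
    for sample in candidates:
        values = get_record(store, sample, variables)
        if evaluate_clause(tree, values):
            hits.add(sample)
    return hits
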