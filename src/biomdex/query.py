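"""User-facing search surface.

Composes the three index families — feature inverted indices (within a
context), the taxonomy index, and the metadata layer (stem full-text and
where-clauses) — into sample hit sets, always by plain set algebra on
sample identifiers.  Because contexts share sample identities, a hit set
found in one context can be partitioned against another
(:func:`partition_by_context`), the mechanism behind "identify samples
processed one way and fetch the data processed another way".
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import indexing, metadata as md
from .indexing import IngestError
from .kvstore import KeyValueBackend
from .where import Clause


class QueryError(Exception):
    """Raised for invalid query requests (not for empty results)."""


@dataclass(frozen=True)
class SampleHitSet:
    """A query result: unique sample ids plus how they were selected."""

    samples: frozenset[str]
    context: str | None = None
    provenance: tuple[str, ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.samples)

    def sorted(self) -> list[str]:
        return sorted(self.samples)


def search_features(
    store: KeyValueBackend,
    context: str,
    features: list[str],
    reduce: str = "any",
) -> SampleHitSet:
    """Samples containing the given features in ``context``.

    ``reduce="any"`` unions the per-feature inverted-index sets (a sample
    qualifies if it contains any of the features); ``"all"`` intersects
    them.  Features absent from the context contribute the empty set.
    """
    if not features:
        raise QueryError("search_features requires at least one feature")
    if reduce not in ("any", "all"):
        raise QueryError(f"unknown reduce mode {reduce!r}")
    if not indexing.context_exists(store, context):
        raise IngestError(f"unknown context {context!r}")
    sets = [indexing.feature_samples(store, context, f) for f in features]
    result = set().union(*sets) if reduce == "any" else set.intersection(*sets)
    return SampleHitSet(
        samples=frozenset(result),
        context=context,
        provenance=(f"features[{reduce}]:{len(features)}",),
    )


def search_taxon(store: KeyValueBackend, context: str, label: str) -> set[str]:
    """Feature ids carrying ``label`` (exact match) in the context's taxonomy.

    Composable with :func:`search_features` to reach samples.  Raises if no
    taxonomy has been loaded for the context, which is distinct from a
    label that retrieves nothing.
    """
    if not indexing.context_exists(store, context):
        raise IngestError(f"unknown context {context!r}")
    if not indexing.taxonomy_loaded(store, context):
        raise QueryError(f"no taxonomy loaded for context {context!r}")
    return indexing.taxon_features(store, context, label)


def select_samples(
    store: KeyValueBackend,
    context: str | None = None,
    features: list[str] | None = None,
    reduce: str = "any",
    where: str | Clause | None = None,
    fulltext: str | None = None,
    fulltext_variable: str | None = None,
) -> SampleHitSet:
    """Intersect any combination of constraints into one hit set.

    Supplied constraints (feature search within ``context``, a metadata
    where-clause, a full-text stem expression) each yield a sample set; the
    result is their intersection, further intersected with the context's
    samples-represented set when a context is given.  At least one
    constraint is required.
    """
    constraint_sets: list[set[str]] = []
    provenance: list[str] = []
    if features:
        if context is None:
            raise QueryError("feature constraints require a context")
        hits = search_features(store, context, features, reduce)
        constraint_sets.append(set(hits.samples))
        provenance.extend(hits.provenance)
    if where is not None:
        constraint_sets.append(md.evaluate_where(store, where))
        provenance.append(f"where:{where}" if isinstance(where, str)
                          else "where:<clause>")
    if fulltext is not None:
        constraint_sets.append(
            md.search_fulltext(store, fulltext, fulltext_variable))
        provenance.append(f"fulltext:{fulltext}")
    if not constraint_sets:
        if context is None:
            raise QueryError("select_samples requires at least one "
                             "constraint")
        # context alone: everything represented in it
        constraint_sets.append(indexing.samples_represented(store, context))
        provenance.append("context-membership")
    result = set.intersection(*constraint_sets)
    if context is not None:
        result &= indexing.samples_represented(store, context)
        provenance.append(f"context:{context}")
    return SampleHitSet(samples=frozenset(result), context=context,
                        provenance=tuple(provenance))


def partition_by_context(
    store: KeyValueBackend, samples: set[str], target_context: str
) -> tuple[set[str], set[str]]:
    """Split ``samples`` into (present in target context, absent from it).

    The two sides are disjoint and cover the input exactly, so a hit set
    from one processing protocol can be re-fetched under another.
    """
    if not indexing.context_exists(store, target_context):
        raise IngestError(f"unknown context {target_context!r}")
    represented = indexing.samples_represented(store, target_context)
    present = set(samples) & represented
    return present, set(samples) - present


def summarize_variable(
    store: KeyValueBackend, samples: set[str], variable: str
) -> dict[str, int]:
    """Tally the raw stored values of ``variable`` among ``samples``.

    Returns a value -> count dict in lexicographic value order, with a
    ``None`` key counting samples that lack the variable; the counts sum
    to ``len(samples)``.  An empty sample set yields an empty table.
    """
    counts: dict[str, int] = {}
    missing = 0
    for sample in samples:
        value = md.get_record(store, sample, [variable])[variable]
        if value is None:
            missing += 1
        else:
            counts[value] = counts.get(value, 0) + 1
    out: dict = dict(sorted(counts.items()))
    if samples:
        out[None] = missing
    return out
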