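"""Context lifecycle and feature-table indexing.

A *context* is a named partition holding all sample data produced under one
sequencing + bioinformatics protocol (e.g. a Deblur 90-nt context vs a
closed-reference OTU context).  Data within a context are comparable;
across contexts only sample identities are.  Each context owns:

* per-kind identifier maps assigning dense integers to feature and sample
  ids in first-seen order (string ids, e.g. exact 16S sequence variants,
  are long and highly redundant across samples; the integer remap keeps the
  stored vectors compact);
* one sparse vector per sample: the (feature-integer, count) pairs with
  nonzero counts;
* an inverted index, feature id -> set of samples the feature was observed
  in, which is what makes "which samples contain this exact sequence"
  answerable in a single set lookup;
* optionally a taxonomy index, taxon label -> set of feature ids.

Loads are idempotent per (context, sample): a sample already present in a
context is skipped in full rather than merged, so re-loading a table never
double-counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import biom
import numpy as np

from .kvstore import KeyValueBackend, SEPARATOR, StoreKey

#: namespaces reserved for the global registry and the metadata layer;
#: contexts may not take these names.
RESERVED_NAMESPACES = frozenset({"state", "metadata"})

_CONTEXT_REGISTRY = StoreKey("state", "context", "all")


class IngestError(Exception):
    """Raised when an input table, taxonomy file or context is invalid."""


@dataclass(frozen=True)
class Context:
    """Summary of one processing-protocol partition."""

    name: str
    description: str
    n_samples: int
    n_features: int


@dataclass(frozen=True)
class LoadSummary:
    samples_loaded: int
    samples_skipped: int
    features_new: int


# ---------------------------------------------------------------------------
# context registry
# ---------------------------------------------------------------------------

def create_context(store: KeyValueBackend, name: str, description: str = "") -> Context:
    """Register a new, empty context.

    ``name`` must be nonempty, free of the key separator, not a reserved
    namespace and not already registered.
    """
    if not name:
        raise IngestError("context name may not be empty")
    if SEPARATOR in name:
        raise IngestError(
            f"context name {name!r} contains the reserved separator"
        )
    if name in RESERVED_NAMESPACES:
        raise IngestError(f"context name {name!r} is reserved")
    if name in store.set_members(_CONTEXT_REGISTRY):
        raise IngestError(f"context {name!r} already exists")
    store.set_add(_CONTEXT_REGISTRY, [name])
    store.put_value(StoreKey("state", "context-description", name), description)
    return Context(name, description, 0, 0)


def list_contexts(store: KeyValueBackend) -> list[Context]:
    """All registered contexts, lexicographic by name."""
    return [get_context(store, n)
            for n in sorted(store.set_members(_CONTEXT_REGISTRY))]


def context_exists(store: KeyValueBackend, name: str) -> bool:
    return name in store.set_members(_CONTEXT_REGISTRY)


def get_context(store: KeyValueBackend, name: str) -> Context:
    _require_context(store, name)
    description = store.get_value(
        StoreKey("state", "context-description", name)) or ""
    return Context(
        name=name,
        description=description,
        n_samples=len(samples_represented(store, name)),
        n_features=len(features_represented(store, name)),
    )


def samples_represented(store: KeyValueBackend, context: str) -> set[str]:
    return store.set_members(StoreKey(context, "samples-represented", "all"))


def features_represented(store: KeyValueBackend, context: str) -> set[str]:
    return store.set_members(StoreKey(context, "features-represented", "all"))


def _require_context(store: KeyValueBackend, name: str) -> None:
    if not context_exists(store, name):
        raise IngestError(f"unknown context {name!r}")


# ---------------------------------------------------------------------------
# identifier maps
# ---------------------------------------------------------------------------

def map_identifiers(
    store: KeyValueBackend,
    context: str,
    ids: Sequence[str],
    space: str = "feature",
) -> list[int]:
    """Map string ids to this context's dense integer space.

    Known ids return their existing integer; new ids are assigned the next
    integers in input order.  Integers start at 0, are never reused, and
    the forward/reverse maps stay mutual inverses.  ``space`` is
    ``"feature"`` or ``"sample"``; the two spaces are independent.
    """
    _require_context(store, context)
    if space not in ("feature", "sample"):
        raise IngestError(f"unknown identifier space {space!r}")
    forward_key = StoreKey(context, f"idmap-{space}", "forward")
    reverse_key = StoreKey(context, f"idmap-{space}", "reverse")
    forward = store.record_get(forward_key)
    next_int = len(forward)
    out: list[int] = []
    new_forward: dict[str, str] = {}
    new_reverse: dict[str, str] = {}
    for identifier in ids:
        existing = forward.get(identifier)
        if existing is None:
            existing = str(next_int)
            forward[identifier] = existing
            new_forward[identifier] = existing
            new_reverse[existing] = identifier
            next_int += 1
        out.append(int(existing))
    if new_forward:
        store.record_put(forward_key, new_forward)
        store.record_put(reverse_key, new_reverse)
    return out


def resolve_identifiers(
    store: KeyValueBackend,
    context: str,
    integers: Sequence[int],
    space: str = "feature",
) -> list[str]:
    """Inverse of :func:`map_identifiers`; unknown integers raise."""
    _require_context(store, context)
    reverse = store.record_get(
        StoreKey(context, f"idmap-{space}", "reverse"),
        [str(i) for i in integers],
    )
    out = []
    for i in integers:
        identifier = reverse[str(i)]
        if identifier is None:
            raise IngestError(
                f"integer {i} not assigned in {context!r} {space} space")
        out.append(identifier)
    return out


# ---------------------------------------------------------------------------
# sparse sample vectors
# ---------------------------------------------------------------------------

def _encode_count(count: float) -> int | float:
    return int(count) if float(count).is_integer() else float(count)


def store_vector(
    store: KeyValueBackend,
    context: str,
    sample: str,
    pairs: Iterable[tuple[int, float]],
) -> None:
    payload = json.dumps(
        [[int(f), _encode_count(c)] for f, c in sorted(pairs)],
        separators=(",", ":"),
    )
    store.put_value(StoreKey(context, "data", sample), payload)


def get_vector(
    store: KeyValueBackend, context: str, sample: str
) -> list[tuple[int, float]] | None:
    """The (feature-integer, count) pairs for one sample, or None."""
    raw = store.get_value(StoreKey(context, "data", sample))
    if raw is None:
        return None
    return [(int(f), c) for f, c in json.loads(raw)]


# ---------------------------------------------------------------------------
# table loading
# ---------------------------------------------------------------------------

def read_biom(source: str | Path | biom.Table) -> biom.Table:
    """Read a feature table: BIOM 1.0 JSON, BIOM 2.1 HDF5, or a live Table."""
    if isinstance(source, biom.Table):
        return source
    path = Path(source)
    if not path.exists():
        raise IngestError(f"no such table file: {path}")
    try:
        import h5py
        if h5py.is_hdf5(str(path)):
            return biom.load_table(str(path))
    except ImportError:  # pragma: no cover - h5py ships with biom
        pass
    text = path.read_text(encoding="utf-8", errors="replace")
    if not text.lstrip().startswith("{"):
        raise IngestError(
            f"{path} is neither BIOM 2.1 HDF5 nor BIOM 1.0 JSON")
    try:
        return biom.parse.parse_biom_table(text)
    except Exception as exc:  # biom raises several parse-error types
        raise IngestError(f"could not parse {path} as BIOM JSON: {exc}") \
            from exc


def load_table(
    store: KeyValueBackend,
    context: str,
    table: str | Path | biom.Table,
) -> LoadSummary:
    """Index a feature table into ``context``.

    For every newly loaded sample this stores its sparse vector, adds the
    sample to each observed feature's inverted-index set, records the
    sample's feature-membership set, and updates the context registries.
    Samples already present in the context are skipped in full.
    """
    _require_context(store, context)
    tab = read_biom(table)
    sample_ids = [str(s) for s in tab.ids("sample")]
    feature_ids = [str(f) for f in tab.ids("observation")]
    if len(set(sample_ids)) != len(sample_ids):
        raise IngestError("table sample ids are not unique")
    if len(set(feature_ids)) != len(feature_ids):
        raise IngestError("table feature ids are not unique")
    for sid in sample_ids:
        if SEPARATOR in sid:
            raise IngestError(
                f"sample id {sid!r} contains the reserved separator")
    for fid in feature_ids:
        if SEPARATOR in fid:
            raise IngestError(
                f"feature id {fid!r} contains the reserved separator")

    already = samples_represented(store, context)
    new_samples = [s for s in sample_ids if s not in already]
    skipped = len(sample_ids) - len(new_samples)
    if not new_samples:
        return LoadSummary(0, skipped, 0)

    features_before = len(features_represented(store, context))
    matrix = tab.matrix_data.tocsc()  # features x samples
    col_of = {s: j for j, s in enumerate(sample_ids)}
    feat_ints = map_identifiers(store, context, feature_ids, "feature")
    map_identifiers(store, context, new_samples, "sample")

    loaded = 0
    for sid in new_samples:
        col = matrix.getcol(col_of[sid])
        rows = col.indices
        counts = col.data
        if np.any(counts < 0):
            raise IngestError(
                f"negative count for sample {sid!r}; counts must be >= 0")
        keep = counts > 0
        rows, counts = rows[keep], counts[keep]
        pairs = [(feat_ints[i], float(c)) for i, c in zip(rows, counts)]
        sample_features = [feature_ids[i] for i in rows]
        store_vector(store, context, sid, pairs)
        store.set_add(StoreKey(context, "sample-features", sid),
                      sample_features)
        for fid in sample_features:
            store.set_add(StoreKey(context, "feature", fid), [sid])
        store.set_add(StoreKey(context, "samples-represented", "all"), [sid])
        store.set_add(StoreKey(context, "features-represented", "all"),
                      sample_features)
        loaded += 1

    features_new = len(features_represented(store, context)) - features_before
    return LoadSummary(loaded, skipped, features_new)


def feature_samples(
    store: KeyValueBackend, context: str, feature: str
) -> set[str]:
    """Inverted-index lookup: samples in which ``feature`` was observed."""
    return store.set_members(StoreKey(context, "feature", feature))


def sample_features(
    store: KeyValueBackend, context: str, sample: str
) -> set[str]:
    """Membership lookup: features observed in ``sample``."""
    return store.set_members(StoreKey(context, "sample-features", sample))


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------

def load_taxonomy(
    store: KeyValueBackend,
    context: str,
    source: str | Path | Iterable[str],
) -> int:
    """Index a 2-column feature-id TAB lineage file into ``context``.

    Each feature is indexed under every rank label of its ``;``-separated
    lineage (labels trimmed, stored verbatim otherwise).  Features not yet
    represented in the context are indexed anyway; they simply retrieve no
    samples.  Returns the number of features indexed.
    """
    _require_context(store, context)
    if isinstance(source, (str, Path)):
        lines = Path(source).read_text(encoding="utf-8").splitlines()
    else:
        lines = [line.rstrip("\n") for line in source]
    count = 0
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise IngestError(
                f"taxonomy line {lineno}: expected 2 tab-separated columns, "
                f"got {len(parts)}")
        feature, lineage = parts[0].strip(), parts[1].strip()
        if SEPARATOR in feature:
            raise IngestError(
                f"taxonomy line {lineno}: feature id contains the reserved "
                f"separator")
        labels = [t.strip() for t in lineage.split(";")]
        labels = [t for t in labels if t]
        for label in labels:
            if SEPARATOR in label:
                raise IngestError(
                    f"taxonomy line {lineno}: label {label!r} contains the "
                    f"reserved separator")
            store.set_add(StoreKey(context, "taxon", label), [feature])
        store.put_value(StoreKey(context, "lineage", feature), lineage)
        store.set_add(StoreKey(context, "taxon-labels", "all"), labels)
        count += 1
    store.put_value(StoreKey(context, "taxonomy-loaded", "flag"), "1")
    return count


def taxonomy_loaded(store: KeyValueBackend, context: str) -> bool:
    return store.get_value(
        StoreKey(context, "taxonomy-loaded", "flag")) is not None


def taxon_features(
    store: KeyValueBackend, context: str, label: str
) -> set[str]:
    """Feature ids carrying ``label`` at any rank of their lineage."""
    return store.set_members(StoreKey(context, "taxon", label))


def feature_lineage(
    store: KeyValueBackend, context: str, feature: str
) -> str | None:
    return store.get_value(StoreKey(context, "lineage", feature))
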