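"""Materialise query results back into analysis-ready files.

A hit set is only useful once it becomes a feature table plus a metadata
file that downstream tools (rarefaction, UniFrac, ordination, statistics)
can consume directly.  :func:`fetch_table` reassembles a BIOM table from
the stored sparse vectors of one context; :func:`fetch_metadata` emits the
matching sample-metadata TSV; :func:`export_hits` bundles both with a
checksummed provenance manifest.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import biom
import numpy as np
from scipy import sparse

from . import __version__
from . import indexing, metadata as md
from .kvstore import KeyValueBackend, StoreKey
from .query import SampleHitSet

GENERATED_BY = f"biomdex {__version__}"


class ExtractError(Exception):
    """Raised when a fetch cannot produce a meaningful result."""


def fetch_table(
    store: KeyValueBackend,
    context: str,
    samples: set[str],
    features: set[str] | None = None,
) -> biom.Table:
    """Assemble a BIOM table for ``samples`` from ``context``'s vectors.

    Columns are the requested samples present in the context, rows the
    union of features observed (count > 0) in them, both lexicographic;
    ``features`` optionally restricts the rows.  Stored integer feature
    ids are translated back to their original strings.  Requesting only
    samples absent from the context is an error distinct from an empty
    table.
    """
    if not indexing.context_exists(store, context):
        raise indexing.IngestError(f"unknown context {context!r}")
    present = sorted(set(samples) & indexing.samples_represented(store, context))
    if not present:
        if samples:
            raise ExtractError(
                f"none of the {len(samples)} requested samples are "
                f"represented in context {context!r}")
        raise ExtractError("no samples requested")

    reverse = store.record_get(
        StoreKey(context, "idmap-feature", "reverse"))
    vectors = {s: indexing.get_vector(store, context, s) for s in present}
    feature_ids: set[str] = set()
    for pairs in vectors.values():
        feature_ids.update(reverse[str(f)] for f, _ in pairs)
    if features is not None:
        feature_ids &= set(features)
        # a restriction can empty some columns; drop those samples so the
        # result contains only samples actually observing the features
        present = [s for s in present
                   if any(reverse[str(f)] in feature_ids
                          for f, _ in vectors[s])]
        vectors = {s: vectors[s] for s in present}
    rows = sorted(feature_ids)
    row_of = {f: i for i, f in enumerate(rows)}

    data, i_idx, j_idx = [], [], []
    for j, sample in enumerate(present):
        for feat_int, count in vectors[sample]:
            fid = reverse[str(feat_int)]
            if fid in row_of:
                i_idx.append(row_of[fid])
                j_idx.append(j)
                data.append(count)
    values = np.asarray(data, dtype=float)
    if values.size and np.all(values == np.floor(values)):
        values = values.astype(np.int64)
    matrix = sparse.coo_matrix(
        (values, (i_idx, j_idx)), shape=(len(rows), len(present)))
    return biom.Table(matrix.tocsr(), rows, present)


def write_table(
    table: biom.Table,
    path: str | Path,
    creation_date: datetime.datetime | None = None,
) -> Path:
    """Write a table as BIOM 1.0 JSON (sparse).

    ``creation_date`` may be injected for byte-stable output; it defaults
    to now.
    """
    path = Path(path)
    stamp = creation_date or datetime.datetime.now()
    path.write_text(
        table.to_json(GENERATED_BY, creation_date=stamp), encoding="utf-8")
    return path


def fetch_metadata(
    store: KeyValueBackend,
    samples: set[str],
    variables: Sequence[str] | None = None,
    missing_marker: str = "",
) -> tuple[list[str], list[list[str]], set[str]]:
    """Collect metadata rows for ``samples``.

    Returns ``(header, rows, samples_without_metadata)``: the header is
    the sample-id column followed by the requested variables (or the union
    of variables observed among the samples), rows are sorted by sample
    id, missing cells carry ``missing_marker``.  Samples with no metadata
    at all are omitted from the rows and reported in the third element.
    """
    with_md = set(samples) & md.metadata_samples(store)
    absent = set(samples) - with_md
    ordered = sorted(with_md)
    if variables is None:
        observed: set[str] = set()
        for sample in ordered:
            observed.update(
                k for k, v in md.get_record(store, sample).items()
                if v is not None)
        variables = sorted(observed)
    else:
        variables = list(variables)
    rows = []
    for sample in ordered:
        record = md.get_record(store, sample, variables)
        rows.append([sample] + [
            record[v] if record[v] is not None else missing_marker
            for v in variables])
    return ["#SampleID"] + variables, rows, absent


def write_metadata(
    header: list[str], rows: list[list[str]], path: str | Path
) -> Path:
    path = Path(path)
    lines = ["\t".join(header)] + ["\t".join(r) for r in rows]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


@dataclass(frozen=True)
class ExportManifest:
    query: str
    context: str | None
    n_samples: int
    timestamp: str
    version: str
    files: dict[str, str]  # filename -> sha256


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def export_hits(
    store: KeyValueBackend,
    hits: SampleHitSet,
    output_dir: str | Path,
    query: str = "",
    timestamp: datetime.datetime | None = None,
) -> ExportManifest:
    """Write the table + metadata + manifest bundle for a hit set.

    ``timestamp`` may be injected to make re-exports byte-identical.  The
    manifest records the query, context, sample count, tool version and
    the sha256 of each written file.
    """
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if hits.context is None:
        raise ExtractError("export requires a context-bound hit set")
    stamp = timestamp or datetime.datetime.now()
    table = fetch_table(store, hits.context, set(hits.samples))
    table_path = write_table(table, out / "table.biom", creation_date=stamp)
    header, rows, _ = fetch_metadata(store, set(hits.samples))
    md_path = write_metadata(header, rows, out / "metadata.tsv")
    manifest = ExportManifest(
        query=query or ";".join(hits.provenance),
        context=hits.context,
        n_samples=len(hits.samples),
        timestamp=stamp.isoformat(),
        version=__version__,
        files={
            table_path.name: _sha256(table_path),
            md_path.name: _sha256(md_path),
        },
    )
    manifest_path = out / "manifest.json"
    manifest_path.write_text(
        json.dumps(manifest.__dict__, indent=2, sort_keys=True) + "\n",
        encoding="utf-8")
    return manifest


__all__ = [
    "ExportManifest", "ExtractError", "export_hits", "fetch_metadata",
    "fetch_table", "write_metadata", "write_table",
]
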