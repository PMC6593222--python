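"""Brute-force oracles and randomized dataset builders for the test suite.

The dataset lives as plain dicts (context -> sample -> feature -> count,
sample -> variable -> value, feature -> lineage); every oracle answers a
query by scanning those dicts directly, independent of the indexed store
the implementation maintains.
"""

from __future__ import annotations

import numpy as np

from biomdex.metadata import is_missing, stem_text
from biomdex.where import And, Comparison, Or

from conftest import make_table

WORD_POOL = [
    "soil", "soils", "saline", "nonsaline", "antibiotics", "antibiotic",
    "forest", "forests", "arid", "acidic", "alkaline", "wet", "dry",
    "agricultural", "agriculture", "grassland", "treated", "treatment",
    "compost", "composted", "fecal", "gut", "mouse", "human", "pH 4",
    "warming", "warmed", "sample 12",
]
EMPO_POOL = ["Soil (non-saline)", "Soil (saline)", "Animal distal gut",
             "Water (non-saline)"]
COUNTRY_POOL = ["USA", "Peru", "China", "NA", "Unknown"]
TAXON_LABELS = ["k__Bacteria", "p__Firmicutes", "p__Acidobacteria",
                "g__Bacillus", "g__Nitrospira", "g__Clostridium"]


def random_dataset(rng: np.random.Generator, n_contexts=1,
                   max_samples=30, max_features=60):
    """Random raw tables + metadata + taxonomy, as plain dicts."""
    contexts = {}
    all_samples = set()
    for c in range(n_contexts):
        name = f"ctx{c}"
        n_samp = int(rng.integers(3, max_samples + 1))
        n_feat = int(rng.integers(5, max_features + 1))
        samples = [f"st{rng.integers(0, 3)}.S{c}{i:03d}" for i in range(n_samp)]
        samples = sorted(set(samples)) or [f"S{c}0"]
        features = [f"F{c}_{j:03d}" for j in range(n_feat)]
        density = rng.uniform(0.05, 0.4)
        table = {}
        for s in samples:
            row = {}
            for f in features:
                if rng.random() < density:
                    row[f] = int(rng.integers(1, 50))
            table[s] = row
        contexts[name] = table
        all_samples.update(samples)

    metadata = {}
    for s in sorted(all_samples):
        if rng.random() < 0.1:
            continue  # some samples have no metadata at all
        record = {}
        if rng.random() < 0.9:
            record["ph"] = (f"{rng.uniform(3, 10):.2f}"
                            if rng.random() < 0.8
                            else str(rng.choice(["NA", "none", "acidic"])))
        if rng.random() < 0.8:
            record["empo_3"] = str(rng.choice(EMPO_POOL))
        if rng.random() < 0.9:
            k = int(rng.integers(1, 4))
            record["description"] = " ".join(
                str(w) for w in rng.choice(WORD_POOL, size=k))
        if rng.random() < 0.7:
            record["country"] = str(rng.choice(COUNTRY_POOL))
        if rng.random() < 0.5:
            record["depth_cm"] = str(int(rng.integers(0, 100)))
        metadata[s] = record

    taxonomy = {}
    for name, table in contexts.items():
        features = sorted({f for row in table.values() for f in row})
        lineages = {}
        for f in features:
            genus = str(rng.choice(TAXON_LABELS[3:]))
            phylum = str(rng.choice(TAXON_LABELS[1:3]))
            lineages[f] = f"k__Bacteria; {phylum}; {genus}"
        taxonomy[name] = lineages
    return contexts, metadata, taxonomy


def dataset_to_inputs(contexts, metadata, taxonomy):
    """Render the raw dicts as the file formats the package ingests."""
    tables = {}
    for name, table in contexts.items():
        samples = sorted(table)
        features = sorted({f for row in table.values() for f in row})
        counts = [[table[s].get(f, 0) for s in samples] for f in features]
        tables[name] = make_table(counts, features, samples)

    variables = sorted({v for rec in metadata.values() for v in rec})
    lines = ["\t".join(["#SampleID"] + variables)]
    for s in sorted(metadata):
        lines.append("\t".join(
            [s] + [metadata[s].get(v, "") for v in variables]))

    tax_lines = {name: [f"{f}\t{lin}" for f, lin in sorted(lins.items())]
                 for name, lins in taxonomy.items()}
    return tables, lines, tax_lines


# ---------------------------------------------------------------------------
# brute-force query answers
# ---------------------------------------------------------------------------

def bf_stored_metadata(metadata):
    """What ingest should retain: records minus missing-marker values."""
    return {s: {v: x for v, x in rec.items() if not is_missing(x)}
            for s, rec in metadata.items()}


def bf_feature_search(table, features, reduce):
    sets = [{s for s, row in table.items() if f in row} for f in features]
    if reduce == "any":
        return set().union(*sets)
    return set.intersection(*sets)


def bf_taxon_features(lineages, label):
    out = set()
    for f, lin in lineages.items():
        labels = {t.strip() for t in lin.split(";")}
        if label in labels:
            out.add(f)
    return out


def bf_stem_index(metadata, variable=None):
    """stem -> samples, by stemming every stored value from scratch."""
    stored = bf_stored_metadata(metadata)
    index: dict[str, set[str]] = {}
    for s, rec in stored.items():
        for v, value in rec.items():
            if variable is not None and v != variable:
                continue
            for stem in stem_text(value):
                index.setdefault(stem, set()).add(s)
    return index


def _bf_number(x):
    try:
        return float(x)
    except (TypeError, ValueError):
        return None


def _bf_eq(stored, literal):
    a, b = _bf_number(stored), _bf_number(literal)
    if a is not None and b is not None:
        return a == b
    return stored == (literal if isinstance(literal, str) else str(literal))


def bf_compare(value, op, literal):
    # independent re-statement of the comparison semantics
    if value is None:
        return False
    if op in ("<", "<=", ">", ">="):
        v, b = _bf_number(value), _bf_number(literal)
        if v is None:
            return False
        return eval(f"v {op} b")  # noqa: S307 - trusted test-only operators
    if op == "==":
        return _bf_eq(value, literal)
    if op == "!=":
        return not _bf_eq(value, literal)
    if op == "in":
        return any(_bf_eq(value, item) for item in literal)
    return not any(_bf_eq(value, item) for item in literal)


def bf_eval_tree(node, record):
    if isinstance(node, Comparison):
        return bf_compare(record.get(node.variable), node.op, node.literal)
    if isinstance(node, And):
        return bf_eval_tree(node.left, record) and bf_eval_tree(node.right,
                                                                record)
    return bf_eval_tree(node.left, record) or bf_eval_tree(node.right, record)


def bf_where(metadata, clause_tree, universe=None):
    stored = bf_stored_metadata(metadata)
    candidates = set(stored) if universe is None else universe
    hits = set()
    for s in candidates:
        rec = stored.get(s, {})
        if bf_eval_tree(clause_tree, rec):
            hits.add(s)
    return hits


# ---------------------------------------------------------------------------
# random where-clauses and full-text expressions (tree + rendered text)
# ---------------------------------------------------------------------------

def random_clause(rng, depth=0):
    if depth < 2 and rng.random() < 0.4:
        left = random_clause(rng, depth + 1)
        right = random_clause(rng, depth + 1)
        return (And if rng.random() < 0.5 else Or)(left, right)
    variable = str(rng.choice(["ph", "empo_3", "country", "depth_cm"]))
    if variable in ("ph", "depth_cm"):
        op = str(rng.choice(["<", "<=", ">", ">=", "==", "!="]))
        literal = float(np.round(rng.uniform(0, 10), 1))
    else:
        op = str(rng.choice(["==", "!=", "in", "notin"]))
        if op in ("in", "notin"):
            pool = EMPO_POOL if variable == "empo_3" else COUNTRY_POOL
            k = int(rng.integers(1, 3))
            literal = tuple(str(x) for x in rng.choice(pool, size=k))
        else:
            pool = EMPO_POOL if variable == "empo_3" else COUNTRY_POOL
            literal = str(rng.choice(pool))
    return Comparison(variable, op, literal)


def render_clause(node, top=True):
    if isinstance(node, Comparison):
        if isinstance(node.literal, tuple):
            inner = ", ".join(f"'{x}'" for x in node.literal)
            return f"{node.variable} {node.op} ({inner})"
        if isinstance(node.literal, float):
            return f"{node.variable} {node.op} {node.literal}"
        return f"{node.variable} {node.op} '{node.literal}'"
    word = "and" if isinstance(node, And) else "or"
    text = (f"{render_clause(node.left, False)} {word} "
            f"{render_clause(node.right, False)}")
    return text if top else f"({text})"


def random_fulltext(rng, depth=0):
    """Return (rendered expression, evaluator over stem->samples index)."""
    if depth < 2 and rng.random() < 0.4:
        op = str(rng.choice(["&", "|", "-"]))
        ltext, lev = random_fulltext(rng, depth + 1)
        rtext, rev = random_fulltext(rng, depth + 1)
        text = f"({ltext} {op} {rtext})"
        if op == "&":
            return text, lambda ix: lev(ix) & rev(ix)
        if op == "|":
            return text, lambda ix: lev(ix) | rev(ix)
        return text, lambda ix: lev(ix) - rev(ix)
    word = str(rng.choice([w for w in WORD_POOL if " " not in w]))
    stems = stem_text(word)

    def evaluate(index, stems=stems):
        if not stems:
            return set()
        out = index.get(stems[0], set()).copy()
        for st in stems[1:]:
            out &= index.get(st, set())
        return out

    return word, evaluate
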