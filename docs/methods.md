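# Methods

## Data model

Everything is stored against a minimal key–value contract
(`biomdex.kvstore.KeyValueBackend`): string values, field→value records,
and string sets supporting intersection, union and left-fold difference.
Keys are composite `namespace:category:item` triples; because the
rendered form must be injective, no component may contain `:` (rejected
at write time, and propagated as input validation: sample ids, context
names, variable names and taxon labels containing `:` are refused at
ingest). The contract deliberately has no key-pattern scanning and no
transactions, so it can sit on any key–value engine; all enumerable
collections (the context registry, each context's samples-represented and
features-represented sets, the metadata sample/variable registries) are
maintained as explicit sets. The reference backend is in-process and
in-memory with explicit snapshot save/load to a single versioned file
(magic header `#biomdex-snapshot 1`, JSON body with sets stored sorted so
snapshots of equal stores are byte-identical). Whether a backend packs
small sets compactly is an internal representation concern and is not
observable through the contract.

## Contexts and indexing

A *context* partitions sample data by sequencing + bioinformatics
protocol. Counts are comparable within a context only; sample identities
are shared across contexts, which is what makes cross-protocol retrieval
(`partition_by_context`) meaningful.

Within a context, feature and sample ids are remapped to dense integers
in first-seen order (two independent id spaces). The maps are stored as
forward/reverse records and are never reassigned; `map_identifiers` is
stable across calls. Each loaded sample stores one sparse vector — the
JSON-encoded list of (feature-integer, count) pairs, sorted by feature
integer, zeros dropped, integral counts serialized as integers — plus a
feature-membership set, and every observed feature's inverted-index set
gains the sample.

Loads are idempotent per (context, sample): a sample already represented
is skipped *in full* and counted in the load summary, never merged —
merging would silently double counts on re-ingest. Counts are accepted as
non-negative reals (BIOM permits floats); negative counts are rejected.

Table input is BIOM 2.1 HDF5 (detected via `h5py.is_hdf5`) or BIOM 1.0
JSON, both parsed by `biom-format`; anything else is rejected rather than
guessed at. Taxonomy is a 2-column TSV (feature id, `;`-separated
lineage); each feature is indexed under every rank label of its lineage,
labels trimmed but otherwise verbatim. Taxon lookup is exact and
case-sensitive; normalising rank prefixes (`g__X` vs `X`) is left to
callers so ingest stays lossless.

## Metadata, stemming and queries

Metadata rows are stored as raw strings; a value is dropped at ingest if
it matches the missing vocabulary (empty string, `NA`, `N/A`, `NaN`,
`None`, `Unknown`, `not applicable`, any `Missing:`-prefixed value, all
case-insensitive — common usage in deposited mapping files).

Full-text indexing stems every stored value: lowercase, split on runs of
non-alphanumeric characters, drop tokens shorter than 2 characters and
purely numeric tokens (so `"pH 7"` indexes under `ph` and bare numerals
never pollute the index), then apply the Porter stemming algorithm and
deduplicate. No stop-word list is applied. Both a global stem→samples
index and a per-variable sub-index are maintained; the global index is by
construction the union of the sub-indices.

The stemmer (`biomdex.porter`) implements the canonical revision of the
published algorithm — the behaviour of the author's distributed
implementations, which differ from the journal text by two step-2
amendments (`bli`→`ble` replacing `abli`→`able`, plus `logi`→`log`) — and
returns words of length ≤ 2 unchanged. The test suite cross-validates it
against a second, independently structured rule-table implementation on a
generated vocabulary of >3000 word forms.

Full-text search is a small set algebra: terms (stemmed before lookup,
unknown stems = empty set), quoted phrases whose stems are intersected,
`&` (intersection, binds tightest), `|` and `-` (union and left-fold
difference, equal precedence, left-associative), parentheses. The Unicode
minus `−` is accepted as `-`.

Where-clauses are typed comparison trees: `variable OP literal` with
`== != < <= > >= in notin`, combined by `and`/`or` (`and` binds tighter)
and parentheses. Values stay raw strings and are typed per comparison:
ordering operators coerce the stored value and *exclude* the sample when
it is missing or non-coercible (so `ph > 0` doubles as a has-valid-pH
filter, matching how such constraints are used in practice); equality
compares exact strings unless both sides coerce numerically; `in`/`notin`
apply the equality rule across the literal list. A missing value
satisfies nothing, including `!=` and `notin` — absence is unknown, not
difference. An ordering comparison against a non-numeric literal is a
query error rather than silent emptiness, since the literal is under the
caller's control.

`select_samples` intersects whatever constraints are supplied (feature
search within a context, where-clause, full-text), then intersects with
the context's samples-represented set when a context is given; it is
therefore commutative and associative in its constraints by construction.

## Synthetic corpus generator

`biomdex.simulate` emulates the retrieval substrate of a multi-study soil
survey. Per sample: pH ~ Uniform(3.5, 9.0); each of 5 low-pH differential
features present with probability logistic(β·(6.5 − pH)) and each of 5
high-pH features with logistic(β·(pH − 6.5)), β = 1.5 log-odds per pH
unit; relative abundances from gamma weights (background features
Gamma(1,1) — jointly Dirichlet — and present differential features
Gamma(3,1), heavy enough that a present feature is essentially never lost
to multinomial sampling at depth); reads ~ Multinomial(Poisson(5000)).
Defaults: 5 studies × 80 samples, 150 background features, 10% of samples
are non-soil decoys (`empo_3 = "Animal distal gut"`, pH reported as
`not applicable`) so metadata constraints do real filtering work.
Feature ids are unique random 90-nt sequences; descriptions draw from
seeded word pools (antibiotics/saline/…) to exercise stem search;
lineages draw from small phylum/genus pools so taxon labels are shared
across features. All randomness flows from a single seeded generator, and
generated files are byte-identical for identical spec + seed (BIOM files
carry a fixed creation stamp).

What the generator does **not** emulate: ecological covariance between
taxa, study-level batch effects and primer biases, chimeras, variable
metadata vocabularies across studies, or realistic sparsity profiles.
Passing tests therefore demonstrate correctness of indexing, query
algebra and retrieval — not robustness of any biological inference to
real-data artefacts.

The two-context variant re-processes a configurable fraction (default
0.6) of samples into a closed-reference-like context: exact-sequence
features are mapped many-to-one onto OTU ids and counts aggregated,
preserving totals.

## Demonstration workflow and problem sizes

`demo.ph_replication` runs generate → load → search → fetch → test: each
differential panel is searched with `reduce=any` under
`ph > 0 and empo_3=='Soil (non-saline)'`, the reported pH of each
retrieval group is collected from the stored metadata, and the groups are
compared with a two-sided Mann-Whitney test (scipy). The two groups may
overlap (a mid-pH sample can contain members of both panels); they are
compared as retrieved, without de-overlapping, since the question is
about retrieval-by-panel. At the default design the separation is strong
(p well below 10⁻⁶ across seeds, low-panel median pH below high-panel
median in every seed).

Test-suite problem sizes were chosen to exercise every code path at desk
scale: randomized oracle corpora up to 50 samples × 200 features with up
to two contexts (200 corpora in the master equivalence test), 20-seed
replication of the demo at the default 5 × 80 design, and >3000-word
stemmer cross-validation. The whole suite runs in well under a minute.

## Numerical and determinism choices

- All observable orders are lexicographic (fetched table rows/columns,
  CLI output lines, serialized sets); ties cannot arise since ids are
  unique.
- Counts are stored as given and serialized as integers when integral,
  else decimals; fetched tables use an integer matrix when every count is
  integral.
- `fetch_table` with a feature restriction drops samples whose restricted
  column would be all-zero, so fetched tables never contain empty rows or
  columns.
- Export bundles accept an injected timestamp; given one, re-exports are
  byte-identical (checksums in the manifest make this verifiable).
- The CLI exits 0 on success, 1 on an empty result, 2 on usage/data
  errors, with one-line `E_<Type>: message` diagnostics on stderr.

## Known limitations

- The in-memory reference backend holds the whole store in RAM; the
  contract is designed so a server-backed adapter could replace it, but
  none is shipped.
- Single-writer locking is advisory (a lock file beside the snapshot);
  there is no concurrent-reader isolation during a write.
- Where-clause evaluation scans candidate samples linearly; there is no
  numeric range index. Fine at desk scale, by design.
- Full-text search has no phrase proximity, no fuzziness, and stems are
  English-oriented (Porter).
- Feature search is exact-match only; sequence similarity search (k-mer,
  alignment) is out of scope, as is any prevalence/ranking statistic.
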