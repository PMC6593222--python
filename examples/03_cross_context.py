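"""Find samples in one processing context, fetch their data from another.

Contexts partition the store by protocol (e.g. exact-variant denoising vs
closed-reference OTU picking).  Sample identities are shared, so a hit set
discovered with exact sequences can be partitioned against a second
context and the overlapping samples re-fetched under that protocol.
"""

from biomdex import (
    CorpusSpec,
    MemoryStore,
    create_context,
    fetch_table,
    generate_two_context_corpus,
    ingest_metadata,
    load_table,
    partition_by_context,
    search_features,
)

spec = CorpusSpec(n_studies=2, samples_per_study=25,
                  n_background_features=40, sequencing_depth=800, seed=42)
corpus, closedref_tables, truth = generate_two_context_corpus(
    spec, overlap_fraction=0.6)

store = MemoryStore()
create_context(store, "deblur-90nt", "exact variants")
create_context(store, "closedref-97", "reference OTUs, 60% of samples")
for study in sorted(corpus.tables):
    load_table(store, "deblur-90nt", corpus.tables[study])
for study in sorted(closedref_tables):
    load_table(store, "closedref-97", closedref_tables[study])
ingest_metadata(store, corpus.metadata_lines)

hits = search_features(store, "deblur-90nt",
                       corpus.truth["low_ph_features"], reduce="any")
present, absent = partition_by_context(store, set(hits.samples),
                                       "closedref-97")
print(f"{len(hits)} samples found via exact variants")
print(f"{len(present)} of them also have closed-reference data, "
      f"{len(absent)} do not")

table = fetch_table(store, "closedref-97", present)
print(f"fetched closed-reference table: "
      f"{len(table.ids('observation'))} OTUs x "
      f"{len(table.ids('sample'))} samples")
# The fetched table contains the same samples under the other protocol's
# feature space - the basis for protocol-bridging meta-analyses.
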