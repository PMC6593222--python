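"""Search samples by metadata: Porter-stem full text and where-clauses.

Every stored categorical value is tokenised and Porter-stemmed, so a
search for "antibiotics" also finds samples annotated "antibiotic
treatment".  Typed where-clauses filter on variables; numeric comparisons
silently exclude samples whose value is missing or not a number, which
makes "ph > 0" a has-valid-pH filter.
"""

from biomdex import MemoryStore, evaluate_where, ingest_metadata, \
    search_fulltext

store = MemoryStore()
rows = [
    "#SampleID\tph\tempo_3\tdescription",
    "S1\t4.2\tSoil (non-saline)\tforest soil, antibiotics amendment",
    "S2\t7.9\tSoil (non-saline)\tgrassland soil core",
    "S3\tNA\tAnimal distal gut\tmouse fecal pellet",
    "S4\t6.1\tSoil (saline)\tantibiotic resistance survey",
]
summary = ingest_metadata(store, rows)
print(f"ingested {summary.samples} samples, "
      f"{summary.values_dropped_missing} missing value dropped")

print("stem search 'antibiotics':",
      sorted(search_fulltext(store, "antibiotics")))
print("stem algebra 'soil - antibiotics':",
      sorted(search_fulltext(store, "soil - antibiotics")))
print("where ph < 7:", sorted(evaluate_where(store, "ph < 7")))
print("where clause with conjunction:",
      sorted(evaluate_where(
          store, "empo_3=='Soil (non-saline)' and ph > 0")))
# S3's pH is the missing marker NA: it is dropped at ingest and can never
# satisfy a numeric comparison.
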