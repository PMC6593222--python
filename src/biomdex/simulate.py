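"""Seeded synthetic corpus generator.

Emulates the shape of a multi-study, pH-structured 16S survey: several
studies of soil samples whose communities contain a shared background of
exact sequence variants plus a handful of *differential* features whose
presence probability rises at low pH (or, mirrored, at high pH).  The
generator writes exactly the formats the ingest side reads — BIOM 1.0 JSON
tables (one per study), a QIIME-style metadata TSV and a two-column
taxonomy TSV — plus a truth file recording the differential feature ids
and every sample's latent pH, so search results can be checked against the
generating process.

Generative model, per sample:

* pH ~ Uniform(ph_range);
* each low-pH feature is present with probability
  ``logistic(beta * (6.5 - pH))`` and each high-pH feature with
  ``logistic(beta * (pH - 6.5))``, where ``beta`` is the association
  strength in log-odds per pH unit;
* relative abundances come from gamma weights (background features
  Gamma(1, 1), i.e. jointly Dirichlet; present differential features
  Gamma(3, 1), so they are reliably sampled at depth), normalised and fed
  to a multinomial at Poisson(sequencing_depth) reads.

A fixed fraction of samples are non-soil decoys (different ``empo_3``, no
reported pH) so that metadata constraints do real work in tests.  All
randomness flows from one seeded generator: identical spec + seed gives
byte-identical files.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import biom
import numpy as np

from .extract import GENERATED_BY

_DNA = np.array(list("ACGT"))

#: fixed creation stamp written into generated BIOM files (determinism)
_EPOCH = datetime.datetime(2000, 1, 1)

_SOIL_DESCRIPTIONS = (
    "agricultural soil treated with antibiotics",
    "forest topsoil core",
    "grassland soil sample",
    "saline soil crust",
    "non-saline arable soil",
    "rhizosphere soil from wheat field",
    "alpine meadow soil",
    "soil amended with compost",
)
_DECOY_DESCRIPTIONS = (
    "fecal sample from laboratory mouse",
    "human distal gut biopsy",
)
_COUNTRIES = ("USA", "Peru", "Australia", "China", "Germany")
_PHYLA = ("Acidobacteria", "Actinobacteria", "Proteobacteria",
          "Firmicutes", "Verrucomicrobia", "Bacteroidetes")
_GENERA = ("Bradyrhizobium", "Streptomyces", "Bacillus", "Nitrospira",
           "Rhodoplanes", "Candidatus_Solibacter", "Gaiella", "Mycobacterium")


class SimulationError(ValueError):
    """Invalid corpus specification."""


@dataclass(frozen=True)
class CorpusSpec:
    """Study-design parameters for one synthetic corpus."""

    n_studies: int = 5
    samples_per_study: int = 80
    n_background_features: int = 150
    n_low_ph_features: int = 5
    n_high_ph_features: int = 5
    ph_range: tuple[float, float] = (3.5, 9.0)
    association_strength: float = 1.5  # log-odds per pH unit
    sequencing_depth: int = 5000       # Poisson mean reads per sample
    decoy_fraction: float = 0.1        # non-soil samples without pH
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_studies", "samples_per_study",
                     "n_background_features", "n_low_ph_features",
                     "n_high_ph_features", "sequencing_depth"):
            if getattr(self, name) <= 0:
                raise SimulationError(f"{name} must be positive")
        lo, hi = self.ph_range
        if not lo < hi:
            raise SimulationError("ph_range must be (low, high) with "
                                  "low < high")
        if not 0 <= self.decoy_fraction < 1:
            raise SimulationError("decoy_fraction must be in [0, 1)")


@dataclass
class Corpus:
    """An in-memory synthetic corpus plus its ground truth."""

    spec: CorpusSpec
    tables: dict[str, biom.Table]          # study id -> feature table
    metadata_lines: list[str]              # TSV incl. header
    taxonomy_lines: list[str]
    truth: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write all corpus files; byte-identical for identical spec+seed."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for study, table in sorted(self.tables.items()):
            p = out / f"{study}.biom"
            p.write_text(table.to_json(GENERATED_BY, creation_date=_EPOCH),
                         encoding="utf-8")
            paths[f"table:{study}"] = p
        p = out / "metadata.tsv"
        p.write_text("\n".join(self.metadata_lines) + "\n", encoding="utf-8")
        paths["metadata"] = p
        p = out / "taxonomy.tsv"
        p.write_text("\n".join(self.taxonomy_lines) + "\n", encoding="utf-8")
        paths["taxonomy"] = p
        p = out / "truth.json"
        p.write_text(json.dumps(self.truth, indent=2, sort_keys=True) + "\n",
                     encoding="utf-8")
        paths["truth"] = p
        return paths


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _random_sequences(rng: np.random.Generator, n: int,
                      length: int = 90) -> list[str]:
    seqs: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        seq = "".join(rng.choice(_DNA, size=length))
        if seq not in seqs:
            seqs.add(seq)
            out.append(seq)
    return out


def _lineage(rng: np.random.Generator) -> str:
    phylum = rng.choice(_PHYLA)
    genus = rng.choice(_GENERA)
    return f"k__Bacteria; p__{phylum}; g__{genus}"


def generate_corpus(spec: CorpusSpec) -> Corpus:
    """Draw one corpus from the generative model described above."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_bg = spec.n_background_features
    n_low = spec.n_low_ph_features
    n_high = spec.n_high_ph_features

    features = _random_sequences(rng, n_bg + n_low + n_high)
    bg_features = features[:n_bg]
    low_features = features[n_bg:n_bg + n_low]
    high_features = features[n_bg + n_low:]

    taxonomy_lines = [f"{f}\t{_lineage(rng)}" for f in features]

    md_header = ["#SampleID", "study_id", "ph", "empo_3", "description",
                 "country"]
    metadata_lines = ["\t".join(md_header)]
    tables: dict[str, biom.Table] = {}
    ph_truth: dict[str, float] = {}
    study_truth: dict[str, str] = {}
    decoys: list[str] = []
    beta = spec.association_strength
    lo, hi = spec.ph_range

    for s in range(spec.n_studies):
        study = f"{1000 + s}"
        n = spec.samples_per_study
        sample_ids = [f"{study}.S{i:04d}" for i in range(n)]
        ph = rng.uniform(lo, hi, size=n)
        is_decoy = rng.random(n) < spec.decoy_fraction
        low_present = rng.random((n, n_low)) < _logistic(
            beta * (6.5 - ph))[:, None]
        high_present = rng.random((n, n_high)) < _logistic(
            beta * (ph - 6.5))[:, None]

        counts = np.zeros((n_bg + n_low + n_high, n))
        for j in range(n):
            weights = np.concatenate([
                rng.gamma(1.0, 1.0, size=n_bg),
                np.where(low_present[j], rng.gamma(3.0, 1.0, size=n_low), 0),
                np.where(high_present[j], rng.gamma(3.0, 1.0, size=n_high), 0),
            ])
            depth = rng.poisson(spec.sequencing_depth)
            counts[:, j] = rng.multinomial(depth, weights / weights.sum())

        observed = counts.sum(axis=1) > 0
        tables[study] = biom.Table(
            counts[observed],
            [f for f, keep in zip(features, observed) if keep],
            sample_ids,
        )

        for j, sid in enumerate(sample_ids):
            ph_truth[sid] = round(float(ph[j]), 2)
            study_truth[sid] = study
            if is_decoy[j]:
                decoys.append(sid)
                row = [sid, study, "not applicable", "Animal distal gut",
                       str(rng.choice(_DECOY_DESCRIPTIONS))]
            else:
                row = [sid, study, f"{ph[j]:.2f}", "Soil (non-saline)",
                       str(rng.choice(_SOIL_DESCRIPTIONS))]
            row.append(str(rng.choice(_COUNTRIES)))
            metadata_lines.append("\t".join(row))

    truth = {
        "spec": {**asdict(spec), "ph_range": list(spec.ph_range)},
        "low_ph_features": low_features,
        "high_ph_features": high_features,
        "background_features": bg_features,
        "ph": ph_truth,
        "study": study_truth,
        "decoy_samples": sorted(decoys),
    }
    return Corpus(spec=spec, tables=tables, metadata_lines=metadata_lines,
                  taxonomy_lines=taxonomy_lines, truth=truth)


def generate_two_context_corpus(
    spec: CorpusSpec, overlap_fraction: float = 0.6
) -> tuple[Corpus, dict[str, biom.Table], dict]:
    """A corpus plus a second, closed-reference-like view of part of it.

    The second context covers ``overlap_fraction`` of each study's samples
    with a smaller feature space: the exact-sequence features are mapped
    many-to-one onto reference OTU ids and their counts aggregated,
    mimicking re-processing the same samples under a different protocol.
    Returns ``(corpus, second-context tables, overlap truth)``.
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise SimulationError("overlap_fraction must be within [0, 1]")
    corpus = generate_corpus(spec)
    # independent stream so the primary corpus is identical either way
    rng = np.random.default_rng((spec.seed, 0x0c2))
    all_features = (corpus.truth["background_features"]
                    + corpus.truth["low_ph_features"]
                    + corpus.truth["high_ph_features"])
    n_otus = max(1, len(all_features) // 3)
    otu_of = {f: f"OTU_{rng.integers(0, n_otus):04d}" for f in all_features}

    second: dict[str, biom.Table] = {}
    overlap_samples: list[str] = []
    for study, table in sorted(corpus.tables.items()):
        sample_ids = [str(s) for s in table.ids("sample")]
        k = int(round(overlap_fraction * len(sample_ids)))
        chosen = sorted(
            rng.choice(len(sample_ids), size=k, replace=False).tolist())
        chosen_ids = [sample_ids[i] for i in chosen]
        if not chosen_ids:
            continue
        overlap_samples.extend(chosen_ids)
        dense = table.matrix_data.toarray()
        feature_ids = [str(f) for f in table.ids("observation")]
        otus = sorted({otu_of[f] for f in feature_ids})
        otu_row = {o: i for i, o in enumerate(otus)}
        agg = np.zeros((len(otus), len(chosen_ids)))
        for fi, fid in enumerate(feature_ids):
            agg[otu_row[otu_of[fid]]] += dense[fi, chosen]
        keep = agg.sum(axis=1) > 0
        second[study] = biom.Table(
            agg[keep], [o for o, k_ in zip(otus, keep) if k_], chosen_ids)

    overlap_truth = {
        "overlap_fraction": overlap_fraction,
        "overlap_samples": sorted(overlap_samples),
        "feature_to_otu": otu_of,
    }
    return corpus, second, overlap_truth
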