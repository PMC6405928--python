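# premir

Species-specific pre-miRNA hairpin discovery toolkit.

The pipeline mirrors the classic homology-seeded, structure-filtered,
SVM-classified workflow for plant precursor miRNA prediction:

1. **homology** — seeded full-coverage ungapped search of known mature
   miRNAs against a genome (word length 7, top-10 hits, fewer than 5
   mismatches), with an exhaustive-scan mode and a BLAST outfmt-6 adapter.
2. **windows** — 500-nt flank extraction around each hit, multi-size
   sliding-window fragmentation (90/100/110/120 nt, step 10), and
   CD-HIT-style redundancy removal.
3. **structure** — hairpin folding with a bundled nearest-neighbour
   energy-minimisation engine (numba-accelerated; a maximum-pairing
   reference backend and an optional ViennaRNA adapter are also provided),
   topology metrics, and the pseudo-hairpin filter (stem 20–50 bp,
   GC 24–82 %, MFE −60…−20 kcal/mol, single hairpin).
4. **features** — a 133-entry reconstruction of the plant pre-miRNA
   feature catalog (composition, triplet elements, MFE-derived indices,
   topology, normalized variants), Mann–Whitney + Benjamini–Hochberg
   feature selection, and CDS-derived negative-set construction.
5. **svm** — class-weighted kernel SVM (linear/polynomial/RBF/sigmoid)
   with the published hyperparameters (γ = 1e-4, C = 5, j = 3, RBF) and a
   positive-score decision rule; JSON model persistence with a feature
   catalog hash guard.
6. **evalmetrics** — the twelve confusion-matrix metrics, trapezoidal
   ROC/AUC, and seeded stratified 5-fold cross-validation.
7. **validate** — star-sequence detection (Dicer duplex, 2-nt 3′
   overhang), exact small-RNA read matching, and homology lookup against a
   reference miRNA collection.
8. **simulate** — synthetic genomes with planted, filter-passing hairpin
   precursors and decoys, so every stage runs offline with known truth.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (metric-formula
fidelity against published table rows, metric identities, AUC vs
Mann–Whitney, homology vs exhaustive Hamming scan, filter boundaries,
window arithmetic, classifier sanity, and planted-genome recovery over 10
seeds).

## CLI

```sh
# generate a fixture bundle with planted ground truth
premir simulate --n-precursors 20 --n-decoys 10 --bg-len 50000 --seed 1 --out fixture/

# build labeled feature matrices from precursor + CDS FASTA
premir prepare-training --mirnas mirnas.fa --cds cds.fa --out training/

# train and evaluate
premir train --matrix training/training_matrix.tsv --out model.json
premir evaluate --matrix training/training_matrix.tsv --out eval/

# scan a genome (GFF3/BED/TSV of positive-scoring hairpin windows)
premir scan --genome fixture/genome.fasta --known-mirnas fixture/known_mirnas.fasta \
            --model model.json --out scan/

# computational validation of predicted matures
premir validate --predictions matures.fa --reads reads.fq \
                --reference-mirnas mirbase_subset.fa --out validation.tsv
```

All thresholds live in a YAML config (`--config`); defaults equal the
published parameterisation. Every command writes a `*.provenance.json`
sidecar recording the config hash, seed and backend. Exit codes: 0 success,
2 configuration error, 3 data error.

## Notes

- Coordinates are 0-based half-open internally; GFF3 output is 1-based
  inclusive.
- The homology engine is ungapped and mismatch-filtered; no E-value is
  computed (the conventional permissive cutoff admits every word-seeded
  candidate at these scales). Sensitivity for queries with ≥ 3 mismatches
  may require `exhaustive: true` on small genomes.
- Feature vectors are used unscaled by default, matching the SVMlight
  convention the tiny default γ is calibrated to; min-max scaling to [0,1]
  is available via `feature_scaling: minmax`.
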