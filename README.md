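# ssbdsb

Sequence-only classification of DNA-binding proteins into single-stranded
DNA binders (SSB) and double-stranded DNA binders (DSB).

The package provides:

- **Feature encodings** (`ssbdsb.features`):
  - square-root overall amino-acid composition (20-dim),
  - gapped dipeptide compositions at intervals 0/1/2 (400-dim each,
    1200-dim concatenated),
  - physicochemical-property region means over a length-conditional
    six-part split (N1–N4, M, C) using a vendored 28-property AAindex
    table (168-dim),
  - PSSM-profile region means over the same split (120-dim).
- **Models and evaluation** (`ssbdsb.classify`): random forest (3000 trees
  by default) and default-parameter SVM, one model per feature family;
  per-fold majority-class down-sampling; stratified 10-fold
  cross-validation; a majority-voting ensemble over the family models; a
  label-permutation baseline; ACC/SN/SP/MCC/F1 and rank-statistic AUC.
- **Descriptive contrasts** (`ssbdsb.analyze`): per-residue and
  per-dipeptide class frequency differences, per-(property, region)
  relative difference rates, random-forest Gini importance summaries.
- **I/O** (`ssbdsb.seqio`): FASTA, id/label tables, PSI-BLAST ASCII PSSM
  files, and the property table.
- **Synthetic data** (`ssbdsb.synthetic`): labeled sequence datasets with a
  tunable class-composition signal, valid PSSM files, random property
  tables — everything needed to exercise the pipeline offline.

## Command line

```sh
# generate a synthetic dataset (FASTA + labels + PSSM files)
ssbdsb simulate --n-dsb 400 --n-ssb 100 --delta 0.08 --seed 0 --out-dir run/

# per-family feature matrices
ssbdsb featurize --fasta run/sequences.fasta --pssm-dir run/pssm --out-dir run/features/

# 10-fold cross-validated metrics table (one row per family + "All features")
ssbdsb cv --fasta run/sequences.fasta --labels run/labels.tsv \
          --pssm-dir run/pssm --seed 0 --out run/metrics.tsv

# label-permutation baseline, same protocol
ssbdsb baseline --fasta run/sequences.fasta --labels run/labels.tsv --seed 0

# train on one dataset, evaluate on a disjoint one
ssbdsb test --train-fasta train.fasta --train-labels train.tsv \
            --test-fasta test.fasta --test-labels test.tsv

# persist models / predict new proteins
ssbdsb train --fasta run/sequences.fasta --labels run/labels.tsv --out model.joblib
ssbdsb predict --model model.joblib --fasta new.fasta --out predictions.tsv

# class contrasts (residues, dipeptides, property difference rates)
ssbdsb analyze --fasta run/sequences.fasta --labels run/labels.tsv --out-dir run/analysis/
```

If no PSSM directory is given, the PSSM feature family is dropped and the
ensemble votes over the remaining five models.

## Notes

- Positive class defaults to DSB (configurable via `--positive-class`).
- Down-sampling is applied inside each training fold only; test folds are
  never altered.
- All randomness flows through explicit seeds; repeated runs with the same
  seed produce byte-identical metric tables.
- The vendored property table (`src/ssbdsb/data/aaindex28.tsv`) carries the
  28 AAindex accessions used for the physicochemical encoding, with values
  from the public AAindex1 release.
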