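# chemnet

Biological distances between chemicals from chemical–protein (STITCH-style)
and protein–protein (STRING-style) interaction networks, hierarchical
clustering of chemicals into functional groups, and structure-based
classifiers that assign novel compounds (SMILES) to those clusters.

## What it does

1. **Network clustering** (`chemnet.network`): reads scored edge tables,
   builds per-chemical protein profiles (score-weighted with one-step
   protein–protein propagation), computes cosine biological distances,
   clusters hierarchically at a distance threshold, filters clusters by
   support, and annotates each cluster with protein sets at a high (Qcutoff)
   and a low (Lcutoff) confidence score cutoff.
2. **Encoding** (`chemnet.encoding`): canonical SMILES, 1024-bit radius-2
   Morgan fingerprints, 42-row per-character feature matrices, and token
   sequences under atom-wise or learned pair-encoding (SPE) tokenization.
3. **Augmentation** (`chemnet.augmentation`): exhaustive or sampled
   enumeration of equivalent SMILES (root atom × branch traversal order) and
   class-wise augmentation that grows small classes toward
   `k × largest class size`.
4. **Models** (`chemnet.models`): four architectures behind one
   train/predict contract — fingerprint MLP (`dnn`), character-matrix CNN
   (`cnn`), 3-layer LSTM perceiver (`rnn_seq2seq`), and language-model
   pretraining + fine-tuning with weight-dropped LSTMs, averaging
   switchover, and gradual unfreezing (`lm_finetune`). Implemented on a
   small NumPy reverse-mode autodiff core (`chemnet.nn`); training is
   deterministic per seed.
5. **Evaluation** (`chemnet.evaluation`): stratified holdout + k-fold CV
   splits with an augmentation leakage guard, macro/micro F1, paired
   sign-flip randomization tests (exhaustive when feasible), architecture
   comparison reports, and top-k prediction with cluster annotation and
   inter-cluster cophenetic distances.
6. **Synthetic fixtures** (`chemnet.fixtures`): planted-partition protein
   communities, cluster-specific chemical attachment, and motif-bearing
   SMILES libraries, so the whole pipeline is testable offline.

## CLI

```bash
# synthetic fixture directory (edge tables, library.smi, labels.csv)
chemnet fixtures make --out fixture/ --seed 5

# cluster chemicals from interaction tables
chemnet cluster run --cp fixture/chemical_protein.tsv \
    --pp fixture/protein_protein.tsv \
    --threshold 0.5 --min-support 10 --linkage average --out clust/

# encode molecules
chemnet encode --scheme fingerprint --in fixture/library.smi \
    --labels fixture/labels.csv --out encoded/

# class-wise augmentation of a labeled CSV (id,smiles,cluster)
chemnet augment --in labeled.csv --k 5 --seed 7 --out augmented.csv

# train / predict
chemnet train --arch dnn --in labeled.csv --out model/
chemnet predict --model model/ --in compounds.smi --top-k 3 --out preds.csv

# cross-validated architecture comparison with randomization tests
chemnet evaluate compare-arch --in labeled.csv --arch dnn --arch cnn \
    --k-folds 10 --out report/
```

## Notes

- The profile/cosine biological distance is a documented, swappable
  surrogate for network-topology distance methods; see
  `chemnet.network.build_profiles`.
- Full-scale model widths are available via `models.full_scale_config`; the
  `desk_config` presets train in seconds to minutes on one CPU.
- Sequence-model augmentation is train-split only; fingerprint and
  feature-matrix encodings are order-invariant, so augmentation does not
  apply to them.
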