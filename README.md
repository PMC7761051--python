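# promidiag

Diagnostic machine learning for compound promiscuity analysis of
biological screening data.

Starting from a ternary compound × target screening matrix (active /
inactive / untested), the pipeline:

1. **Curates** the data: drops assays with hit rates above a threshold
   (default 2%) and compounds carrying interference flags (PAINS,
   aggregator, chemical liability, FLuc inhibitor, cytotoxic).
2. **Samples MT-/ST-CPD groups**: multi-target compounds (promiscuity
   degree ≥ 5, or a configurable threshold) each matched, per active
   target, with a single-target compound that is active on that target
   and *explicitly* inactive on the group's other targets — every group
   member has a recorded outcome for every group target (data
   completeness; untested never counts as inactive).
3. **Profiles nearest-neighbor structure**: per compound, the maximum
   Tanimoto similarity (Morgan radius-2, 2048-bit fingerprints) to any
   other MT and any other ST compound.
4. **Builds dataset conditions**: full, 50% random group removal, and
   50% nearest-neighbor removal (25% of groups with the most similar
   MT-CPDs plus 25% with the most similar ST-CPDs).
5. **Runs diagnostic ML**: balanced MT/ST pairs, double cross-validation
   (10 external × 10 internal trials, 80/20 splits), three classifiers —
   k-NN over Tanimoto distance, random forest, and SVM with linear or
   Tanimoto kernel — reporting BA, F1, MCC, precision, recall, and AUC.
6. **Analyzes structure**: analog-series fractions (single-cut
   core-sharing proxy) and target networks linked by shared MT-CPDs.

A synthetic-data module generates fingerprint libraries with planted
analog series, promiscuity roles, screening-scale test frequencies, and
the MT/ST nearest-neighbor asymmetry, so every stage is testable offline.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (metric oracle
suite, ROC anchors, KNN equivalence, kernel PSD, group completeness, and
the scaled benchmark trends); the full suite takes a few minutes on one
CPU.

## CLI

```sh
promidiag simulate --seed 1 --out-dir bundle/            # synthetic inputs
promidiag curate   --matrix bundle/activity_triplets.tsv --flags bundle/flags.tsv --out-dir run/
promidiag groups   --matrix bundle/activity_triplets.tsv --pd-threshold 5 --seed 1 --out-dir run/
promidiag nn       --groups run/groups.jsonl --fingerprints bundle/fingerprints.tsv --out-dir run/
promidiag reduce   --groups run/groups.jsonl --fingerprints bundle/fingerprints.tsv --condition NN_REMOVAL --out-dir run/
promidiag ml       --groups run/groups.jsonl --fingerprints bundle/fingerprints.tsv --models KNN,RF,SVM --out-dir run/
promidiag analogs  --ground-truth bundle/ground_truth.tsv --out run/analogs.json
promidiag network  --groups run/groups.jsonl --min-shared 50 --out-dir run/
promidiag all      --config config.json                  # everything, one seed
```

`promidiag all` consumes a JSON config (inputs, curation thresholds,
sampling, conditions, CV protocol, hyperparameter grids, models, seed)
and writes per-stage artifacts plus a summary table of mean ± sd for the
five performance measures per condition × model.

## Layout

```
src/promidiag/
  activity_data.py       ternary matrix model, I/O, curation filters
  group_sampling.py      MT identification, matched ST groups, completeness
  chem_similarity.py     fingerprints, Tanimoto, NN profiling
  dataset_conditions.py  full / random-removal / NN-removal conditions
  diagnostic_ml.py       balancing, double CV, KNN/RF/SVM, metrics, ROC
  structure_analysis.py  analog detection, target networks
  synthetic_data.py      planted-structure generator
  benchmark.py           scaled end-to-end benchmark harness
  pipeline.py, cli.py    orchestration and command-line interface
```
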