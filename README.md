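# ctbayes

Detection-censored qPCR quantification with Bayesian multiple testing for
age-stratified case/control designs.

The package implements a complete analysis pipeline for TaqMan-style Ct
matrices from a child/adult celiac-disease case-control study design:

1. **Synthetic data** (`ctbayes.simdata`) — Ct datasets with a configurable
   stratified design (default: 13 CD children, 7 control children, 6 CD
   adults, 5 control adults), per-assay Gaussian latent Ct, per-stratum group
   effects, and deterministic censoring at a limit-of-detection cycle
   (wells above it are emitted as `Undetermined`). Ground truth is returned
   for recovery tests.
2. **Quantification** (`ctbayes.qpcr`) — wide-CSV Ct I/O, partition of
   assays by detection status (never detected / detected in a minority of
   samples / analyzable), dCt against the mean of selected reference assays,
   and comparative-Ct fold changes (2^-ddCt) against an age-matched control
   calibrator.
3. **Reference genes** (`ctbayes.refstab`) — stability ranking by pairwise
   variation (M values with stepwise exclusion and the V(k/k+1) series) and
   by a model-based group-bias score; consensus selection of k references.
4. **Differential expression** (`ctbayes.bayesmt`) — per-gene
   difference-of-means statistics with Welch standard errors, a
   spike-and-slab two-groups model on standardized statistics fitted by
   penalized marginal likelihood (or a Gibbs sampler), posterior null
   probabilities `Pr(mu_i = 0 | all statistics)`, and the Bayes decision
   rule rejecting when the posterior alternative strictly exceeds
   `c_fn / (c_fp + c_fn)` (0.5 at equal costs).
5. **Detection tests** (`ctbayes.detect`) — one-sided Fisher exact tests on
   detected/undetected contingency tables of rarely detected genes, and a
   Spearman age-correlation screen.
6. **Reporting** (`ctbayes.report`) — combines the three posterior tables
   (children, adults, cases-by-age) into an age-of-onset taxonomy
   (`similar_both`, `only_children`, `only_adults`, `higher_adults`,
   `higher_children`, `not_altered`), writes TSV/JSON outputs, and hosts the
   pipeline orchestrator.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (closed-form and
enumeration oracles, parameter-recovery and calibration simulations).

## CLI

```sh
ctbayes simulate --seed 1 --out data/            # CSV trio + ground truth
ctbayes preprocess --ct data/ct_matrix.csv --samples data/samples.csv \
    --assays data/assays.csv --refs PUS10,GLB1 --out pre/
ctbayes refgenes --ct data/ct_matrix.csv --samples data/samples.csv \
    --assays data/assays.csv --k 2
ctbayes test --expr pre/delta_ct.tsv --samples data/samples.csv \
    --comparisons children,adults,cd_by_age --engine eb --out post/
ctbayes detect-test --ct data/ct_matrix.csv --samples data/samples.csv \
    --assays data/assays.csv --genes IL21,IL17F,IL22
ctbayes run --config config.yaml --out results/ --seed 1   # whole pipeline
```

A minimal pipeline config:

```yaml
simulate: {}          # or io: {ct: ..., samples: ..., assays: ...}
filters: {majority_fraction: 0.5}
model: {engine: eb, min_per_group: 3}
costs: {c_fp: 1, c_fn: 1}
```

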