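# metabostrat

Stratification of an imbalanced two-class metabolomics cohort from an LC-MS
peak-area table, and identification of the differential metabolites that
separate the classes.

The motivating problem: a cohort of elderly diabetic patients splits into a
majority and a minority clinical stratum (e.g. 238 "deficiency" vs 57
"excess" syndrome patients), profiled by UPLC-QTOFMS into ~135 annotated
peak-area features. The questions are (a) can the strata be classified from
the serum metabolome, and (b) which metabolites carry the separation?

The pipeline:

1. **Preprocess** — remove the internal-standard feature, sum-normalize each
   sample, unit-variance scale each feature.
2. **Rebalance** — SMOTE oversampling of the minority class to parity
   (optionally tuning the neighbor count).
3. **Select features** — a genetic-algorithm wrapper whose fitness is the
   balanced prediction error of a kernel-OPLS (K-OPLS) classifier, repeated
   over many independent runs.
4. **Call differentials** — a feature is called when its selection frequency
   across GA runs beats a binomial null (P < 0.001) *and* it differs between
   classes by a Wilcoxon rank-sum test (P < 0.05).
5. **Final model** — K-OPLS on the selected features with kernel width σ and
   orthogonal-component count Ao tuned by cross-validated accuracy, reported
   with R2X/R2Y/Q2Y, AUC (DeLong 95% CI), sensitivity and specificity.

See [docs/methods.md](docs/methods.md) for the statistical details, parameter
rationale and limitations.

## Quick start (Python)

The API follows the model/results convention: construct a model object, call
`fit()`, inspect the returned results object.

```python
from metabostrat import (
    GAConfig, PipelineConfig, SyntheticSpec, generate_cohort, run_full,
)
from metabostrat.synthetic import IS_MZ, IS_RT

# simulate an imbalanced 80-patient cohort with 3 planted ~1.7-fold features
table, labels, truth = generate_cohort(
    SyntheticSpec(n_class0=60, n_class1=20, n_features=40,
                  n_informative=3, log2_effect=0.8, seed=4)
)

config = PipelineConfig(
    is_mz=IS_MZ, is_rt=IS_RT,    # strip the internal standard
    smote_n_grid=None,           # keep the protocol value n=3
    ga=GAConfig(population_size=20, n_generations=30, n_runs=20),
    seed=0,
)
results = run_full(table, config)   # = SyndromeStratifier(table, config).fit()
print(results.summary())
```

Output (verbatim):

```text
Metabolomics stratification results
========================================
samples: 80 (20 excess / 60 deficiency), features: 39
SMOTE neighbor parameter n: 3
GA runs: 20, mean selected per run (m): 10
features in final model: 3

Final K-OPLS model (evaluated on the original cohort)
  sigma=2.22  Ao=0  ACCV=0.983
  R2X=0.504  R2Y=0.846  Q2Y=0.837
  AUC=0.990 (95% CI 0.973-1.000)
  sensitivity=0.950  specificity=0.983
  total accuracy=0.975  balanced accuracy=0.967
Strict held-out evaluation
  AUC=0.993  sensitivity=1.000  specificity=0.900  balanced accuracy=0.950

differential metabolites called: 3
  M0013: selected 15/20 runs, P_GA=5.36e-06, P_Wilcoxon=1.02e-08 (up in excess)
  M0025: selected 13/20 runs, P_GA=2.42e-04, P_Wilcoxon=2.45e-07 (up in excess)
  M0027: selected 19/20 runs, P_GA=8.90e-11, P_Wilcoxon=1.26e-09 (up in excess)
```

The three calls are exactly the three planted features
(`truth.informative_feature_ids`). Note the two evaluations: the headline
block re-uses the training cohort (the protocol's convention, optimistic);
the strict block is a held-out half-split.

Other entry points on the results object: `results.called` (DataFrame of
passing features), `results.calls` (all features with both P values),
`results.subgroup_robustness(covariate, cutoff)` (refit within covariate
strata), `results.save(run_dir)` (all artifacts + manifest).

Lower-level pieces are usable on their own, e.g.:

```python
from metabostrat import KOPLS
res = KOPLS(X_train, y_train, sigma="median", n_ortho=2).fit()
res.predict_class(X_new)
q2y, accv = res.cross_validate(n_folds=10, seed=0)
```

## Quick start (CLI)

```bash
metabostrat simulate --out-dir sim --seed 4           # synthetic cohort
metabostrat run-all sim/peaks.tsv sim/labels.tsv \
    --out-dir run --ga-runs 20 --ga-generations 30 --no-smote-optimization
metabostrat clinical-summary clinical.csv             # baseline table
```

`run-all` writes `report.json`, `report_strict.json`,
`differential_calls.tsv`, `selection_counts.tsv`, `accv_surface.tsv`,
`scores.tsv` and a `manifest.json` with the config hash.

Peak tables are plain TSV with features as rows (`feature_id`, `rt_min`,
`mz`, one column per sample) plus a two-column `sample_id  label` file
(1 = minority/excess class).

## Testing and reproduction

```bash
python -m pytest            # full suite; the end-to-end recovery study
                            # (marked "slow") dominates the runtime
python -m pytest -m "not slow"   # everything else, ~10 s
```

One test is red by design: `test_criterion_6b_null_cohorts_yield_no_calls`
documents that the dual significance criterion does **not** control
family-wise error on null cohorts at the protocol's stated thresholds (the
repeated GA runs are correlated through the shared data, breaking the
binomial independence null). The mechanism and the recommended remedy
(a multiplicity-corrected Wilcoxon co-criterion) are analyzed in
[docs/methods.md](docs/methods.md).

The suite verifies the numerical core against independent oracles
(`tests/oracles.py`): linear-kernel K-OPLS against a from-scratch primal
OPLS, the binomial selection-frequency tail against rational-arithmetic
summation, and the Wilcoxon test against full permutation enumeration.
`tests/test_acceptance.py` holds one test per release criterion.

To regenerate the acceptance evidence JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

All randomness flows from explicit seeds (`numpy` `SeedSequence` spawning per
stage), so every pipeline run, test and script is reproducible bit-for-bit
given its seed.
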