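# prforest

Probabilistic random forests (PRF) for tabular data with **uncertain class
labels**, plus the experimental machinery to compare label-handling policies
on cohorts where some outcomes were assigned *post hoc* and are not certain.

A PRF treats input features as probability distributions (Gaussian, with the
stated uncertainty as standard deviation) and class labels as probability
mass functions. During training a sample propagates to *both* children of a
split with the Gaussian crossing probabilities; impurity is a modified Gini
over probability-weighted class masses; a `keep_probability` threshold drops
negligible paths. Prediction propagates a point to all leaves and averages
terminal-node class distributions by arrival probability. With all
uncertainties zero the learner reduces exactly to a greedy weighted-Gini
CART ensemble (and automatically switches to a fast numba kernel for that
case).

The package ships:

- `prforest.dataset` — `UncertainDataset` / `UncertainSample` containers
  (features, per-feature uncertainties, label pmfs, confirmed/post hoc flags).
- `prforest.splitting`, `prforest.tree`, `prforest.forest` — the learner:
  split search, probabilistic tree growth (reference numpy engine + numba
  fast path), forest fitting, prediction, impurity-based feature importances,
  balanced soft-label class weights, JSON model serialization.
- `prforest.policies` — the three label policies: `exclude` (drop uncertain
  samples), `naive` (accept nominal labels), `probabilistic` (soft pmfs with
  a configurable probability, default 0.5, on the nominal label).
- `prforest.evaluation` — nested stratified k-fold CV (default k=7) with
  inner-loop grid search, confirmed-label-only test metrics
  (precision/recall/F1 in percent, ROC/AUC), and `run_comparison`, which runs
  all policies against a shared fold plan and shared random streams so the
  comparison is exactly paired.
- `prforest.synthetic` — a seeded generator of synthetic clinical cohorts
  (default: 81 confirmed positive, 29 confirmed stable, 32 post hoc "stable"
  with 50% latent positives; log-normal volumetric features, binary
  treatment arm) and a lossless CSV round trip with a separate latent-truth
  sidecar.
- `prforest.cli` — a `prforest` command with `simulate`, `fit`, `predict`
  and `compare` verbs; every run writes a manifest (seed, config, versions,
  input digests).

## CLI quick start

```bash
# 1. generate a synthetic cohort (142 subjects) + latent-truth sidecar
prforest simulate --out cohort.csv --seed 7

# 2. compare the three label policies under nested stratified 7-fold CV
prforest compare --data cohort.csv --seed 7 --out results/
cat results/summary.csv            # mean (SD) AUC / recall / precision / F1

# 3. fit and apply a single model
prforest fit --data cohort.csv --policy probabilistic --out model.json --seed 7
prforest predict --model model.json --data cohort.csv --out predictions.csv
```

`compare` accepts `--policies exclude,naive,probabilistic`,
`--posthoc-prob` (default 0.5), `--k` (default 7), `--keep-probability`
(default 0.05) and `--grid grid.json` (lists for `n_trees`, `max_features`,
`min_samples_split`, `min_samples_leaf`).

## Notes

- All randomness flows from explicit seeds; identical seeds give
  bit-identical models, cohorts and reports.
- Evaluation metrics are always computed on confirmed-label test samples
  only; post hoc samples never enter confusion counts.
- Default hyperparameters use effective-mass leaf/split minimums of 5/10 —
  regularized trees are both the sensible default at n≈140 and necessary for
  soft labels to behave differently from hard wrong labels (fully grown
  trees isolate either into single-sample leaves).
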