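# erpseq

A tested, reusable pipeline for dissociating contextual constraint
(cloze-distribution entropy) from word predictability (log₂ cloze
probability) in single-trial ERP amplitudes, with sequential
Bayes-factor sample-size determination:

- **cloze predictors** (`erpseq.cloze`) — stem collapsing, cloze
  proportions, Laplace-smoothed log₂ cloze, Shannon entropy in bits,
  model-subset centring;
- **synthetic data** (`erpseq.simulate`) — Latin-square designs,
  Dirichlet-categorical cloze response sets calibrated to two-level
  constraint (mean entropies ≈ 0.68 / 2.44 bits), hierarchical trial
  amplitudes (correlated by-subject intercept+slopes, by-item
  intercepts), raw epochs with injected component templates and
  blink/step artifacts, and independent-race stop-signal sessions —
  all bit-reproducible under a seed;
- **ERP preprocessing** (`erpseq.preprocess`) — zero-phase FIR/IIR
  bandpass, segmentation, 200 ms baseline correction, sliding
  peak-to-peak (100 µV / 150 ms) and voltage-step (50 µV/ms) artifact
  rejection, ROI × window averaging (N400 / anterior PNP / posterior
  P600), trial-table assembly;
- **hierarchical Bayesian models** (`erpseq.model`) — Gaussian LMMs with
  truncated-normal and LKJ priors. Random effects are marginalized
  analytically (Woodbury identity on precomputed Gram matrices), and the
  low-dimensional collapsed posterior is sampled by mode-initialized
  adaptive Metropolis; R̂ / bulk- and tail-ESS diagnostics via arviz;
- **evidence** (`erpseq.evidence`) — iterative bridge-sampling marginal
  likelihoods with a moment-matched split-half proposal, nested-model
  Bayes factors with evidence classification, prior-sensitivity sweeps,
  and a Savage–Dickey cross-check;
- **sequential design** (`erpseq.sequential`) — the BF ≥ 10 / ≤ 1/10
  stopping rule with a 150-participant cap, and simulation-based design
  analysis (median BF vs. sample size);
- **stop-signal analytics** (`erpseq.stopsignal`) — session screening and
  SSRT by the integration method;
- **orchestration** (`erpseq.pipeline`, `erpseq.cli`) — a single config
  drives synthesis → preprocessing → the two confirmatory comparisons
  (constraint on conditions b∪d with predictability as nuisance;
  predictability on a∪b) → bridge-sampling BFs with the pre-registered
  one-sided priors → deterministic JSON/TSV reports.

## CLI

```bash
erpseq simulate design --subjects 4 --items 224 --seed 1 --out design.tsv
erpseq simulate cloze --items 224 --seed 2 --out predictors.tsv
erpseq simulate trials --subjects 20 --items 40 --seed 3 --out table.tsv
erpseq fit --table table.tsv --model model.yaml --seed 4 --out fit/
erpseq evidence bf --table table.tsv --model model.yaml --term entropy_centered
erpseq evidence sweep --table table.tsv --model model.yaml --term entropy_centered \
    --scales 0.2,0.5,1,2 --variants truncated,untruncated --out sweep.tsv
erpseq sequential --table table.tsv --model model.yaml --term entropy_centered \
    --every 5 --threshold 10 --cap 150 --out trace.tsv
erpseq design-analysis --grid 100:700:7 --reps 1 --seed 5 --out curve.tsv
erpseq ssrt --sessions sessions/ --out ssrt.tsv
erpseq run-all --config config.yaml --seed 6 --out results/
```

A model YAML names the response, fixed terms, random structure and
priors:

```yaml
response: amplitude
fixed_terms: [entropy_centered, log2_cloze_centered]
random_subject: [intercept, entropy_centered, log2_cloze_centered]
random_item: true
priors:
  intercept: {family: normal, loc: 0, scale: 5}
  entropy_centered: {family: truncated_normal, loc: 0, scale: 0.2, truncation: negative_only}
  log2_cloze_centered: {family: normal, loc: 0, scale: 1}
  sigma_subject: {family: truncated_normal, loc: 0, scale: 0.5, truncation: positive_only}
  sigma_item: {family: truncated_normal, loc: 0, scale: 0.5, truncation: positive_only}
  sigma_residual: {family: truncated_normal, loc: 8, scale: 2, truncation: positive_only}
  rho: {family: lkj, lkj_eta: 2}
```

Exit codes distinguish validation (2), convergence (3) and I/O (4)
failures.

## Notes on scale

Registered-report contracts (50,000 MCMC iterations; R̂ ≤ 1.01 and
ESS ≥ 2,000 on every parameter) are preserved as the defaults of
`check_convergence`; `fit_model` defaults to a documented desk-scale
reduction (4 chains × 2,000 post-warmup draws) that can be raised via
`iterations=`/`warmup=`.
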