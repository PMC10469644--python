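# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `evfingerprint`.

## Generative model for the synthetic cohort

Each patient belongs to one of four biopsy strata — negative biopsy, grade
group (GG) 1, GG 2, GG 3–5 — with default margins 157/90/95/73 out of 415.
The default "fixed counts" mode apportions the configured proportions by
largest remainder and shuffles the assignment, reproducing the margins
exactly; a multinomial mode is available. Patients in the top stratum draw an
ISUP grade from {3, 4, 5} with probabilities (0.60, 0.25, 0.15) — only the
GG ≥ k dichotomies matter downstream.

**Event model.** A patient's plasma carries a latent mixture of three EV
subpopulations ("bulk", "debris", "tumour"), each log-normal per channel in
log10 units with a shared scatter–marker correlation ρ (default 0.3),
implemented as a one-factor model: log10 x_c = μ_c + σ_c(√ρ z₀ + √(1−ρ) z_c).
Per-patient mixture fractions are Dirichlet around the stratum weights with
concentration 8.0. The tumour subpopulation — elevated PSMA, ghrelin-probe
and polysialic-acid fluorescence — has stratum weights (0.015, 0.04, 0.08,
0.18); a `separation` knob scales the between-stratum contrast of those
weights around their cohort mean, with 0 producing an exactly null generator.
With the defaults, the latent tumour fraction discriminates GG ≥ 3 with AUC
≈ 0.87, placing the downstream machine-learning scores in the published
discrimination regime (EV score ≈ 0.85, clinical ≈ 0.7) rather than at
ceiling. This calibration was fixed once, against the latent fractions only.

**Acquisition.** Events arrive Poisson at a configurable rate per µL of
diluted sample; acquisition runs at 3.01 µL·min⁻¹ for up to 120 s or
5,000,000 events, whichever first, after a 100-fold plasma dilution. The
default event rate (4,000 events/µL, ≈ 24,000 events per replicate) is a
realistic instrument throughput; the `scaled()` profile (330 events/µL,
≈ 2,000 events per replicate) is used by the test suite and acceptance
script. Replicates (default 3) share the patient's latent mixture and add a
5 % log-normal concentration jitter; real replicate variance is unpublished,
so this default is a package choice.

**Clinical covariates.** Age, PSA and BMI are log-normal per stratum with the
published medians as targets and sigmas implied by the published IQRs; the
five binary covariates use the published per-stratum rates. Missingness is
completely at random at per-covariate rates (0–10 %), matching the reported
"available in ≥ 83 % of patients" without asserting a mechanism.

**Seed discipline.** One master seed spawns a cohort-level stream plus one
child stream per patient, keyed by patient index; enlarging the cohort never
reshuffles earlier patients, and identical configs are byte-identical.

What the generator does *not* emulate: antibody binding kinetics, spectral
spillover/compensation, swarm/coincidence detection, instrument drift, and
any real correlation structure between clinical covariates and EV content
beyond the shared grade stratum. Passing tests therefore demonstrate that the
pipeline recovers signal *of the kind injected*, not that the assay works on
real plasma.

## ROI features

Intensities are log10-transformed with non-positive values clamped to a floor
(default: half the smallest positive value in the channel). Each event maps
to exactly one 16 × 16 bin per channel pair; out-of-range events clamp into
the outer bins so that ROI counts conserve the event total — "particle
concentration" implies no event is discarded. Bin edges default to a fixed
log10 range (0, 4) per channel, which is deterministic and leakage-proof; a
quantile strategy fit on training data is available and warns when a non-
training pool is offered. ROI counts divide by (acquisition volume /
dilution), i.e. events per µL of *undiluted* plasma — the divisor is explicit
and configurable because published reports rarely state it. Replicate vectors
are averaged element-wise.

## EVMAP learner

- **Folds:** repeated stratified k-fold (default 5 folds); stratification
  preserves class counts within one patient per fold. A class smaller than
  the fold count raises an error that names the remedy.
- **RFE:** at each subset size a random forest (impurity importances,
  recomputed each iteration) is fit per repeat×fold; held-out AUCs average
  into the profile and the lowest-ranked floor(fraction × current) features
  (at least one) are dropped, to a single feature. Removal fraction is 10 %
  for the GG ≥ 2 / GG ≥ 3 targets and 25 % for GG ≥ 1. The selected subset
  maximizes mean AUC; ties prefer fewer features.
- **Grid search:** all 4 × 3 × 2 = 24 combinations of boosting rounds, depth
  and learning rate, ranked by mean CV AUC; ties break deterministically
  toward fewer rounds, then smaller depth, then smaller eta.
- **Ensemble:** with fixed parameters, one booster per repeat×fold (500 at
  the full 100-repeat scale) is trained on the 80 % training split and scores
  its held-out fold; the EVMAP score is the mean of a patient's held-out
  probabilities × 100. All XGBoost knobs outside the grid stay at library
  defaults; single-threaded training plus per-model derived seeds makes the
  ensemble bit-reproducible.
- **Scaled profile:** tests and the acceptance script run 10 repeats × 5
  folds (50 models) with pinned parameters (nrounds 100, depth 3, eta 0.1)
  and skip RFE/grid search; the full protocol remains a config switch. The
  note's problem sizes are the package's own desk-scale defaults.

## Clinical stack

Missing covariates are imputed with training-fold medians (binary covariates
round half-up to {0, 1}); imputation and model fitting never see held-out
rows. The clinical risk calculator is a pluggable logistic
`RiskModelSpec` (intercept, coefficient map, named covariate transforms,
percent output). The shipped default is a **synthetic stand-in** over the six
standard covariates — its coefficients are not a published calculator's, but
its output range and direction match one (median ≈ 9 % in GG ≤ 2 vs ≈ 16 % in
GG ≥ 3 on the default cohort); the real calculator drops in as YAML. The
stack itself is a plain maximum-likelihood logistic regression under
5-fold CV in three variants: EVMAP+PSA+age, EVMAP+PSA+age+DRE, and
EV-Fingerprint = EVMAP + clinical-risk probability (the headline variant
stacks the risk calculator's output, not the raw covariates). Perfect
separation raises an explicit error; an optional ridge fallback
(sklearn, C = 10) is provided for degenerate folds and is what the pipeline
uses by default.

## Evaluation statistics

- **AUC** is the trapezoidal ROC integral, identical to the normalized
  Mann–Whitney U with midrank ties (property-tested).
- **DeLong** uses the O(n log n) midrank structural-components estimator;
  identical score vectors short-circuit to p = 1, and a zero-variance
  difference with equal AUCs is reported as indistinguishable rather than an
  error.
- **BCa bootstrap** is implemented directly (bias correction from the
  bootstrap CDF at the point estimate, acceleration from jackknife skewness)
  because confusion-metric CIs need label-stratified *paired* resampling of
  (score, label) patients; scipy's BCa is used as a cross-check in tests. A
  degenerate bootstrap distribution yields a zero-width interval with a
  warning. Default 100,000 resamples; tests use 1,000–6,000.
- **Cutoffs** come from the rule "sensitivity ≥ 95 %, then maximum
  specificity" over observed score values, with ties resolved toward higher
  sensitivity and then the higher cutoff — the secondary sensitivity
  preference keeps perfectly separable data at the 100 %/100 % operating
  point.
- **Positivity convention:** score ≥ cutoff means "biopsy recommended"
  everywhere (confusion, avoidance, decision curves).
- **Display rounding** is half-up to integer percent in report tables; all
  machine-readable outputs keep full precision. Ratios with empty
  denominators are NaN, never 0.
- **Decision curves** use NB(p_t) = TP/n − (FP/n)·p_t/(1−p_t) with treat-all
  and treat-none references and the biopsies-avoided-per-100 transform;
  thresholds outside (0, 1) are excluded, percent grids are auto-converted.
- **Cohort summaries** use Mann–Whitney U for interval covariates and
  Fisher's exact test for binary ones, with no multiplicity correction
  (matching standard practice for descriptive tables).

### A note on null calibration of cross-validated scores

Out-of-fold ensemble scores are a function of the labels they are later
compared against. Under a pure null their AUC is *not* distributed like an
independent score's — permuting labels against the fixed scores gives a band
that is far too narrow (observed null AUCs ≈ 0.38–0.61 at n = 200). The
package's null-signal test therefore refits the entire ensemble under label
permutations and tests exchangeability of the observed AUC within the refit
distribution (a min/max band over 39 refits is an exact 5 % test).

## Known limitations

- The FCS reader/writer is minimal (list mode, float data, single dataset);
  it round-trips the package's own files and plain list-mode floats but is
  not a general FCS toolkit. CSV is the primary text interface.
- The shipped clinical risk coefficients are a stand-in; absolute risk
  calibration of the "pcptrc" column is meaningful only relative to the
  synthetic cohort.
- RFE at the full 1024-feature scale with 10-repeat CV is computationally
  heavy by design (thousands of forest fits); the pipeline exposes it but the
  desk-scale profile skips it.
- BCa coverage for skewed statistics at small n is slightly below nominal
  (≈ 92 % for the exponential mean at n = 30) — a property of the method, not
  of this implementation, and shared by reference implementations.
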