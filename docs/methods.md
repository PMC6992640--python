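# Methods

This note documents the models, defaults, numerical choices and
limitations behind each stage of the pipeline, and what the synthetic-data
generators do and do not emulate.

## Viability normalization

Each treated well's luminescence signal is divided by the mean
vehicle-control signal of the same tumor model and scaled to percent.
No clamping is applied anywhere in the screen statistics: apparent
viability above 100% is biologically meaningful here, because drugs that
activate the CMV promoter driving the luciferase reporter (HDAC inhibitors
are the canonical case, and some proteasome inhibitors at low dose) inflate
the signal without increasing cell number. Records whose replicate-mean
viability exceeds an **artifact threshold** (default 120% of vehicle) are
flagged. The threshold is a judgment call: it sits above typical plate
noise (a few percent SD) and below the 130-200% apparent-viability range
such reporter artifacts produce. Flagged drugs are not removed; in ranking
they sink to the bottom (policy `sink`), preserving list lengths so top-N
cutoffs stay comparable across configurations; a `drop` policy is
available.

Replicates are averaged at the viability level for the screen, but for
combination dose-response analysis replicate **Fa** values are averaged
before fitting — the two stages use stage-appropriate defaults.

Fraction affected is Fa = 1 − viability/100, clamped into
[ε, 1 − ε] with ε = 1e-4. The clamp exists because the median-effect
linearization takes log(Fa/(1−Fa)), undefined at the boundary; clamped
points are marked and excluded from fits rather than silently pulled in.

## Hit triage

Within each model drugs are ranked by ascending mean viability (most
cytotoxic first); ties break lexicographically on the drug label so that a
top-N cutoff is deterministic regardless of input order. The per-model
top-N sets are partitioned by occupancy: a drug is in cell *k* when it
appears in exactly *k* of the sets (the cells partition the union — this
is property-tested). The follow-up set is the union of chosen cells plus
explicit manual nominations; which single-model exclusives to nominate is
scientific judgment, so they are arguments, never inferred.

Hierarchical clustering of response/expression matrices defaults to
centered Pearson correlation distance with average linkage — the customary
configuration for expression heatmaps — both configurable and recorded in
the result. Constant rows are rejected under correlation distance (the
distance is undefined) with the offending row named.

## Supra-additivity statistic

For fixed single doses, delta = combo inhibition − (sum of single-agent
inhibitions); the sign classifies supra/additive/sub trends. The additivity
reference is deliberately the plain **effect sum**, not Bliss independence:
the statistic is implemented verbatim, and under Bliss-independent
generation it evaluates to exactly −100·i1·i2, a strictly sub-additive
signature — a useful oracle and a caveat for interpretation (high single
agent effects force negative deltas).

Across models the package computes a two-sided one-sample t-test of the
mean delta against zero, the t-based 95% CI, and a Wilson score 95% CI for
the proportion of models trending supra-additive — Wilson because it
behaves at the n = 4 typical of PDX panels. An all-identical delta vector
is reported with a degenerate-variance flag and NaN statistics rather than
a fabricated p-value. Deltas default to per-model means (n = models); a
per-replicate mode exists.

## Median-effect synergy analysis

Dose-response series follow the mass-action median-effect model
Fa/Fu = (D/Dm)^m. Fitting is unweighted OLS of log10(Fa/Fu) on log10 D
(base 10; the slope is base-invariant, the intercept handling fixes Dm =
10^(−intercept/m)). Points with clamped Fa are excluded and logged with
reasons; at least two usable points are required, and a non-positive slope
raises an invalid-fit error (a non-cytotoxic series has no meaningful Dm).
Two-point fits report |r| = 1 by construction.

The combination index uses the classic mutually-exclusive (no cross-term)
form, the default of the standard desktop tool for this analysis; the
non-exclusive variant is out of scope. The Fa evaluation grid defaults to
0.05…0.95 in steps of 0.05 plus 0.97, covering the high-effect region.
DRI_j(Fa) = Dx_j(Fa)/(p_j·D_mix(Fa)); the identity CI = Σ_j 1/DRI_j holds
to machine precision and is asserted in tests.

The decision rule — promising iff CI < 1 **and** both DRI > 1 at every
grid point with Fa > 0.75 — is exposed both on fits (`call_synergy`) and
on raw profiles (`synergy_rule_violations`). One subtlety: for a profile
derived from a single consistent set of fits, CI < 1 mathematically implies
both DRI > 1 (CI is the sum of the positive DRI reciprocals), so the DRI
clause only bites for externally supplied or replicate-averaged profiles.

**Loewe construction used for ground truth.** With equal slopes m and dose
fractions (p1, p2), the Loewe-additive mixture satisfies
1/Dm_mix = p1/Dm1 + p2/Dm2; scaling Dm_mix by an interaction multiplier κ
yields a mixture whose CI equals κ at every Fa. This is how the generator
plants known synergy. With unequal slopes the constant-κ guarantee is lost
(CI varies with Fa); the generator therefore assumes equal slopes and
documents the caveat.

## Expression and outcomes

Subtype summaries report mean and range per intrinsic subtype; all-pairs
Tukey HSD comparisons use the studentized-range distribution. Correlation
panels are pairwise-complete Pearson; binary clinical covariates are
consumed as 0/1, making those cells point-biserial correlations; cells with
a constant variable or fewer than 3 complete pairs are undefined (NaN), not
zero.

Median splits are strict: samples ordered by (value, label), the top
floor(N/2) are "high", so ties at the median resolve to the low group,
deterministically. Crossing two genes' splits yields hh/hl/lh/ll quadrants;
for even N the counts satisfy |hh| = |ll| and |hl| = |lh| exactly
(property-tested). Survival comparison uses the product-limit estimator
and the k-sample log-rank test; quadrant pairs are compared with
unadjusted p-values by default, with an optional Holm adjustment.

## Synthetic data

Generators emulate the experimental designs, not the biology:

- **Screen**: default 1,363 drugs × 10 models in duplicate with 8 vehicle
  wells per model at a set photon flux; true per-drug viabilities drawn as
  hits (5-50% of vehicle, default fraction 0.15), reporter artifacts
  (130-200%, fraction 0.05) and weak responders (60-100%), with per-model
  jitter (SD 5) for tumor-model heterogeneity and Gaussian plate noise on
  the viability scale (SD 5 percent of vehicle — typical duplicate
  scatter).
- **Dose response**: seven-dose ladders; Gaussian noise on log10(Fa/Fu)
  (default SD 0.05), the scale on which the model is linear, so the OLS
  estimators are consistent; replicate Fa values averaged as in analysis.
- **Combination**: the scaled-Loewe construction above with known κ.
- **Cohort**: default 855 samples across six intrinsic subtypes (basal-like
  fraction 0.164, matching a 140-patient basal stratum); log-normal
  expression with subtype-specific log-means (EGFR and BIRC5 elevated in
  basal-like); exponential event times whose hazard is looked up from the
  sample's *realized* expression quadrant, with independent exponential
  censoring — so quadrant stratification targets exactly the planted
  contrast.

Every generator draws from a named substream of one integer seed (stream
ids are frozen), so outputs are bit-reproducible and adding a generator
never perturbs existing draws.

**What passing tests do not show.** The generators have no plate spatial
effects, no off-target pharmacology or time-course kinetics, Gaussian
rather than heteroscedastic plate noise, exactly exponential survival, and
mixtures that obey the equal-slope Loewe construction. Tests demonstrate
that the estimators recover planted truth under these models — not that
real screens satisfy them.

## Problem sizes and numerical choices

Simulation-based checks use: 200 seeded series for median-effect and CI
recovery (log-noise SD 0.05; median bias < 5% asserted); a 500-drug ×
4-model screen for hit recall; 1,000 null cohorts of 140 samples for
log-rank calibration (the basal-stratum size; at much smaller n the 3-df
chi-square approximation of the log-rank statistic is visibly
anticonservative, a known small-sample property). Table I/O re-parses
numerics with Python's strtod for exact round-trips. All dose handling is
in µM internally.

## Known limitations

- Constant-ratio designs only; no response-surface models (Bliss/ZIP/HSA
  surfaces) or checkerboards, and no three-drug combinations.
- No plate-effect (row/column/edge) correction.
- Subtype labels are inputs; no PAM50 calling. No Cox regression.
- The CI formula's mutually-nonexclusive variant is not implemented.
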