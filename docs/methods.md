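# Methods

This note documents the statistical procedures, the synthetic-data
model, the numerical conventions, and the design decisions behind
`rhythmpower`.  It states no empirical result beyond what the test
suite and `scripts/acceptance.py` compute at run time.

## Preprocessing

Input is a tidy long table — participant, protein, DLMO time (hours
since the participant's dim light melatonin onset), technical
replicate, abundance — plus a per-participant DLMO clock-time table.
Stages, in order:

1. **Replicate averaging.** Technical replicates of one
   (participant, protein, timepoint) cell are collapsed to the
   arithmetic mean of their non-missing values; a cell is missing only
   if all replicates are.
2. **Missingness filter.** A protein is excluded when its fraction of
   missing cells, pooled over all participants and timepoints, is
   *strictly greater than* 10 % (configurable).  On the default 16-point
   design this keeps 1 missing cell per participant-series (6.25 %) and
   drops 2 (12.5 %).  The fraction is pooled, not per-participant; the
   filter's own report lists every protein with its fraction.
3. **Per-participant z-scoring.** Each (participant, protein) series is
   centred to mean 0 and scaled to sample sd 1 (ddof = 1).  Centring is
   included even though only the scaling matters downstream — the
   cosinor MESOR absorbs any offset — because it makes the "unit total
   variance" premise of the power module hold exactly per series.
   Scaling is per series, not pooled across proteins.  Constant series
   raise an error naming the participant and protein; missing points
   stay missing (no imputation).
4. **Time conversion utilities.** `clock_to_dlmo` is a plain
   subtraction of the participant's DLMO clock time, with clock hours
   allowed to run past 24 for sequential sessions (03:46 the next
   morning is 27.77); this keeps the mapping monotone over a 30 h
   session and exactly invertible.  `wrap_dlmo_hours` maps values into
   the signed display range (−12, 12] for reporting; `decimal_to_hhmm`
   renders decimal hours as HH:MM with round-half carry.

## Cosinor screen

Per participant and period τ ∈ {24, 12} h, ordinary least squares of
the z-scored series on [1, cos(2πt/τ), sin(2πt/τ)] gives MESOR and the
coefficient pair (β, γ); amplitude and acrophase follow as
A = √(β²+γ²), φ = (τ/2π)·atan2(γ, β) mapped into [0, τ).  Fits require
at least 4 non-missing points and a full-rank design (times not all
congruent modulo τ); all non-missing timepoints enter unweighted.

The population summary is the arithmetic mean of the k individual
coefficient vectors, and the zero-amplitude test is the classical
population-mean cosinor (Hotelling-type): T² = k m̄ᵀS⁻¹m̄ with S the
between-subject sample covariance of (β_i, γ_i), referred to
F = ((k−2)/(2(k−1)))·T² on (2, k−2) df.  This is the standard statistic
of population-mean cosinor software; k ≥ 3 is required and a singular S
(e.g. identical noiseless subjects) is an explicit error.  The test is
exact under Gaussian noise; per-participant z-scoring makes the
subject coefficient vectors a Gaussian scale mixture instead, a
perturbation small enough that the Monte-Carlo calibration check in the
acceptance suite (500 null proteins, k = 10) still sees the nominal 5 %
rate within ±2 points.

A protein × period passes the screen iff p < 0.05 **and** population
amplitude > 0.1 z-units, both strict, mirroring common practice of
gating on a minimal effect size as well as significance.  No
protein-level FDR is applied; a Benjamini–Hochberg column can be
emitted for reference but never gates the flag.  Acrophases are
reported in [0, τ) with a signed (−τ/2, τ/2] display column, since both
conventions circulate in the field.  Per-protein fit failures are
collected and reported rather than aborting the screen.

Cross-period leakage: on the default 16-point/30 h grid the 24 h and
12 h harmonics are not orthogonal (the span is 1.25 cycles of the 24 h
component), so a pure 24 h cosine leaks a nonzero amplitude into the
12 h fit (≈ 0.19 per unit amplitude, from the design's normal
equations; frozen as a regression test).  The amplitude gate and the
population test keep this from flagging spurious 12 h rhythms at the
amplitudes of interest, but the leakage is a property of the sampling
design users should know about.

## Power cost of uncontrolled rhythmicity

Variance decomposition: σ²_total = σ²_base + σ²_rhythm + σ²_cov, with
σ²_cov = 0 under independence of the rhythm and the base variation;
multiple cosine components add their rhythm variances.  The two-group,
equal-n, equal-variance, two-sided design gives

    n = (Z_{α/2}+Z_β)²·2·σ²_total/d²,   Z_β = √(n d²/(2σ²_total)) − Z_{α/2},

a closed-form pair that inverts exactly (the suite checks the round
trip to 1e-9).  Defaults: α = 0.05, baseline β = 0.20, d = 0.5 z-units.
Normal quantiles are computed to double precision; rounding to integer
percent (half-up) happens once, in the reporting layer.

On z-scored data the two reported columns take the d-free forms

    increase in n  = 100·(1/(1−σ²_rhythm) − 1),
    β uncontrolled = Φ̄((Z_{α/2}+Z_{β₀})·√(1−σ²_rhythm) − Z_{α/2}),

where n is first fixed at the value achieving the baseline power under
the controlled variance 1 − σ²_rhythm and then evaluated at total
variance 1.  Both are strictly increasing in A with A² leading
behaviour.

**Amplitude→variance convention.** The variance sum law gives
σ²_rhythm = A²/2 for a cosine of amplitude A (`eq2-half`).  The
published per-protein table, however, is reproduced — all 15 rows,
both columns, after integer rounding — only by σ²_rhythm = A²
(`table3-full`), equivalent to treating the reported A as the rhythm's
standard deviation; this was established by brute-force recomputation
of both conventions over all rows, and is kept as a regression test.
`table3-full` is therefore the default so that reported numbers match
the reference table; `eq2-half` is selectable everywhere, always yields
strictly smaller costs for A > 0, and neither convention is asserted as
"correct".  A 15-row reference screen table (protein, period,
acrophase, p, amplitude) ships with the package as ready-made input for
these computations.

## Synthetic cohort generator

The generator emulates a DLMO-aligned constant-routine proteome time
course:

| parameter | default | meaning |
|---|---|---|
| n_participants | 10 | cohort size |
| timepoints | 0, 2, …, 30 | 16 two-hourly DLMO-hours |
| n_replicates | 3 | technical replicates per sample |
| noise_sd | √(1 − ΣA²/2) per protein | sample-level Gaussian sd |
| replicate_noise_frac | 0.20 | replicate sd as a fraction of noise_sd |
| missing_rate | 0 | MCAR cell missingness probability |
| baseline_mean / sd | 0 / 0.5 | participant×protein baseline M_ip |
| dlmo_clock_mean / sd | 22.77 / 1.11 | cohort DLMO clock time (dec. h) |

Abundance for participant i, protein p at DLMO time t is
M_ip + Σ_c A_c·cos(2π(t−φ_c)/τ_c) + ε_cell, with independent
replicate-level noise on top and missingness applied at the cell level
(all replicates of a missing cell missing).  The default noise sd makes
the series' total variance ≈ 1 by the variance sum law, so planted
amplitudes are directly on the post-z-score scale used for reporting;
an explicit `noise_sd` overrides this per-cohort.  Randomness uses one
root seed with per-(participant, protein) substreams, so enlarging the
cohort or appending proteins never perturbs existing data, and equal
seeds give byte-identical tables.

What the generator does **not** emulate: peptide-level structure,
intensity-dependent (non-MCAR) missingness, between-run drift,
non-Gaussian heavy-tailed noise, inter-individual amplitude/phase
heterogeneity beyond coefficient noise, and correlated proteins.
Passing tests on this generator therefore demonstrate correctness of
the estimators and pipeline mechanics under the stated noise model, not
robustness to real LC-MS pathologies.  Replicate CVs and abundance
distributions of real data are unknown here; the replicate-noise and
baseline defaults are placeholders chosen once, configurable, and of
negligible influence on the screen (replicate noise is shrunk 3-fold by
averaging; baselines are absorbed by centring).

**Estimator bias note.** The population amplitude √(β̄²+γ̄²) is a norm
of a noisy mean and thus carries a Rice-type upward bias of roughly
Var(β̄)/(2A) for A well above the noise floor (≈ +0.02 at A = 0.3 with
k = 10 on the default design).  Consequently, recovery of a planted
amplitude is assessed on the resultant vector — average the cohort-level
(β̄, γ̄) estimates across replicate simulations, then take the norm —
the same aggregation rule the population-mean cosinor applies across
subjects; a plain mean of per-cohort amplitudes would measure the bias,
not the signal.  Acrophases are aggregated by circular mean.

## Pipeline and reproducibility

The end-to-end runner executes generate/ingest → replicate averaging →
missingness filter → z-scaling → per-period screen → power table and
curves, writing plain CSV throughout plus a JSON manifest with the
config hash, seed, per-stage record counts and library versions.
Report files are staged in memory and written only after all stages
succeed, so failed runs leave no partial outputs; identical config and
seed give byte-identical files (no timestamps are embedded).  Figures
(polar acrophase plot, cost curves) are optional side-effects; their
data always also exists as text.

## Problem sizes in the test suite

The suite's Monte-Carlo checks use 500 null proteins for Type I error
calibration (±2-point band around 5 %), 200 replicate cohorts for
amplitude/acrophase recovery (±0.02 z-units, ±0.5 h), a 73-protein
cohort with planted single- and dual-period rhythms for screen
mechanics, and 1,000 random designs for the n↔Z_β round trip.  All
stochastic tests run from fixed seeds; hypothesis-based property tests
are derandomized.  Mechanics tests plant amplitudes of 0.65–0.7 so that
detection is essentially deterministic and the assertions exercise
bookkeeping (panel membership, strict gates, per-period rows) rather
than detection power; power at reference-scale amplitudes (~0.3) is
deliberately left to the calibration and recovery checks, which use the
reference-scale conditions unchanged.

## Known limitations

- Single-component cosinor only; no period estimation, multi-harmonic
  fits, or rank-based (JTK-style) detectors — small cohorts at 16
  timepoints invite overfitting with richer models.
- Power framework covers two-group mean comparison with equal n and
  variance; other designs (paired, survival, regression adjustment) are
  out of scope, as is a nonzero rhythm–base covariance beyond carrying
  a user-supplied constant.
- The zero-amplitude test's exactness degrades for very small k or
  strongly non-Gaussian noise; k ≥ 3 is a hard floor, k ≈ 10 is the
  intended regime.
- No protein-level multiple-testing control by design; at 73 proteins ×
  2 periods the screen expects ~7 false positives at p < 0.05, which the
  amplitude gate only partially suppresses.
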