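# Methods

This note documents the models, conventions and numerical choices behind
`imaware`, and what the synthetic-data tests do and do not establish about
real recordings.

## Stimulus model

A trial is 10 s long. The masker is a set of pure tones (20 ms, 10 ms
raised-cosine ramps) on frequencies log-spaced between 239 and 5000 Hz with
`fpo` values per octave. Each frequency runs its own renewal process: the
first onset is uniform on [0, interval_max] and later gaps are i.i.d. uniform
on [interval_min, interval_max] with mean `miti`; whether the original
paradigm used per-track renewal processes or a pooled process is not
decidable from its description, so the per-track reading is used and stated
here. The four density conditions are the (miti, fpo) pairs
(200, 32), (400, 64), (600, 96), (800, 128), carrying the labels 11, 20, 28,
36 s⁻¹oct⁻¹ in that order; the labels are treated as opaque condition names
because they are not recomputable from fpo/miti (all four pairs share
fpo/miti = 160 s⁻¹oct⁻¹) — an ambiguous quantity is never recomputed.

The target is a regular stream of 100 ms tones starting 600 ms into the
masker, with per-tone amplitude equal to the masker tones (0 dB
target-to-masker ratio). The protected region spans ±1 ERB around the target
frequency, the interval closed on both ends (boundary tones removed —
conservative protection). Rendering peak-normalizes to −1 dBFS before 16-bit
quantization; absolute presentation level is out of scope. Note that the
protected region constrains tone *placement*; the 20 ms tones still splatter
spectral sidelobes into it, so the spectral test asserts an order-of-
magnitude power deficit rather than literal zero energy.

## Behavioral scoring

Responses before 1600 ms on target-present trials cannot reflect two heard
target repetitions and are dismissed as guesses; by default such trials are
recoded as misses (every trial must land in exactly one of the four outcome
categories), with an `drop_guesses` switch to exclude them instead.
d′ uses the log-linear correction (add 0.5 per cell, 1 per denominator) by
default so empty cells stay finite; false alarms are attributed to the
density of the trial they occurred on, since every trial carries a masker.

## Synthetic EEG generator

The generator's purpose is parameter recovery: its defaults encode the
effect structure the downstream analyses are designed to detect, so that
every stage can be validated end to end without recordings.

* **Base signal** — per channel, a first-order autoregressive process
  (coefficient 0.9, i.e. a spectral corner near 16 Hz at 1 kHz) shaped by a
  zero-phase 1/f gain (exponent 1) above 1 Hz, then standardized and scaled
  to 10 µV SD. The same shaping filter is applied to every channel, so
  configured inter-channel correlations pass through unchanged.
* **Coupling schedule** — innovations of the temporal-cluster channels share
  a common factor with time-varying weight: pairwise correlation 0.45 before
  and 0.15 after the reference on hits, 0.30 throughout on misses. This
  produces the target multi-information pattern (hits above misses before
  the reference, below after).
* **Entropy offsets** — hit-minus-miss shifts per cluster, expressed in
  permutation-entropy units (defaults: fronto-central +0.060, the other
  clusters −0.006 to −0.009). They are realized by variance-preserving
  mixing of broadband noise into a cluster's channels. Because no closed
  form maps a mixing weight to a permutation-entropy shift, the generator
  simulates a calibration curve once per parameter set (fixed internal seed,
  120 windows per grid point, log-spaced weights — the ordinal structure of
  a smooth base responds over roughly two decades of weight) and inverts it.
  The curve's ceiling is the permutation entropy of band-limited noise after
  4× oversampling (≈0.734), which is why the baseline weight (0.033) sits
  low on the curve. Subject random intercepts are drawn directly in entropy
  units (SD 0.006) and pushed through the same inverse map.
* **ERP kernels** — Gaussian bumps (σ = 30 ms) time-locked to tone onsets,
  added on hit trials only, so the configured amplitudes are hit-minus-miss
  contrasts: negative ARN-like bumps peaking 200 ms after tone B1 at C5, F6,
  F7 (−1.193, −1.120, −1.277 µV) and positive P300-like bumps at 350 ms at
  FCz, Cz, CPz, Pz (+0.636, +0.780, +0.999, +1.003 µV). Tones sit at
  −1.45, −0.45, +0.55, +1.55 s relative to the reference (a 1 Hz stream with
  the press ~450 ms after the first detected repetition); onsets are fixed
  rather than jittered.
* **References** — hits draw a press time from N(3.45 s, 1.58 s) truncated to
  [3, 7] s on the trial clock; misses use the fixed 3.4 s reference. Epochs
  are generated directly around the reference.
* **Randomness** — one global seed; per-subject substreams are derived as
  `default_rng([seed, 1000 + subject_index])`, so subjects are independent
  and datasets reproducible bit-for-bit (hash-checked in the tests).

What the generator does *not* emulate: volume conduction and realistic
cross-cluster covariance, ocular/muscular artifacts, non-stationary rhythms
(alpha bursts), latency jitter of evoked components, and any nonlinearity of
real EEG. Passing recovery tests therefore demonstrates the correctness of
the estimators and inference chain, not their sensitivity on real data.

## Preprocessing conventions

Band-pass 1–80 Hz as a 4th-order Butterworth applied forward-backward
(zero phase; only the cutoffs are prescribed by the paradigm, the
realization is this package's choice). Resampling uses the Fourier method,
exact for the integer-second epochs used here (6 s: 1 kHz → 4 kHz for
entropy, → 125 Hz for integrated information). The electrode-to-cluster map
is reconstructed from 10/20 name prefixes (midline → sagittal S; T/FT/TP →
temporal; Fp → antero-frontal; O → parieto-occipital) and shipped as an
editable YAML asset (`imaware/data/cluster_map.yaml`); the reference
assignment exists only in graphical form, so real-data use should review
this asset.

## ERP analysis

Tone-locked epochs span −200…+500 ms with the −200…0 ms mean subtracted
(the baseline interval is this package's choice; only the span is
prescribed). B1/B2 are the nearest onsets strictly before the reference,
A1/A2 the first at or after it. "Peak" is the signed extremum within the
component window — minimum for ARN, maximum for P300 — on per-subject
condition averages (per-subject values are what the subject-level mixed
models require). The recovery test uses a delete-one-trial jackknife SE per
condition; extremum extraction on noisy averages is biased toward larger
magnitudes, which is why recovery is asserted within sampling error rather
than exactly.

## Entropy measures

All five estimators run on 1000-sample windows after oversampling to 4 kHz
(24 windows per 6-s epoch; oversampling adds no information but is retained
for fidelity to the windowing scheme). The two epoch-edge windows are
dropped by default as filter-edge guards, leaving 11 windows per side — this
resolves an internal inconsistency in the source description (24 windows
defined, 11+11 analyzed) in favor of the analyzed count; `drop_edges=False`
restores all 24.

Conventions, each switchable or parameterized:

* SpEn: Shannon entropy of the raw-periodogram distribution over rFFT bins,
  normalized by log(bin count); Welch (8 segments) switchable. Note the raw
  periodogram of white noise has iid exponential ordinates, so its expected
  normalized entropy is 1 − (1 − γ)/log(n_bins) ≈ 0.93, not 1.0 — the tests
  assert this exact level.
* ApEn: Pincus convention, self-inclusive matching, Φ_m − Φ_{m+1}, m = 2,
  r = 0.2·SD (SD-relative, hence affine-invariant).
* SaEn: Richman–Moorman convention, self-matches excluded, both template
  lengths counted over the same N − m templates; undefined (NaN + warning)
  when no matches exist. ApEn and SaEn deliberately keep their historically
  different matching conventions.
* PeEn: ordinal patterns of order 3, delay 1; ties rank by order of
  occurrence (stable argsort), so constant series give zero entropy;
  normalized by log(order!).
* SvEn: singular values of the order-3 delay-embedding matrix normalized to
  sum to one; normalized by log(order).

ApEn and SaEn share one O(N²) template-distance pass (numba-compiled when
available, with an identical pure-NumPy fallback); every estimator is tested
to 1e-10 against an independently written brute-force oracle.

## Integrated information on Gaussian models

All four measures operate on the second-order description of (past, present)
at lag τ — covariances Σ_p, Σ_t and cross-covariance — under a partition of
the channels (default atomic: each channel its own part, the natural reading
of "all interactions removed"; an exhaustive bipartition search is not
implemented because the temporal cluster is analyzed atomically throughout).

* Φ_MI is the total correlation of the joint past+present vector across
  parts (τ-dependent through each part's own past-present coupling); the
  purely instantaneous total correlation is available by evaluating the same
  formula at zero cross-covariance.
* Φ_H (stochastic interaction) is Σᵢ H(presentᵢ | pastᵢ) − H(present | past),
  with conditional entropies from Schur complements.
* Φ* is I(past; present) minus the mismatched-decoding information of the
  decoder that uses the part-wise conditional model; the Gaussian closed
  form of I*(β) is maximized over the decoding exponent β ∈ [0, 20] by
  bounded Brent search (xatol 1e-8). I*(1) equals I for an exact decoder, so
  Φ* vanishes on independent parts.
* Φ_G is the minimum KL divergence to Gaussian models whose present-on-past
  regression is block-diagonal (residual correlations free, past marginal
  shared). It is computed by alternating minimization — the optimal residual
  covariance given the regression is the actual residual covariance; the
  optimal support-restricted regression given the weights solves a linear
  system — iterated until the divergence changes by < 1e-10. The tests
  cross-check against generic multi-start numerical minimization.

Numerics: covariances are symmetrized and, when a Cholesky factorization
fails, ridged by 1e-8·trace/n escalating ×10 up to three times with a
warning; tiny negative measure values (< 1e-9 in magnitude) are clipped to
zero with a diagnostic.

Time courses use sliding windows of 110 samples with stride 10 at 125 Hz:
65 windows over the 750-sample epoch, 27 of which end at or before the
central reference. This reconstructs the paradigm's 27-before/65-total
window geometry, which is not otherwise derivable from the epoch length
alone (descriptions of the before/after split disagree — 37 vs 38 "after";
this construction yields 38, and both counts are reachable through the
window/stride configuration). Within each window the measure is computed at
each τ ∈ {1, …, 10} samples (8–80 ms; the count of lags is prescribed, their
values are not) and averaged.

## Mixed-effects inference

Feature tables are aggregated to (subject, detection, condition, cluster)
cell means and fitted by ML with `statsmodels` MixedLM (random intercept per
subject; Powell then L-BFGS — Powell handles variance components on the zero
boundary cleanly). Term F statistics are Wald tests on the fixed-effect
covariance with residual denominator degrees of freedom (n − rank(X)); at
the table sizes used here this is indistinguishable from
Satterthwaite/Kenward–Roger-style corrections, which `statsmodels` does not
provide. Estimated marginal means average model cell predictions over the
unnamed factors; hit−miss contrasts per cluster are Bonferroni-adjusted by
the family size (9). Partial η² = F·df₁/(F·df₁ + df₂). A likelihood-ratio
test of the random intercept against plain OLS (0.5·χ²₁ boundary mixture) is
reported but never used as a gate.

## Power calculation

`power_simulation` draws, per replicate, subject intercepts with variance
ICC and residuals with variance 1 − ICC (unit total), adds a two-level
within-subject effect of d total-SD units, fits the random-intercept model
by ML and tests the effect at α (Wald, two-sided). Balance makes the ML fit
closed-form (the GLS slope equals the within-subject OLS slope; variance
components separate into within/between sums of squares), which the tests
verify against `statsmodels` to numerical precision; 4 × 1000 replicates run
in seconds.

A structural observation, verifiable from the closed form: with 15 subjects
× 80 observations and an intercept-only random structure, the within-subject
contrast cancels the intercept entirely, so SE(d̂) = √(4(1 − ICC)/1200) ≤
0.048 for every ICC ≤ 0.6 and the power to detect d = 0.44 saturates near
100% regardless of the intraclass correlation. A planning figure of 84% for
this design is attainable only with an additional variance component that
the intercept-only specification does not contain — for example a
subject-by-condition random slope with SD ≈ 0.55 total-SD units, which
`power_simulation` exposes through its optional `slope_sd` argument (default
0). The acceptance computation therefore reports the honestly computed
(saturated) power of the specified design across the ICC sweep.

## Scales used in the automated checks

The recovery tests run scaled-down designs chosen as the package's own test
sizes: one electrode per cluster and 4 trials per condition for the entropy
pipeline (10 subjects), 100 trials per condition for ERP recovery (one
subject), 50 trials per condition and the 4 temporal electrodes for the
multi-information time course, and 1000 Monte-Carlo replicates per ICC for
power. The full 64-channel montage and study-scale subject counts run
through exactly the same code paths, only slower.

## Known limitations

* The entropy-offset calibration targets permutation entropy; the other four
  measures respond to the same broadband admixture with the correct sign but
  uncalibrated magnitude.
* The calibrated offset range is bounded by the oversampling ceiling
  (≈0.734 − baseline ≈ 0.65 upward, baseline − ≈0.62 downward); offsets
  outside it raise a configuration error.
* Extremum-based peak amplitudes are magnitude-biased on noisy averages
  (inherent to the convention, shared by any reimplementation).
* `anova_table` uses residual degrees of freedom; with very small designs
  (few subjects, few cells) its F tests are anticonservative.
* The EDF reader and artifact-repair hook are pass-through conveniences for
  real data; no artifact simulation or repair is implemented.
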