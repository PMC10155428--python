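# Methods

This note documents the models, numerical choices and known limitations of
synergykit, and what its synthetic study conditions do and do not establish
about real recordings.

## Session model and container

A session is one visit: a channels x samples EMG matrix at a fixed sampling
rate (default 600 Hz), an ordered event table of cued trials — 0-based,
half-open `[start, end)` sample windows, one row per movement x trial x
condition — and participant metadata.  The canonical channel order is the
ten lower-limb muscles R-IL, R-RF, R-TA, R-EHL, R-G, L-IL, L-RF, L-TA,
L-EHL, L-G (iliopsoas, rectus femoris, tibialis anterior, extensor hallucis
longus, gastrocnemius, right then left); files with shuffled channels are
re-ordered on read.  The container is an open HDF5 layout (`/emg`,
`/events`, root attributes) written with `track_times=False` so identical
records produce byte-identical files; a wide-CSV + JSON-sidecar import
covers plain-text interchange.  Proprietary acquisition formats are out of
scope.  Events mark whole trials; the flexion and extension sub-phases
inside a trial are not distinguished because tone-to-phase timing is
protocol-dependent.

## Preprocessing

* **Bandpass**: Butterworth, default 10-300 Hz, overall order 6 (three poles
  per edge).  At 600 Hz sampling the printed 300 Hz upper edge equals
  Nyquist, where a digital bandpass is degenerate; the design caps the upper
  edge at 0.99 x Nyquist (297 Hz) and this cap is configurable.  Filtering
  is forward-backward (`sosfiltfilt`) by default so envelopes are not
  delayed; a causal mode exists for streaming-like use.
* **Artifact removal**: running median, kernel 5 samples, reflect padding,
  applied only to declared artifact channels (default both iliopsoas
  channels, the ones nearest a lumbosacral stimulation electrode).  A median
  of a zero-mean broadband signal attenuates its amplitude (about 0.55x for
  the synthetic carrier); this per-channel gain change is deliberately left
  uncorrected because the later min-max normalization removes per-channel
  gain exactly.
* **RMS envelope**: non-overlapping windows, default 100 ms (60 samples);
  the trailing incomplete window is dropped.
* **Segmentation and time normalization**: the envelope is cut at the event
  windows (envelope sample i covers raw samples `[i*w, (i+1)*w)`) and each
  trial is linearly interpolated onto a uniform 7000-point grid including
  both endpoints.  Linear interpolation is the simplest scheme consistent
  with resampling variable-length trials to a common grid; it preserves
  affine signals exactly.
* **Amplitude normalization**: min-max to [0, 1].  Default scope is
  per-muscle-per-session (one min/max per muscle over all trials of the
  visit), which preserves relative amplitude across movements and
  conditions; a per-trial scope is available.  The two scopes answer
  different questions and the package treats the choice as a config
  parameter rather than deciding it; results in this package's tests use
  the session scope.
* **Ensemble averaging**: element-wise mean of the three trials of each
  movement x condition, giving the 10 x 7000 matrix used for synergy
  extraction and spinal mapping.

## Higuchi fractal dimension

For a series of N samples, delays k = 1..k_max and phases m = 1..k, the
normalized curve length is

    L_m(k) = (1/k) * [ Σ_{i=1..n_mk} |E(m+ik) − E(m+(i−1)k)| ] * (N−1)/(n_mk k),
    n_mk = int((N−m)/k),  L(k) = mean_m L_m(k),

and the dimension is the least-squares slope of ln L(k) on ln(1/k).  The
slope formulation (rather than a pointwise ratio) yields the standard
positive estimate: exactly 1 for affine series (L(k) ∝ 1/k), near 2 for
white noise, near 1.5 for ordinary Brownian motion — these limits are the
calibration checks in the test suite.  Choices:

* `k_max = 64` by default for 7000-point envelopes.  No canonical value
  exists; the slope is stable over a broad range for envelope-like signals,
  and k_max must stay below N/2.
* Delays with non-finite or zero L(k) are excluded from the fit; if fewer
  than two remain the series is reported degenerate, never imputed.
* HFD is computed per trial on the time-normalized 7000-point envelope
  (so values are comparable across trials of different raw lengths), then
  averaged over the three trials of each muscle x movement x condition.
  Interpolation to 7000 points smooths the series, compressing absolute
  HFD values toward 1; between-condition *contrasts* survive this
  compression, and those contrasts — not absolute levels — are what the
  group statistics consume.

## Spinal motor-output maps

Segment activity is the chart-weighted average
`S_j(t) = Σ_i k_ij E_i(t) / n_j` over segments L1..S1, with weights
k_ij ∈ [0, 1] and n_j the count of muscles with positive weight at segment
j.  The shipped chart is an implementation default assembled from published
Sharrard-type innervation tables for the ten recorded muscles; any CSV with
the same shape is accepted, and validation requires every muscle to load at
least one segment, every segment to receive at least one muscle, and all
weights in [0, 1].  Charts naming segments outside L1..S1 are rejected.  The
projection is linear, so mapping ensemble-averaged envelopes equals
averaging mapped trials; no temporal smoothing is applied.

## Synergy extraction

Factors are fitted by the classic multiplicative update rule for the
Frobenius objective, which preserves non-negativity and never increases the
residual (asserted per iteration in tests).  Numerical choices:

* Initialization: W, A entries uniform on (0, 1], A scaled by mean(E);
  100 restarts by default; the lowest final residual wins, ties broken by
  restart index.  Restarts are batched as stacked 3-d arrays, run a 60-iteration
  burn-in together, and the best 5% (at least one) continue until the
  relative residual improvement drops below 1e-6 or 1000 iterations.  Every
  restart is started, so the multi-start semantics are unchanged; pruning
  only abandons dominated restarts early.
* Fully zero rows or columns of E are nudged by machine-epsilon-scale
  values so the updates stay defined.
* W columns are rescaled to unit maximum with the scale absorbed into A
  (the usual scale-indeterminacy convention); factor equality is always
  assessed up to column permutation and positive rescaling.
* R² defaults to `1 − SSE/SST` with SST the centered total sum of squares
  of the data.  A literal variant that normalizes by the variance of the
  *reconstruction* is provided (`r2_definition="reconstruction_centered"`) for
  comparison; it is non-standard (can exceed 1, need not be monotone) and
  is not used by default.
* Order selection: smallest k in 1..10 with R² ≥ 0.85; if no rank crosses,
  the largest scanned rank is returned with an explicit `threshold_met =
  False` flag.  The scan is capped at the channel count.  An optional lazy
  mode stops the R² curve at the first crossing — the selected order is
  provably identical, only the curve's tail is left uncomputed — and is
  used where only the order matters.
* Extraction operates per movement x condition ensemble (the 10 x 7000
  matrix); concatenating conditions before factorization is not done, to
  keep the per-movement matrix shape the analysis elsewhere assumes.

## Cross-participant matching

The cohort template is the participant maximizing the summed
optimal-assignment cosine similarity to all others (sum aggregation; for
equal-k cohorts this equals the mean criterion), ties to the lowest index.
Assignment uses the Hungarian algorithm on the cosine matrix, which the
tests verify against exhaustive permutation search.  Sets with different
synergy counts are never padded; they are compared only after re-reading
both at a caller-supplied common rank (the stored per-rank fits make this
free).  Activation coefficients of matched synergies are compared by
mean-centered, norm-scaled correlation at lag zero, so values land in
[−1, 1].

## Group statistics

* Normality: Lilliefors variant of the Kolmogorov-Smirnov test (normal with
  estimated mean/SD), the appropriate composite form when parameters are
  fitted from the sample.
* Paired contrast (stim vs no-stim): Wilcoxon signed-rank per muscle x
  movement, paired on (participant, session).  Zero differences are
  discarded before ranking; at least five nonzero pairs are required;
  exact p for n ≤ 25 without tied magnitudes, tie-corrected normal
  approximation otherwise.
* Unpaired contrast (control vs stim): Mann-Whitney U, exact for small
  tie-free samples.
* Family-wise control: Bonferroni, threshold α/m.  The family size m
  defaults to the number of comparisons actually run and is overridable,
  because a report's family may legitimately include tests outside one
  table.  The displayed threshold rounds to one significant figure,
  downward when rounding would exceed the exact value (0.05/67 → 0.0007).
* Equivalence of R² between groups: two one-sided Welch t tests with an
  absolute margin, default 0.05 R² — no canonical margin exists for
  variance-accounted-for scales, so the default is deliberately modest and
  configurable.

Type-I calibration of the battery (rejection rate within [0.03, 0.08] at
nominal 0.05 under null simulation) and agreement of exact p-values with
brute-force enumeration are part of the test suite.

## Synthetic study conditions

The generator emulates the assessment protocol: 6 movements x 3 trials per
condition, one condition for controls (18 trials) and stim + no_stim for
patients (36 trials), 10 channels at 600 Hz.  Per-trial duration is a free
parameter (default 6 s with 2 s rest) since protocols time trials by
auditory cues, not fixed clocks.

Signal model: each channel is a unit-RMS broadband carrier amplitude-
modulated by the planted non-negative envelope `W_true A_true`, plus
additive broadband noise (`noise_sd`, as a fraction of clean-signal RMS)
and optional periodic biphasic stimulation-artifact pulses (28-44 Hz) on
the artifact channels.  The carrier is a random-phase multisine on 10-250 Hz
whose components are harmonics of 10 Hz: over any full 100 ms analysis
window its RMS is exactly constant, so the RMS envelope of the clean signal
reproduces the planted mixture and envelope-recovery tests are sharp rather
than limited by carrier statistics.  The planted basis deals the ten
muscles into near-disjoint support groups per synergy (plus a small random
background), and activations are staggered raised-cosine bursts — this
makes the factorization identifiable, which is what "planted structure" has
to mean for recovery tests to be well-posed.  A cohort can share one basis
via `basis_seed` while varying noise and amplitude jitter per participant.
The no_stim patient condition carries no planted drive at all (noise only),
emulating absent volitional EMG without stimulation.

Because min-max normalization divides each muscle by its session maximum,
any per-channel gain of the measurement chain — including the median
filter's amplitude attenuation — cancels, and the planted loadings as seen
by the pipeline are `W_true` row-divided by the planted mixture's
per-muscle maximum (`PlantedTruth.normalized_loadings`).  Recovery is
therefore assessed in normalized-envelope space.

What passing synthetic tests establish: the chain is self-consistent —
planted order and loadings survive preprocessing, normalization and
factorization at realistic noise; artifact filtering helps rather than
hurts; the statistics are calibrated.  What they do not establish: real
sEMG has nonstationary noise, motion artifacts, electrode crosstalk,
inter-trial variability of burst timing and genuinely time-varying
synergies, none of which the generator models; absolute fractal-dimension
levels on interpolated envelopes are design-dependent and only contrasts
transfer.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run at deliberately modest sizes
chosen to exercise every code path: order-recovery sweeps use 10 seeded
sessions per planted rank (k = 2, 3, 4) at 5% noise with the full
100-restart budget; calibration uses 200 null replicates per test; the
directional-effect cohort uses 12 patient sessions with 3 s trials; oracle
equivalence uses 50 random series (curve lengths) and 20 random envelopes
(spinal maps).
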