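# synergykit

Analysis of multi-channel surface EMG (sEMG) from cued lower-limb motor
assessments: muscle-synergy extraction, spinal motor-output mapping and
envelope-complexity measurement, with the nonparametric statistics used to
compare patient conditions and cohorts.  It is written for researchers
studying motor control after spinal cord injury — in particular the effect
of epidural spinal cord stimulation (eSCS) on volitional movement — but the
pipeline applies to any fixed-protocol sEMG session with trial event
markers.

Because clinical sEMG recordings are rarely shareable, the package includes
a first-class synthetic-session generator that emulates the assessment
protocol (6 voluntary movements x 3 trials per condition, 10 named
lower-limb channels at 600 Hz) with planted, recoverable synergy structure,
so every stage is testable end to end without any data download.

## The models

**Preprocessing.** Each channel is bandpass filtered (Butterworth, 10-300 Hz,
order 6, zero phase), stimulation-artifact channels are median filtered
(kernel 5), and the RMS envelope is computed over non-overlapping 100 ms
windows.  Trials are segmented by their event timestamps, time-normalized by
interpolation to 7000 points, min-max amplitude normalized, and the three
trials of each movement are ensemble averaged into a 10 x 7000 matrix `E`.

**Muscle synergies.** `E ≈ W A` with `W ≥ 0` (muscles x k loadings) and
`A ≥ 0` (k x time activations), fitted by multiplicative-update NNMF with
100 random restarts per rank.  The synergy count is the smallest k whose
variance accounted for,

    R²(k) = 1 − Σ(E − Ê_k)² / Σ(E − mean E)²,

reaches 85% over k = 1..10.  Synergies are compared across participants by
cosine similarity `R = wᵀa w_b / (‖w_a‖‖w_b‖)` with optimal one-to-one
assignment to a cohort template; activation coefficients by zero-lag
cross-correlation.

**Spinal maps.** Envelopes are projected onto lumbosacral segments L1..S1
through a myotomal chart `k_ij` (Sharrard-derived default, any CSV
accepted): `S_j(t) = Σ_i k_ij E_i(t) / n_j`, with `n_j` the number of
muscles innervated from segment j.

**Complexity.** The Higuchi fractal dimension of each trial envelope — the
slope of `ln L(k)` against `ln(1/k)` over the normalized curve-length family
`L(k)` — quantifies envelope roughness: smooth volitional bursts near 1,
noise-like activity near 2.

**Statistics.** Lilliefors (Kolmogorov-Smirnov) normality check, paired
Wilcoxon signed-rank (stim vs no-stim), Mann-Whitney U (control vs patient),
Bonferroni family-wise correction (0.05 over 67 tests displays as 0.0007),
and a TOST equivalence test on R² values.

## Worked example

`examples/04_synergy_extraction.py` (abridged) plants a known 3-synergy
structure, runs the full chain and checks what comes back:

```python
import synergykit as sk
from synergykit.matching import match_and_reorder
from synergykit.synergy import extract_synergies

gen = sk.GeneratorConfig(n_synergies=3, noise_sd=0.05, seed=11)
record, truth = sk.synthesize_session(gen, group="control")
prep = sk.preprocess_session(record, sk.PipelineConfig())
syn = extract_synergies(prep.ensembles[0], sk.PipelineConfig(), seed=1,
                        lazy_curve=True)
perm, sims = match_and_reorder(syn.W, truth.normalized_loadings())
```

Running the script prints

```
movement BL-Hip: selected k = 3 (threshold met: True)
R^2 curve: [0.2574 0.664  0.9996]
matched cosine similarity per planted synergy: [1.     1.     0.9999]
```

— the R² curve crosses
the 85% threshold exactly at the planted rank 3, and each recovered loading
column matches its planted counterpart with cosine similarity ≈ 1.  The
other scripts in `examples/` walk through session simulation and I/O,
preprocessing and complexity tables, spinal maps, and cohort matching plus
the statistical battery.  A thin CLI mirrors the library
(`synergykit run|simulate|preprocess|hfd|spinalmap|synergy|match|stats`).

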