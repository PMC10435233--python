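# Methods

This note records the models, conventions, parameter choices and known
limitations behind `optophysio`. It describes what the code computes; every
empirical number quoted here is produced by the test suite or by
`scripts/acceptance.py`.

## Photostate model

Bistable opsins photoconvert between a stable dark state and an active
photoproduct; the photoproduct can be driven back by light of another
wavelength (photoreversal) and also decays light-independently
(adaptation). The active fraction is modelled by the linear two-state ODE

    da/dt = α(t) (1 − a) − β(t) a,
    α = k_act σ_act(λ) I,    β = k_rev σ_rev(λ) I + k_adapt

with all rates ≥ 0 and spectral efficiencies σ(λ) ∈ [0,1]. Because light
schedules are piecewise constant, the integrator advances the exact
exponential solution segment by segment (sample intervals straddling a
segment boundary are split at the boundary), so it is exact up to rounding:
the acceptance script measures < 1e-13 maximum relative error against the
closed form, far inside the 1e-6 design requirement. Boundedness a ∈ [0,1]
holds analytically and is asserted on randomized schedules in a property
test.

Spectral efficiencies are Gaussian bumps with configurable centre/width.
No quantitative kinetic constants exist for these pigments in vivo, so the
three presets are qualitative design choices with two anchors: (i) the
centres sit at the stimulation wavelengths used for each pigment (520 nm
mosquito Opn3, 470 nm pufferfish TMT, 405 nm lamprey parapinopsin, with the
parapinopsin reversal band at 470–520 nm); (ii) magnitudes were tuned once
so that the default heart scenario (1 s, 0.5 mW/mm² pulse at the peak
wavelength) yields an emergent arrest latency distribution centred near
0.8 s and resumption near 9 s — the values reported for the mosquito-Opn3
cardiac assay — and then frozen. Adaptation is ordered
k_adapt(mosOpn3) < k_adapt(others), matching the observation that mosquito
Opn3 holds its active state longest under prolonged light. One knowingly
unreproduced detail: the published parapinopsin pulse-dark resumption
(12.1 s) exceeds the mosquito-Opn3 value, which a faster-adapting preset
cannot produce; the ordering constraint was kept instead.

## Heart simulation

Beats come from a phase accumulator over an instantaneous rate
r(t) = r₀ · g(a), r₀ = 150 bpm. The gate is

    g(a) = 1 − (min(a, θ)/θ)^p,   g = 0 for a ≥ θ

with arrest threshold θ = 0.5 and sharpness p = 4. A purely linear gate
(p = 1) slows beats so early during the pulse that the missed-beat rule
fires ~0.45 s after stimulus onset — arrest would look far more gradual
than the observed "arrest within about one second"; p = 4 keeps the rate
near baseline until the threshold is approached. Suppression is applied
instantly; recovery of the realized rate toward the gated target is
first-order with τ = 2 s, giving the observed gradual return of beating
without claiming a mechanism. Each beat renders as a raised-cosine
luminosity pulse (120 ms width, amplitude 1 AU); the ventricular pulse
train is the atrial train shifted by the AV delay (80 ms default). Sampling
is 67 frames/s (the assay camera's rate; configurable), noise is additive
Gaussian per sample, and the per-trial seed is recorded in the ground
truth.

Ground-truth arrest metrics are derived from the *exact* planted beat times
by the same missed-expected-beat rule the detector applies to *detected*
beats (first post-stimulus inter-beat gap > 2× baseline IBI; onset = last
beat + one IBI). Recovery error therefore isolates trace-level detection:
with the default detector it is ≤ 1 ms noiseless and ≤ 10 ms at noise of
10% of the beat amplitude (acceptance script, 100 seeds each), against
design bounds of one frame (14.9 ms) and 50 ms.

## Beat detection

`detect_beats` smooths the trace with a 75 ms boxcar, detrends with a 1 s
rolling median, and runs peak picking with a minimum inter-beat interval of
0.25 s and a floor on *both* height and prominence of 5 robust sigmas
(1.4826 × MAD of the detrended trace, with a dynamic-range fallback when
the MAD is exactly zero on noiseless pulse trains). The joint
height-and-prominence floor is what keeps long beat-free arrest stretches
free of spurious noise peaks; prominence alone admits rare noise excursions
over a multi-second gap. Peak times are refined to sub-frame resolution by
a three-point parabolic fit, which is why noiseless beat times recover to
~0.01 frames. These defaults were fixed by analysing the generator's
noiseless and 10%-noise regimes during detector design.

## Relative heartbeat frequency

Raw frequency at time t is the beat count in the closed window [t−h, t+h]
divided by 2h; a boundary beat counts once. The trace is normalized by the
mean raw frequency over a pre-stimulus baseline window, so the baseline
averages to 1 by construction and quantization is ±1/(2h) beats. The
half-width default is h = 0.5 s; the assay description also mentions a 1 s
reading in one figure legend, so h is a parameter rather than a constant.
Windows extending beyond the record yield NaN.

## AV conduction delay

Each atrial peak is matched to the earliest ventricular peak strictly after
it and before the next atrial peak — one-to-one and non-crossing by
construction; unmatched atrial peaks are dropped, and matched pairs with
delay > 0.5 s are excluded and counted (`n_excluded`), mirroring the
assay's exclusion rule. The retained-delay invariant (0, 0.5] is enforced
by the result type itself.

## Calcium traces

Fluorescence is baseline + per-beat exponential transients (peak equal to
the coupling constant, 250 ms decay) − an arrest-coupled dip proportional
to the instantaneous suppression level, clipped strictly positive. ΔF/F is
(F − F0)/F0 under three baseline conventions: sample at stimulation onset,
pre-stimulus window mean (2 s default), or a user-marked post-resumption
steady-state window. The assay descriptions say "dividing by" the baseline
intensity, but the plotted traces are zero-centred, so the subtractive
ΔF/F convention is used and recorded in the output metadata.

## Frame rendering and extraction

`render_heart_frames` draws two non-overlapping ellipse chambers whose
interior intensity is an affine map of the input traces; ROI means
therefore reproduce the traces up to affine scaling (round-trip correlation
> 0.99 is tested, and in practice ≈ 1). Optional per-frame area modulation
scales the semi-axes by √ratio for heart-area tests. `measure_heart_area`
smooths temporally (3 frames), applies a global Otsu threshold computed on
the frame nearest the arrest onset, and counts the largest connected
component, normalized to the area at arrest onset — an automatic surrogate
for the assay's manual outlining, required for testability. ROI means are
computed on raw frames (no background subtraction).

## Locomotion

Input is pre-tracked lateral displacement normalized by body length; video
tracking is out of scope. The bout envelope is a 150 ms rolling maximum so
individual tail beats (~20 Hz) do not fragment bouts; the threshold default
is 0.05 body lengths and sub-threshold gaps shorter than 100 ms merge.
Because the envelope widens intervals by half a window and the oscillation
ramps from zero, bout edges are refined to the first/last raw crossing of
half the threshold; median latency recovery error on the synthetic cohort
is ≈ 1.1–1.2 frames (bound: 2). Trial classification follows the assay
rules exactly: induced within 8 s, pre-stimulus movement excluded from
rates, inhibition when an ongoing bout ends within 1 s of opsin
stimulation.

The synthetic locomotion cohort plants per-trial bouts with induced
probability 0.89, latency 3.2 ± 1.1 s, duration 4.4 ± 2.0 s and strength
0.30 ± 0.08 body lengths — the strongly responsive Gq-rhodopsin regime —
plus a 5% chance of a pre-stimulus bout.

## Statistics

Group summaries are mean ± SEM (sd/√n) over per-larva values. The rank-sum
test uses the exact null distribution for combined n ≤ 20 without ties
(verified against full labeling enumeration for all size combinations with
combined n ≤ 10) and the tie-corrected normal approximation otherwise;
fully degenerate input (all pooled values equal) returns p = 1 by symmetry.
One-way ANOVA + Tukey HSD come from scipy; for two groups the Tukey p
equals the pooled-variance t-test p (q = √2·t), which is tested. All tests
are two-sided. Trial-1 vs trial-6 effects are paired per larva and tested
with the Wilcoxon signed-rank test (p = 1 when all differences vanish).
Linear mixed-effects analyses are deliberately not implemented; the
pipeline emits tidy per-trial tables suitable for external fitting.

## What the generator does and does not emulate

It reproduces: beat-locked luminosity oscillation, abrupt arrest with
graded recovery, fixed AV lag, wavelength-dependent switching (including
the violet-on/blue-off contrast between a parapinopsin-like and an
Opn3-like regime), beat-coupled calcium transients with arrest dips, and
discrete tail bouts on a noise floor. It does not emulate: photon/camera
noise statistics (noise is additive Gaussian), optical blur, heart or body
motion other than the rendered pulsation, biophysics of the
GIRK-channel pathway (suppression is phenomenological), swim-kinematics
substructure, or manual-scoring variability. Passing parameter-recovery
tests therefore demonstrates correctness of the analysis rules and
detectors under these idealized conditions, not robustness to every
artifact of real video.

## Problem sizes and numerical choices

Default analyses run on 25–50 s records at 67 fps (≈1700–3400 samples);
cohorts are 4 larvae × 6 trials per regime and recovery sweeps use 100
seeds, sizes chosen so the whole suite and the acceptance script each
complete in seconds on one CPU while keeping every rule exercised at the
assay's own trial structure. Degenerate inputs are handled explicitly:
flat traces yield empty beat series (not errors), empty ROIs, non-positive
baselines, overlapping bouts or chambers, zero segmented area, unknown
config keys and non-uniform sampling are rejected with messages. Tie-break
conventions: a beat on a counting-window boundary counts once; AV matching
prefers the earlier ventricular peak; bout merging precedes edge
refinement. All randomness flows from explicit integer seeds
(numpy `default_rng` / `SeedSequence`), and rerunning the pipeline with the
same resolved configuration is byte-identical.
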