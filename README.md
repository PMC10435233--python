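# optophysio

Quantification pipeline for optogenetic physiology assays in larval
zebrafish: video-derived heartbeat and cardiac-arrest analysis,
atrio-ventricular (AV) conduction delay, ΔF/F calcium-trace analysis, and
trial-structured tail-bout locomotion metrics — together with a synthetic
data generator driven by a bistable-opsin photostate model, so that every
analysis stage can be validated by parameter recovery without any raw video.

## Who this is for

Groups using G-protein-coupled bistable rhodopsins (e.g. mosquito Opn3,
pufferfish TMT-opsin, lamprey parapinopsin) or channelrhodopsins to control
cardiomyocytes or reticulospinal neurons in zebrafish larvae, and who need a
reproducible, scriptable replacement for manual video scoring: ROI
luminosity → beat times → arrest metrics, and tail displacement → bouts →
locomotion rates, with the study's statistics (Wilcoxon rank-sum, one-way
ANOVA + Tukey HSD) on tidy per-trial tables.

## The models at the core

**Photostate.** A bistable pigment shuttles between a dark (inactive) state
and an active photoproduct. The active fraction *a(t)* obeys the linear
two-state ODE

    da/dt = k_act σ_act(λ) I (1 − a) − [k_rev σ_rev(λ) I + k_adapt] a

with wavelength-dependent activation and photoreversal efficiencies σ(λ)
(Gaussian bumps in [0,1]), irradiance *I* (mW/mm²), and a light-independent
adaptation decay k_adapt. The integrator advances the exact exponential
solution per piecewise-constant light segment, so it matches the closed form
to machine precision.

**Heart.** Beats are a phase accumulator over an instantaneous rate gated by
*a(t)*: fully suppressed above an arrest threshold, scaled by
1 − (a/θ)⁴ below it, relaxing back to the 150 bpm baseline with a
first-order time constant after the active fraction decays. Each beat is a
raised-cosine luminosity pulse; the ventricular train lags the atrial train
by the AV delay (80 ms default). Arrest metrics follow a
missed-expected-beat rule: arrest onset = last beat before the first
inter-beat gap > 2× the baseline IBI, plus one IBI; latency is onset minus
stimulus onset; resumption is the next beat minus onset. AV delay matches
each atrial peak to the earliest subsequent ventricular peak, discarding
pairs with delay > 0.5 s.

**Locomotion.** Bouts are maximal intervals where the rolling-maximum
envelope of |tail displacement| (body-length units) exceeds a threshold. A
trial is *induced* if the first post-stimulus bout starts within 8 s;
latency, duration and strength (peak displacement) come from that bout;
trials moving before the stimulus are excluded from rates.

## Worked example

```python
import numpy as np
from optophysio import (HeartSimParams, opsin_presets, pulse_schedule,
                        simulate_photostate, simulate_heart_trial,
                        detect_beats, detect_arrest, av_delay)

schedule = pulse_schedule("mosopn3", onset_s=5.0)   # 1 s, 520 nm, 0.5 mW/mm2
pigment = opsin_presets()["mosopn3"]
a = simulate_photostate(pigment, schedule, duration_s=30.0, dt_s=1/67)

heart = HeartSimParams(noise_sd=0.1)                # 10% of beat amplitude
atrium, ventricle, truth = simulate_heart_trial(heart, a, 30.0, seed=8,
                                                stim_onset_s=5.0)

beats = detect_beats(atrium)
arrest = detect_arrest(beats, schedule)
av = av_delay(beats, detect_beats(ventricle))

print(f"beats detected           : {len(beats)} (planted {len(truth.beat_times_s)})")
print(f"latency to arrest        : {arrest.latency_to_arrest_s:.3f} s "
      f"(planted {truth.latency_to_arrest_s:.3f} s)")
print(f"time to resumption       : {arrest.time_to_resumption_s:.3f} s "
      f"(planted {truth.time_to_resumption_s:.3f} s)")
print(f"AV delay (mean, retained): {1e3*np.mean(av.delays_s):.1f} ms "
      f"(planted 80.0 ms, {len(av)} pairs, {av.n_excluded} excluded)")
```

prints

```
beats detected           : 38 (planted 38)
latency to arrest        : 0.915 s (planted 0.910 s)
time to resumption       : 9.460 s (planted 9.465 s)
AV delay (mean, retained): 80.1 ms (planted 80.0 ms, 38 pairs, 0 excluded)
```

The simulated larva stops beating ~0.9 s after the green pulse and resumes
~9.5 s later; the detector recovers both times to within a few milliseconds
from the noisy luminosity trace alone, and every retained atrio-ventricular
pair sits at the planted 80 ms conduction delay.

The same machinery is available from the shell:

```sh
optophysio simulate heart --opsin mosopn3 --seed 8 --out trial.csv
optophysio cardiac arrest --trace trial.atrium.csv --stim-onset 5.0
optophysio run --config config.yaml --out results/
```

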