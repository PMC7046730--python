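# vasrf

Virtual auditory space (VAS) stimulus synthesis and spatial receptive-field
analysis for auditory midbrain recordings.

## The problem

An animal cannot sense sound direction directly; it computes it from three
acoustic cues created by the head and pinnae: interaural time differences
(ITDs), interaural level differences (ILDs), and direction-dependent
spectral filtering (spectral cues). In a small-headed animal like the
mouse the ITD is at most ~29 µs and plays no role, so the interesting
question is how ILDs and spectral cues together produce the map of
azimuthal auditory space found in the superior colliculus (SC).

`vasrf` implements the full computational chain used to answer that
question with earphone experiments:

* **HRTF handling** — complementary Golay-code impulse-response
  reconstruction, an HRIR grid container, and extraction of the three cues
  (`vasrf.hrtf`);
* **stimulus synthesis** — HRIR-filtered 100-ms noise bursts, the
  cue-frozen variants (zero ITD, zero mean ILD, flat spectrum), monaural
  and extended-ILD sets (±40 dB in 2-dB steps), and binaural dynamic
  random chords (48 tones, 5–80 kHz, 12/octave) (`vasrf.stimuli`);
* **spike statistics** — 5–20 ms window counts and quasi-Poisson
  (overdispersed) response significance (`vasrf.spikes`);
* **receptive-field fitting** — a Kent-distribution rate model fitted by
  maximum quasi-likelihood with BIC model selection (`vasrf.kent`);
* **topography** — χ² line fits of RF azimuth against anatomical position
  with statistical ⊕ systematic (±19°) errors (`vasrf.topography`);
* **cue similarity** — cosine similarity indices (SI/NSI) quantifying how
  much an RF depends on each frozen cue, and ILD tuning-curve
  classification (`vasrf.similarity`);
* **STRFs** — binaural spike-triggered averages of random chords with
  Bonferroni-corrected binomial significance and the binaural similarity
  index (`vasrf.strf`);
* **synthetic data** — parametric mouse-like HRTFs and simulated
  overdispersed neurons with known ground truth, so the whole chain can be
  validated without recordings (`vasrf.synth`).

## The model at the core

The spatial RF of a neuron is a Kent (Fisher–Bingham) distribution on the
sphere,

    f(x) = exp(−κ) · exp{ κ γ₁·x + β[(γ₂·x)² − (γ₃·x)²] },

normalized to 1 at the center γ₁, with concentration κ (RF size, radius
ρ = arccos(1 − 1/2κ)), ellipticity β (fit-restricted to 4β < κ) and an
orthonormal axis triple γ₁, γ₂, γ₃. Spike counts follow an overdispersed
rate model

    μ(direction) = b + A · f(direction),     Var[N] = φ · E[N],

whose quasi-likelihood (negative binomial moment-matched to φ, exactly
Poisson at φ = 1) is maximized over all parameters; the RF is significant
when this model beats a flat rate by BIC. Map structure is then a weighted
line fit of fitted RF azimuths against anteroposterior position.

## Worked example

```python
import numpy as np
from vasrf import (SyntheticHrtfSpec, make_synthetic_hrtf, fit_kent,
                   fit_topographic_map)
from vasrf.synth import make_population, simulate_kent_responses

spec = SyntheticHrtfSpec()                 # mouse-like parametric HRTF
grid = make_synthetic_hrtf(spec)           # 17 azimuths x 5 elevations
neurons = make_population(20, map_slope_deg_mm=58.0, jitter_deg=19.0,
                          phi=5.0, seed=1, hrtf_spec=spec)
counts = simulate_kent_responses(neurons, grid.directions, n_trials=30,
                                 seed=2, frame=grid.frame)

fit = fit_kent(counts[0], grid.directions, phi=5.0, frame=grid.frame)
print(fit.summary())

fits = [fit_kent(counts[i], grid.directions, phi=5.0, frame=grid.frame)
        for i in range(len(neurons))]
keep = [i for i, f in enumerate(fits) if f.significant and f.elevation < 30]
res = fit_topographic_map([neurons[i].ap_position_mm for i in keep],
                          [fits[i].azimuth for i in keep],
                          [fits[i].azimuth_error for i in keep])
print(res.summary())
```

The first `summary()` prints the single-neuron fit, e.g.

```
Kent receptive-field fit (top-z frame)
==============================================
observations                2550
overdispersion phi         5.000
log quasi-likelihood    -1674.40
BIC (Kent / flat)         3403.7 / 3669.2
significant RF              True
----------------------------------------------
parameter       estimate     std err
azimuth           71.961       4.657
elevation          6.111       9.259
psi              -28.545      14.915
kappa              2.735       0.579
beta               0.647       0.274
baseline           0.079       0.026
amplitude          1.608       0.165
radius (deg)       35.20
```

— this neuron's RF sits at ~72° azimuth with a ~35° radius, and the Kent
model beats the flat model by ~265 BIC points. The population `summary()`
then reports the recovered map:

```
Topographic map fit (weighted least squares)
==============================================
points                          20
slope (deg/mm)                70.7 +- 9.1
offset (deg)                   2.5 +- 8.7
chi2 / dof                    1.55
Pearson r                     0.83
systematic error (deg)        19.0
```

— a small 20-neuron sample recovers the configured 58°/mm slope within
1.4 of its reported error; with the 100-neuron population used by
`scripts/acceptance.py` the slope error shrinks to ~4°/mm and χ²/dof
settles near 1 once the ±19° systematic scatter enters the χ² weights.

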