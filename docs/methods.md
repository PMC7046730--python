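# Methods

This note documents the models, conventions and numerical choices behind
`vasrf`, and what its synthetic validation does and does not establish.

## Coordinate frames

Two spherical frames share the Cartesian axes X = rostral, Y = left,
Z = dorsal, with azimuth positive toward the contralateral (right) side
and elevation 0° on the horizontal plane:

* **front-Z** (polar axis rostral) — the frame of HRIR measurement and
  stimulus grids. The azimuth is the signed angle from straight ahead and
  the elevation rotates the direction about the rostral axis.
* **top-Z** (polar axis dorsal) — the frame of RF fitting and reporting.
  Front-Z has an azimuth discontinuity across the vertical midline plane,
  which destabilizes fits to frontal RFs; top-Z moves the singularity to
  the poles. On the horizontal plane the two azimuths coincide, so map
  analyses restrict to fitted elevations < 30° where the frames are
  nearly interchangeable.

Conversions go through the unit vector and are exact; each frame's pole
has one undefined angle, canonicalized to 0.

## Impulse responses and cues

HRIRs are measured (or synthesized) per direction and ear. Golay
complementary pairs of order m (length 2^m) probe a system; summing the
cross-correlations of the two responses with their codes and dividing by
2·2^m returns the impulse response exactly for any system shorter than
the code.

Cue conventions, fixed once:

* **ITD** — right-minus-left time of the `argmax |h(t)|` sample, no
  sub-sample interpolation (2 µs resolution at 500 kHz against a ~29 µs
  physiological maximum); ties break to the earliest sample.
* **ILD** — right-minus-left of the dB-domain mean magnitude spectrum
  over FFT bins inside 5–80 kHz. dB-domain averaging was chosen because
  ILDs are reported in dB and the choice makes the broadband ILD
  scale-equivariant; linear-amplitude averaging would differ by a few
  tenths of a dB for the spectra involved.
* **Spectra** — magnitude spectra use an FFT length equal to the next
  power of two ≥ the IR length, *not* oversampled: with the FFT length
  equal to the (power-of-two) IR length, a circular delay changes no
  magnitude bin, which the ITD-freezing operation relies on (see below).
  dB values are floored at −240 dB.

## Stimuli and cue freezing

VAS stimuli are 100-ms white-noise bursts with 5-ms linear tapers,
band-limited to 5–80 kHz, filtered per ear by the direction's HRIR
including phase. Noise is regenerated per direction and trial from a
seed derived as `(master_seed, direction_index, trial_index)`, so no
pattern is frozen yet every run is reproducible.

Freezing fixes one cue at a reference value for all directions while the
others vary naturally — the frozen cue is still present, it is just
uninformative about direction:

* **frozen ITD** — the left IR is circularly shifted so its peak time
  matches the right ear's. A circular shift preserves every magnitude
  bin bit-exactly (hence ILDs and spectral cues), which a zero-padded
  linear shift would not.
* **frozen ILD** — each ear is rescaled by one scalar per direction so
  both band-average levels equal their mean; shapes and timing untouched.
* **frozen spectrum** — each IR becomes a single-sample impulse at its
  original peak position with amplitude set to the ear's band-average
  level, preserving ITD exactly and broadband ILD to numerical precision.
* **monaural** — the ipsilateral (left) channel is silenced. The
  broadband ILD is then reported at +40 dB, the ceiling of the
  extended-ILD stimulus set, rather than +∞; any monotone saturating ILD
  readout is indifferent to the choice of cap.

The extended-ILD set spans −40…+40 dB in 2-dB steps (41 levels, 30
repeats each, order shuffled by seed), imposed as ±ILD/2 around a fixed
reference amplitude. Stimulus levels throughout are in arbitrary
full-scale units; absolute SPL calibration is hardware-specific and out
of scope.

Dynamic random chords use 48 tones at 5·2^(k/12) kHz, k = 0…47 (12 per
octave starting at 5 kHz, top tone ≈ 75.5 kHz — the nominal "5–80 kHz"
bracket names the band, not the last tone). Patterns last 10 ms with
3-ms tapers; each tone is ON with probability 0.5, ears independent; a
2-minute presentation is 12,000 patterns, and repeats reuse the identical
pattern set.

## Spike statistics

Analysis counts come from the half-open 5–20 ms post-onset window (the
fast response component; slow responders are out of scope). Counts are
overdispersed: Var = φ·mean with φ estimated as sample-variance/mean
(φ ≈ 5 is typical; φ = 1 is Poisson). "Quasi-Poisson" fixes only these
two moments, so tail probabilities and likelihoods need a concrete
distribution: we use the negative binomial moment-matched to
(mean, φ·mean), which reduces to the exact Poisson at φ → 1; the choice
between overdispersed count families has negligible effect at these
means. Response significance compares the neuron's total evoked count
with the baseline expectation scaled from a pre-stimulus window of the
same trials (upper tail, α = 0.001; φ < 1 estimates are clamped to 1).
Fractions of neurons in a category carry binomial errors
√(p(1−p)/N).

## Kent receptive-field model

The RF shape is the Kent density normalized to 1 at its center (see the
README for the formula), chosen over a planar Gaussian because RFs span a
large solid angle; at large κ the two agree (within 1% inside one radius
for κ ≥ 50). The rate model is μ(dir) = b + A·f(dir) with b, A ≥ 0 fitted
jointly (the data cannot separate a baseline from a very broad Kent
component, which the BIC comparison absorbs). The radius is
ρ = arccos(1 − 1/2κ), the angle where the density falls to e^(−1/2) — the
spherical analogue of one Gaussian σ; κ ≤ 0.5 pegs ρ at 90° and is
flagged.

Fitting maximizes the negative-binomial quasi-likelihood with the
plug-in φ shared with the significance tests. Parameterization for the
optimizer: center azimuth ∈ [−144°, 144°] and elevation ∈ [0°, 90°]
(bounds), orientation ψ ∈ [−90°, 90°], κ = exp(u), and
β = (κ/4)·logistic(v) which enforces the stability restriction 4β < κ
smoothly. Multi-start L-BFGS-B: the three highest-mean directions seed
the center (ties broken by the lowest direction index) crossed with two
initial concentrations (κ₀ ∈ {3, 15}); the best optimum wins, and a run
where no start produces a finite optimum is flagged failed and excluded
upstream. Parameter errors are square roots of the diagonal of the
pseudo-inverse of a central-difference Hessian of the negative
log-likelihood at the optimum (pseudo-inverse because β often sits at
its boundary). BIC uses −2·logL + k·ln(n) with n = direction×trial
observations, k = 7 for the Kent rate model and k = 1 for the flat
(single-rate) alternative; the RF is significant when BIC(Kent) <
BIC(flat).

## Topography

RF azimuth (top-Z) is regressed on anteroposterior position by weighted
least squares with per-point error √(stat² + sys²); sys = 19° is the
quadrature combination of eye-position (±3°), pinna-movement (±13°) and
across-animal HRTF (±14°) uncertainties. The fit reports slope, offset,
their errors from the normal equations, χ²/dof and the (unweighted)
Pearson r. Omitting the systematic term on realistically jittered data
inflates χ²/dof by more than an order of magnitude — the diagnostic that
motivates it. Anatomical registration across recordings uses the visual
map of the overlying layers: a line through (shank position, visual RF
azimuth) defines the origin at its zero crossing, and neurons at negative
positions are excluded.

## Similarity indices

A direction-response vector is mean-subtracted, then unit-normalized (in
that order), and the SI is the inner product of two such vectors. The
control SI (two interleaved presentations of the same stimulus) measures
reproducibility; neurons pass at one-sided p < 0.01 of SI > 0. NSI loss
is 1 − SI_cue/SI_control. SI errors propagate per-direction Poisson count
errors to first order (delta method); a trial-resampling bootstrap
cross-check agrees within ~30% at the trial counts used. ILD response
curves over the 41 extended-ILD levels are classified flat / monotonic /
peaked: a quasi-Poisson χ² against the grand mean (dof = 40, α = 0.01)
separates flat from tuned; a tuned neuron is "peaked" only when some
interior level significantly exceeds *both* ±40 dB endpoints after
Bonferroni correction over the 39 tested levels.

## STRFs

The STA assigns to each (ear, frequency, lag) the count-weighted mean of
the pattern values at 1…10 patterns before the spike bin, minus the
per-ear, per-frequency realized stimulus mean M (≈ 0.5 up to sampling
fluctuation). Lag 0 is excluded: a response within the pattern's own
10-ms bin cannot be driven by that pattern's onset at this
discretization. Bins with several spikes weight their history by the
count. Significance is the two-sided binomial test of S·N successes in N
trials at probability M, Bonferroni-corrected over all 960 pixels
(10 lags × 48 frequencies × 2 ears) at family α = 0.001; neurons with
fewer than 20 spikes are excluded. The BSI is the cosine similarity of
the two ears' STA blocks; population maps report the per-pixel fraction
of significant positive (negative) structure by RF-azimuth group
(frontal < 35°, lateral ≥ 35°; the 35° split balances group sizes,
whereas NSI summaries split at 45°).

## Synthetic data: what it emulates

The parametric HRTF reproduces the three cue structures: a spherical
path-difference ITD (ear separation 1 cm, c = 343 m/s, max ≈ 29 µs); a
broadband ILD that is odd in azimuth, peaks at 65° with a 30 dB maximum
and scales with cos(elevation) (sine of a rescaled azimuth, clipped so
the ILD stays positive over the whole contralateral hemifield — the
simplest smooth form with the right peak); and spectral cues built from
the frontal band template (amplified 10–24 and 48–60 kHz, attenuated
25–45 and 63–76 kHz, 20 dB peak-to-trough) that cross-fades into a
spectral comb whose phase rotates 1.2° per azimuth degree (so the ±144°
range spans under one period and no two azimuths share a spectrum) and
whose period stretches with elevation. IRs are synthesized in the
frequency domain with linear phase carrying the interaural delay; the
spectral-shape component is band-mean-removed so it cannot leak into the
broadband ILD.

Simulated neurons implement the two-channel model of azimuthal tuning:
expected count = (baseline + gain·[w_spec·spec_drive +
w_ild·σ(ILD)])·window, where spec_drive is the rectified Pearson
correlation between the contralateral ear-input spectrum (1/12-octave
channels) and the neuron's preferred template — taken from the synthetic
HRTF at its preferred direction — and σ is a monotonic ILD sigmoid
(threshold 5 dB, slope 5 dB). The RF thus *arises from* the cues:
flattening the spectrum silences the spectral channel, silencing one ear
saturates the ILD channel, and doing both flattens the response. Drives
combine additively (the simplest composition consistent with a
weighted-input model; the data constrain only the weights' azimuth
dependence, not the composition rule). Counts are negative-binomial with
variance φ·mean — a proper integer distribution matching the
quasi-Poisson moments. Populations cross-fade w_spec → w_ild with
|azimuth| (midpoint 45°, ±15° width), place RF azimuths on a
58°/mm map with 14° offset and 19° Gaussian jitter, and let the RF
radius grow with azimuth (ρ ≈ 22° + 0.21·|az|).

A separate direct Kent-rate simulator draws counts from
(b + A·Kent(dir))·window and is the ground truth for fitter validation
and map recovery: there the fitted quantity and the simulated quantity
coincide by construction, which is what a parameter-recovery study needs.

**What passing tests show — and don't.** Synthetic validation
establishes that the estimators are consistent and calibrated under the
stated noise model (overdispersed counts, 19° map jitter) and that the
qualitative cue-freezing fingerprint (spectral loss frontal, ILD loss
lateral, combined loss complete, ITD loss nil) follows from the
two-channel architecture. It does not certify behaviour under real-data
pathologies the generator omits: non-stationary firing (locomotion,
adaptation), spike-sorting contamination, correlated noise across
directions, latency heterogeneity, or HRTFs whose cue structure differs
from the parametric form. Real-data headline numbers (NSI-loss bar
heights, BSI–azimuth slope, the visual/auditory slope ratio) depend on
the recorded population and are deliberately not asserted.

## Problem sizes and tolerances

Validation runs use sizes chosen to make Monte-Carlo assertions stable at
desk scale: 100 neurons × 85 directions × 30 trials for map recovery
(slope asserted within 2 combined σ; χ²/dof within [0.5, 1.5]), 40
neurons × 20 trials for the cue-freezing structure (sign assertions
only), 10⁴–10⁶ draws for tail-probability and moment checks (4σ
Monte-Carlo bands), and half-minute chord segments for STRF checks.
Numerical tolerances: exact identities at machine precision; dB-level
invariants at 10⁻⁹ to 10⁻⁶ where the operation is exact by construction;
stochastic checks at explicit σ-scaled bands. Degenerate inputs
(all-zero IRs, zero-variance response vectors, zero-mean counts,
constant visual azimuths) raise rather than return sentinels, except the
monaural ILD cap documented above.

## Known limitations

* The spectral-template drive makes frontal RF size emergent rather than
  directly set by κ; two transitional (azimuth ≈ 36°, elevated) template
  placements correlate with a nearby frontal direction, a benign
  ambiguity akin to real spectral-cue confusions.
* ITD peak detection at integer samples quantizes the maximal ITD to the
  2-µs grid (28 µs measured against the 29.2 µs model bound).
* The Kent fit reports Hessian errors; profile-likelihood intervals
  would be more faithful for κ near its lower bound but cost far more.
* `estimate_ap_positions` assumes a single linear visual map per probe;
  curved penetrations violate this silently.
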