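"""Parametric HRTFs and simulated spiking populations with known ground truth.

This module is the package's test bed: it generates (i) a synthetic HRIR
grid whose three localization cues follow simple parametric laws, and
(ii) simulated neurons whose responses are driven by those cues, so every
downstream stage (response statistics, Kent RF fitting, cue-freezing
similarity, STRF estimation, topography) can be validated against a known
answer without any recorded data.

Synthetic HRTF
--------------
* ITD: spherical path-difference model, ``-(d/c) sin(az) cos(el)`` with
  ear separation d = 1 cm and c = 343 m/s, giving at most ~29 us.
* broadband ILD: a smooth odd function of azimuth peaking at 65 deg
  (where a mouse's ILD is maximal), scaled by cos(elevation).
* spectral cues: for frontal directions the contralateral ear carries a
  band template -- amplified 10-24 and 48-60 kHz, attenuated 25-45 and
  63-76 kHz -- that cross-fades into a direction-dependent spectral comb
  away from the front, so the monaural spectrum identifies direction.
  The left ear is the mirror image (az -> -az) of the right.

Simulated neurons
-----------------
A neuron's expected count in the analysis window is

    lambda(dir) = (baseline + gain * [w_spec * spec_drive(dir)
                                      + w_ild * sigmoid(ILD(dir))]) * T,

where ``spec_drive`` is the rectified Pearson correlation between the
contralateral ear-input spectrum and the neuron's preferred spectral
template (taken from the synthetic HRTF at the neuron's preferred
direction), and the ILD sigmoid is a monotonic threshold curve -- the two
inputs of the weighted two-channel model of azimuthal tuning.  The RF
therefore *arises from* the cues: freezing the stimulus spectrum silences
the spectral channel, silencing one ear saturates the ILD channel, and
doing both flattens the response entirely.  Counts are drawn with mean
lambda and variance phi*lambda (negative-binomial moment matching; exact
Poisson at phi = 1).

A separate direct Kent-rate simulator (:func:`simulate_kent_responses`)
draws counts from ``lambda = (baseline + gain * Kent(dir)) * T`` and is
the ground truth for fitter validation and map-recovery studies.

All randomness flows from explicit seeds; there is no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .hrtf import HrirGrid, magnitude_spectrum_db
from .kent import KentParams, kent_density, direction_to_vector
from .stimuli import (ChordStimulus, StereoStimulus, chord_frequencies,
                      frozen_grid, ILD_CAP_DB)

__all__ = [
    "SyntheticHrtfSpec",
    "SyntheticNeuron",
    "SimulatedRecording",
    "DirectionalCues",
    "make_synthetic_hrtf",
    "synthetic_spectrum_db",
    "grid_cues",
    "stimulus_cues",
    "simulate_neuron_response",
    "simulate_cue_population",
    "simulate_kent_responses",
    "simulate_chord_response",
    "simulate_spike_times",
    "make_population",
    "sample_counts",
]

DEFAULT_WINDOW_S = 0.015  # length of the 5-20 ms analysis window


# ---------------------------------------------------------------------------
# Synthetic HRTF
# ---------------------------------------------------------------------------

@dataclass
class SyntheticHrtfSpec:
    """Parameters of the parametric mouse-like HRTF.

    The defaults emulate the measured situation: 1 cm ear separation
    (ITD <= ~29 us), broadband ILD peaking at 65 deg azimuth with a ~30 dB
    maximum, and frontal spectral bands amplified at 10-24 / 48-60 kHz and
    attenuated at 25-45 / 63-76 kHz with a 20 dB peak-to-trough contrast.
    """

    ear_separation_m: float = 0.01
    sound_speed_m_s: float = 343.0
    ild_peak_azimuth_deg: float = 65.0
    ild_max_db: float = 30.0
    notch_depth_db: float = 20.0
    amplified_bands_hz: tuple = ((10_000.0, 24_000.0), (48_000.0, 60_000.0))
    attenuated_bands_hz: tuple = ((25_000.0, 45_000.0), (63_000.0, 76_000.0))
    sample_rate: float = 500_000.0
    ir_length: int = 256
    azimuths_deg: np.ndarray = field(
        default_factory=lambda: np.arange(-144.0, 144.0 + 1e-9, 18.0))
    elevations_deg: np.ndarray = field(
        default_factory=lambda: np.arange(0.0, 80.0 + 1e-9, 20.0))
    band: tuple = (5_000.0, 80_000.0)

    def __post_init__(self) -> None:
        if self.ild_max_db < 0:
            raise ValueError("ild_max_db must be nonnegative")
        az = np.asarray(self.azimuths_deg, dtype=float)
        el = np.asarray(self.elevations_deg, dtype=float)
        if np.any(np.abs(az) > 144.0 + 1e-9):
            raise ValueError("azimuths must lie within +-144 deg")
        if np.any((el < 0) | (el > 80.0 + 1e-9)):
            raise ValueError("elevations must lie within 0-80 deg")
        for lo, hi in (*self.amplified_bands_hz, *self.attenuated_bands_hz):
            if not (self.band[0] <= lo < hi <= self.band[1]):
                raise ValueError("spectral bands must lie inside the "
                                 "reproduction band")
        self.azimuths_deg = az
        self.elevations_deg = el

    @property
    def directions(self) -> np.ndarray:
        az, el = np.meshgrid(self.azimuths_deg, self.elevations_deg,
                             indexing="ij")
        return np.column_stack([az.ravel(), el.ravel()])


def _smoothbox(x, lo, hi, width=0.08):
    return 0.5 * (np.tanh((x - lo) / width) - np.tanh((x - hi) / width))


def _band_pattern(freqs_hz, spec: SyntheticHrtfSpec):
    """Frontal band template on a +-1 scale as a function of frequency."""
    x = np.log2(np.maximum(freqs_hz, 1.0) / 5_000.0)
    p = np.zeros_like(x)
    for lo, hi in spec.amplified_bands_hz:
        p += _smoothbox(x, np.log2(lo / 5e3), np.log2(hi / 5e3))
    for lo, hi in spec.attenuated_bands_hz:
        p -= _smoothbox(x, np.log2(lo / 5e3), np.log2(hi / 5e3))
    return p


def _ild_broadband_db(spec: SyntheticHrtfSpec, az_deg, el_deg):
    """Odd azimuth profile peaking exactly at ``ild_peak_azimuth_deg``.

    sin of a rescaled azimuth, clipped at 150 deg of phase so the ILD
    stays positive over the whole contralateral hemifield.
    """
    phase = np.clip(np.asarray(az_deg, dtype=float)
                    * 90.0 / spec.ild_peak_azimuth_deg, -150.0, 150.0)
    return (spec.ild_max_db * np.sin(np.radians(phase))
            * np.cos(np.radians(el_deg)))


def synthetic_spectrum_db(spec: SyntheticHrtfSpec, az_deg: float,
                          el_deg: float, ear: str, freqs_hz) -> np.ndarray:
    """Direction-dependent spectral-shape component of one ear, in dB.

    For the right ear the frontal band template cross-fades with a
    spectral comb whose phase rotates with direction (so spectra at
    different directions decorrelate); the left ear is the azimuthal
    mirror.  Excludes the flat ILD offset and the band-pass window.
    """
    if ear == "left":
        return synthetic_spectrum_db(spec, -az_deg, el_deg, "right", freqs_hz)
    if ear != "right":
        raise ValueError("ear must be 'left' or 'right'")
    f = np.asarray(freqs_hz, dtype=float)
    x = np.log2(np.maximum(f, 1.0) / 5_000.0)
    w_front = np.exp(-(az_deg / 55.0) ** 2 - (el_deg / 55.0) ** 2)
    # azimuth rotates the comb phase (1.2 deg of phase per degree, so the
    # +-144 deg range spans < 360 deg and no two azimuths share a shape);
    # elevation stretches the comb period, which decorrelates elevations
    # without trading off against the azimuth phase
    phase = np.radians(az_deg * 1.2)
    period_oct = 1.8 * (1.0 + el_deg / 240.0)
    comb = np.cos(2 * np.pi * x / period_oct - phase)
    shape = w_front * _band_pattern(f, spec) + (1.0 - w_front) * comb
    return 0.5 * spec.notch_depth_db * shape


def make_synthetic_hrtf(spec: SyntheticHrtfSpec | None = None,
                        seed: int = 0) -> HrirGrid:
    """Build the parametric HRIR grid.

    Impulse responses are synthesized in the frequency domain: a smooth
    band-pass window (5-80 kHz), the direction-dependent spectral shape
    (band-mean removed so it does not leak into the broadband ILD), half
    the broadband ILD per ear with opposite signs, and a linear phase
    carrying the interaural delay.  *seed* is accepted for interface
    symmetry; the construction is deterministic.
    """
    spec = spec or SyntheticHrtfSpec()
    n = spec.ir_length
    fs = spec.sample_rate
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    lo, hi = spec.band
    # raised-cosine edges outside the passband leave in-band gains exact
    window_db = np.full_like(freqs, -80.0)
    inside = (freqs >= lo) & (freqs <= hi)
    window_db[inside] = 0.0
    ramp_lo = (freqs >= lo - 2_000.0) & (freqs < lo)
    window_db[ramp_lo] = -80.0 * (lo - freqs[ramp_lo]) / 2_000.0
    ramp_hi = (freqs > hi) & (freqs <= hi + 4_000.0)
    window_db[ramp_hi] = -80.0 * (freqs[ramp_hi] - hi) / 4_000.0

    t0 = (n // 2) / fs
    directions = spec.directions
    ir = {"left": np.zeros((len(directions), n)),
          "right": np.zeros((len(directions), n))}
    half_sep_delay = spec.ear_separation_m / (2.0 * spec.sound_speed_m_s)
    for i, (az, el) in enumerate(directions):
        lateral = np.sin(np.radians(az)) * np.cos(np.radians(el))
        ild = _ild_broadband_db(spec, az, el)
        for ear, ear_sign in (("left", +1.0), ("right", -1.0)):
            shape = synthetic_spectrum_db(spec, az, el, ear, freqs)
            shape = shape - shape[inside].mean()
            gain_db = window_db + shape + ear_sign * (-ild / 2.0)
            delay = t0 + ear_sign * half_sep_delay * lateral
            h = np.fft.irfft(10.0 ** (gain_db / 20.0)
                             * np.exp(-2j * np.pi * freqs * delay), n)
            ir[ear][i] = h
    return HrirGrid(sample_rate=fs, directions=directions,
                    ir_left=ir["left"], ir_right=ir["right"],
                    frame="front-z", band=spec.band)


# ---------------------------------------------------------------------------
# Cue snapshots consumed by the neuron model
# ---------------------------------------------------------------------------

@dataclass
class DirectionalCues:
    """Per-direction cue values extracted from a (possibly frozen) grid."""

    directions: np.ndarray
    channel_freqs_hz: np.ndarray
    spectra_db: np.ndarray        # (n_dirs, 2 ears, n_channels); L then R
    ild_broadband_db: np.ndarray  # capped at +-ILD_CAP_DB
    silent_ear: np.ndarray        # (n_dirs, 2) bool
    frame: str = "front-z"


def _channelize(freqs, db, channel_freqs):
    """Average a dB spectrum into 1/12-octave channels (interp fallback)."""
    out = np.empty((db.shape[0], len(channel_freqs)))
    half = 2.0 ** (1.0 / 24.0)
    for k, fc in enumerate(channel_freqs):
        sel = (freqs >= fc / half) & (freqs < fc * half)
        if np.any(sel):
            out[:, k] = db[:, sel].mean(axis=1)
        else:
            out[:, k] = [np.interp(fc, freqs, row) for row in db]
    return out


def grid_cues(grid: HrirGrid, n_channels: int = 48) -> DirectionalCues:
    """Extract the cue snapshot of every grid direction.

    Spectra are reduced to 1/12-octave channels on the chord tone grid;
    the broadband ILD is the in-band dB-mean difference, capped at
    +-40 dB, with a silent ear pushing the ILD to the cap.
    """
    ch = chord_frequencies(n_channels)
    lo, hi = grid.band
    silent = np.column_stack([~np.any(grid.ir_left, axis=1),
                              ~np.any(grid.ir_right, axis=1)])
    freqs, db_l = magnitude_spectrum_db(grid.ir_left, grid.sample_rate)
    _, db_r = magnitude_spectrum_db(grid.ir_right, grid.sample_rate)
    spec_l = _channelize(freqs, db_l, ch)
    spec_r = _channelize(freqs, db_r, ch)
    sel = (freqs >= lo) & (freqs <= hi)
    ild = db_r[:, sel].mean(axis=1) - db_l[:, sel].mean(axis=1)
    ild[silent[:, 0]] = ILD_CAP_DB   # left silent -> maximal right advantage
    ild[silent[:, 1]] = -ILD_CAP_DB
    ild = np.clip(ild, -ILD_CAP_DB, ILD_CAP_DB)
    return DirectionalCues(directions=grid.directions.copy(),
                           channel_freqs_hz=ch,
                           spectra_db=np.stack([spec_l, spec_r], axis=1),
                           ild_broadband_db=ild, silent_ear=silent,
                           frame=grid.frame)


def stimulus_cues(stimulus: StereoStimulus, band=(5_000.0, 80_000.0),
                  n_channels: int = 48) -> DirectionalCues:
    """Cue snapshot of a single synthesized waveform (one 'direction')."""
    ch = chord_frequencies(n_channels)
    silent = np.array([[not np.any(stimulus.left),
                        not np.any(stimulus.right)]])
    n = len(stimulus.right)
    freqs = np.fft.rfftfreq(n, d=1.0 / stimulus.sample_rate)
    spectra = []
    for w in (stimulus.left, stimulus.right):
        mag = np.abs(np.fft.rfft(np.asarray(w, float)))
        spectra.append(20.0 * np.log10(np.maximum(mag, 1e-12))[None, :])
    spec_l = _channelize(freqs, spectra[0], ch)
    spec_r = _channelize(freqs, spectra[1], ch)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if silent[0, 0]:
        ild = np.array([ILD_CAP_DB])
    elif silent[0, 1]:
        ild = np.array([-ILD_CAP_DB])
    else:
        ild = np.clip(spectra[1][:, sel].mean(axis=1)
                      - spectra[0][:, sel].mean(axis=1),
                      -ILD_CAP_DB, ILD_CAP_DB)
    direction = np.atleast_2d(np.asarray(stimulus.direction, dtype=float))
    return DirectionalCues(directions=direction, channel_freqs_hz=ch,
                           spectra_db=np.stack([spec_l, spec_r], axis=1),
                           ild_broadband_db=ild, silent_ear=silent)


# ---------------------------------------------------------------------------
# Neurons
# ---------------------------------------------------------------------------

@dataclass
class SyntheticNeuron:
    """A simulated neuron with a known RF and cue weighting.

    ``azimuth_deg``/``elevation_deg`` (top-z), ``kappa`` and ``beta`` are
    the ground-truth Kent RF; ``w_spec``/``w_ild`` weight the spectral and
    ILD drive channels; ``template_db`` is the preferred spectral shape
    (contralateral ear, 1/12-octave channels).  Counts are overdispersed
    with variance/mean ratio ``phi``.
    """

    azimuth_deg: float
    elevation_deg: float = 10.0
    kappa: float = 6.0
    beta: float = 0.0
    w_spec: float = 1.0
    w_ild: float = 0.0
    baseline_rate_hz: float = 5.0
    gain_hz: float = 120.0
    phi: float = 5.0
    ild_threshold_db: float = 5.0
    ild_slope_db: float = 5.0
    template_db: np.ndarray | None = None
    ap_position_mm: float | None = None
    latency_peak_s: float = 0.012
    latency_width_s: float = 0.003

    def __post_init__(self) -> None:
        if self.phi < 1.0:
            raise ValueError("overdispersion phi must be >= 1")
        if self.w_spec < 0 or self.w_ild < 0 or self.w_spec + self.w_ild <= 0:
            raise ValueError("drive weights must be nonnegative, not both zero")

    @property
    def kent_params(self) -> KentParams:
        return KentParams.from_angles(self.azimuth_deg, self.elevation_deg,
                                      0.0, self.kappa, self.beta)

    def spec_drive(self, cues: DirectionalCues) -> np.ndarray:
        """Rectified correlation of the contra-ear spectrum with the
        template; 0 for flat spectra or a silent contralateral ear."""
        if self.template_db is None:
            return np.zeros(len(cues.directions))
        t = self.template_db - self.template_db.mean()
        t_norm = np.linalg.norm(t)
        s = cues.spectra_db[:, 1, :]
        s = s - s.mean(axis=1, keepdims=True)
        s_norm = np.linalg.norm(s, axis=1)
        ok = (s_norm > 1e-6) & (t_norm > 1e-9) & ~cues.silent_ear[:, 1]
        drive = np.zeros(len(s))
        drive[ok] = s[ok] @ t / (s_norm[ok] * t_norm)
        return np.clip(drive, 0.0, None)

    def ild_drive(self, cues: DirectionalCues) -> np.ndarray:
        return expit((cues.ild_broadband_db - self.ild_threshold_db)
                     / self.ild_slope_db)

    def expected_counts(self, cues: DirectionalCues,
                        window_s: float = DEFAULT_WINDOW_S) -> np.ndarray:
        drive = (self.w_spec * self.spec_drive(cues)
                 + self.w_ild * self.ild_drive(cues))
        return (self.baseline_rate_hz + self.gain_hz * drive) * window_s

    def chord_kernel(self, n_lags: int = 2) -> np.ndarray:
        """(2, n_channels, n_lags) spectro-temporal kernel for the LN model.

        Contra (right) ear: the unit-norm template with a decaying lag
        profile.  Ipsi ear: the same shape scaled by ``w_spec - w_ild``,
        so spectral neurons are binaurally symmetric (BSI > 0) and ILD
        neurons anti-symmetric (BSI < 0).
        """
        if self.template_db is None:
            raise ValueError("neuron has no spectral template")
        t = self.template_db - self.template_db.mean()
        t = t / np.linalg.norm(t)
        lag_profile = np.array([1.0, 0.4])[:n_lags]
        contra = t[:, None] * lag_profile[None, :]
        ipsi_w = float(np.clip(self.w_spec - self.w_ild, -1.0, 1.0))
        return np.stack([ipsi_w * contra, contra])


@dataclass
class SimulatedRecording:
    """Spike counts per (neuron, condition, trial, direction)."""

    counts: dict                   # condition -> (n_neurons, n_trials, n_dirs)
    directions: np.ndarray
    neurons: list
    window_s: float = DEFAULT_WINDOW_S
    frame: str = "front-z"
    locomotion: np.ndarray | None = None  # per-trial flag, constant False

    def __post_init__(self) -> None:
        n_trials = next(iter(self.counts.values())).shape[1]
        if self.locomotion is None:
            self.locomotion = np.zeros(n_trials, dtype=bool)


def sample_counts(rng: np.random.Generator, lam, phi: float) -> np.ndarray:
    """Integer counts with mean ``lam`` and variance ``phi * lam``.

    Negative binomial with r = lam/(phi-1), p = 1/phi; Poisson at phi = 1.
    """
    lam = np.asarray(lam, dtype=float)
    if phi < 1.0:
        raise ValueError("phi must be >= 1")
    if phi <= 1.0 + 1e-9:
        return rng.poisson(lam)
    r = np.maximum(lam, 1e-12) / (phi - 1.0)
    return rng.negative_binomial(r, 1.0 / phi)


def simulate_neuron_response(neuron: SyntheticNeuron, stimulus,
                             seed: int = 0, n_trials: int = 1,
                             window_s: float = DEFAULT_WINDOW_S):
    """Simulate responses to a single stimulus.

    For a :class:`StereoStimulus` the cue values are measured from the
    waveform itself and *n_trials* overdispersed counts are drawn.  For a
    :class:`ChordStimulus` the LN model runs over the full pattern
    sequence and per-10-ms-bin counts are returned.
    """
    rng = np.random.default_rng(seed)
    if isinstance(stimulus, ChordStimulus):
        return simulate_chord_response(neuron, stimulus, seed)
    cues = stimulus_cues(stimulus)
    lam = neuron.expected_counts(cues, window_s)[0]
    return sample_counts(rng, np.full(n_trials, lam), neuron.phi)


def simulate_cue_population(neurons, grid: HrirGrid, conditions,
                            n_trials: int = 20, seed: int = 0,
                            window_s: float = DEFAULT_WINDOW_S
                            ) -> SimulatedRecording:
    """Counts for a population under each stimulus condition of a grid.

    The grid is transformed per condition (cue freezing / monaural), cue
    snapshots extracted once per condition, and counts drawn per neuron,
    trial and direction.  'control' reuses the original grid with an
    independent count stream (fresh noise, same filtering).
    """
    ss = np.random.SeedSequence(seed)
    counts = {}
    for cond, child in zip(conditions, ss.spawn(len(conditions))):
        rng = np.random.default_rng(child)
        cues = grid_cues(frozen_grid(grid, cond))
        block = np.empty((len(neurons), n_trials, len(grid.directions)),
                         dtype=np.int64)
        for i, nrn in enumerate(neurons):
            lam = nrn.expected_counts(cues, window_s)
            block[i] = sample_counts(
                rng, np.broadcast_to(lam, (n_trials, len(lam))), nrn.phi)
        counts[cond] = block
    return SimulatedRecording(counts=counts, directions=grid.directions.copy(),
                              neurons=list(neurons), window_s=window_s,
                              frame=grid.frame)


def simulate_kent_responses(neurons, directions, n_trials: int = 30,
                            seed: int = 0, frame: str = "front-z",
                            window_s: float = DEFAULT_WINDOW_S) -> np.ndarray:
    """Counts from the direct Kent rate model (fitter ground truth).

    ``lambda(dir) = (baseline + gain * Kent(dir; truth)) * window`` per
    neuron; returns an (n_neurons, n_trials, n_directions) array.
    """
    rng = np.random.default_rng(seed)
    vectors = direction_to_vector(np.asarray(directions, float), frame)
    out = np.empty((len(neurons), n_trials, len(vectors)), dtype=np.int64)
    for i, nrn in enumerate(neurons):
        lam = (nrn.baseline_rate_hz
               + nrn.gain_hz * kent_density(vectors, nrn.kent_params)) \
            * window_s
        out[i] = sample_counts(rng, np.broadcast_to(lam, (n_trials, len(lam))),
                               nrn.phi)
    return out


def simulate_chord_response(neuron: SyntheticNeuron, chord: ChordStimulus,
                            seed: int = 0, chord_gain_hz: float = 60.0,
                            chord_baseline_hz: float = 2.0) -> np.ndarray:
    """LN-model spike counts per 10-ms pattern bin over all repeats.

    The linear stage correlates the neuron's spectro-temporal kernel with
    the (pattern - 0.5) history; the nonlinearity is a rectifier; counts
    are overdispersed as elsewhere.
    """
    rng = np.random.default_rng(seed)
    k = neuron.chord_kernel()
    n_lags = k.shape[2]
    pats = np.stack([chord.patterns_left, chord.patterns_right]) \
        .astype(float) - 0.5
    n_pat = chord.n_patterns
    drive = np.zeros(n_pat)
    for lag in range(1, n_lags + 1):
        for e in range(2):
            drive[lag:] += pats[e, :n_pat - lag] @ k[e, :, lag - 1]
    rate = chord_baseline_hz + chord_gain_hz * np.clip(drive, 0.0, None)
    lam_bin = rate * chord.pattern_duration
    lam_all = np.tile(lam_bin, chord.n_repeats)
    return sample_counts(rng, lam_all, neuron.phi)


def simulate_spike_times(counts_per_event, event_times,
                         latency_peak_s: float = 0.012,
                         latency_width_s: float = 0.003,
                         seed: int = 0) -> np.ndarray:
    """Place spikes at latencies drawn from a Gaussian kernel after onset.

    Latencies are truncated to [1 ms, 30 ms] so all spikes stay close to
    the fast-response analysis window; returns a sorted spike-time array.
    """
    rng = np.random.default_rng(seed)
    times = []
    for c, ev in zip(np.asarray(counts_per_event, int),
                     np.asarray(event_times, float)):
        lat = rng.normal(latency_peak_s, latency_width_s, int(c))
        lat = np.clip(lat, 0.001, 0.030)
        times.extend(ev + lat)
    return np.sort(np.asarray(times))


# ---------------------------------------------------------------------------
# Populations
# ---------------------------------------------------------------------------

def make_population(n_neurons: int, map_slope_deg_mm: float = 58.0,
                    map_offset_deg: float = 14.0,
                    ap_range_mm: tuple = (0.0, 1.8),
                    jitter_deg: float = 19.0, phi: float = 5.0,
                    seed: int = 0, positions_mm=None,
                    hrtf_spec: SyntheticHrtfSpec | None = None) -> list:
    """A population whose RF azimuths follow a topographic map.

    RF azimuth = offset + slope * (A-P position) + Gaussian jitter (the
    +-19 deg systematic scatter of the real map); the spectral/ILD drive
    weights cross-fade with azimuth (frontal neurons spectral, lateral
    neurons ILD-driven, midpoint 45 deg) and the RF radius grows with
    azimuth (kappa falls), mirroring the measured radius-azimuth trend.
    Spectral templates are taken from *hrtf_spec* at each neuron's
    preferred direction.
    """
    if n_neurons < 1:
        raise ValueError("n_neurons must be >= 1")
    rng = np.random.default_rng(seed)
    spec = hrtf_spec or SyntheticHrtfSpec()
    if positions_mm is None:
        positions_mm = rng.uniform(*ap_range_mm, n_neurons)
    positions_mm = np.asarray(positions_mm, dtype=float)
    az = (map_offset_deg + map_slope_deg_mm * positions_mm
          + (jitter_deg * rng.standard_normal(n_neurons)
             if jitter_deg > 0 else 0.0))
    az = np.clip(az, -140.0, 140.0)
    el = np.clip(np.abs(rng.normal(10.0, 8.0, n_neurons)), 0.0, 50.0) \
        if jitter_deg > 0 else np.full(n_neurons, 10.0)
    ch = chord_frequencies()
    neurons = []
    for i in range(n_neurons):
        radius = 22.0 + 0.21 * abs(az[i])          # degrees
        kappa = 1.0 / (2.0 * (1.0 - np.cos(np.radians(min(radius, 85.0)))))
        w_ild = float(expit((abs(az[i]) - 45.0) / 15.0))
        template = synthetic_spectrum_db(spec, az[i], el[i], "right", ch)
        neurons.append(SyntheticNeuron(
            azimuth_deg=float(az[i]), elevation_deg=float(el[i]),
            kappa=float(kappa), beta=0.0,
            w_spec=1.0 - w_ild, w_ild=w_ild, phi=phi,
            template_db=template, ap_position_mm=float(positions_mm[i])))
    return neurons
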