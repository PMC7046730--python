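"""Stimulus construction for virtual auditory space (VAS) experiments.

Every stimulus condition used in the analysis is built here from an
:class:`~vasrf.hrtf.HrirGrid`:

* full-field VAS noise bursts (100-ms white noise, 5-ms linear tapers,
  filtered per ear by the direction's HRIR),
* the cue-frozen grid variants (zero ITD, zero mean ILD, flat spectrum)
  and monaural variants,
* the extended-ILD stimulus set (flat-spectrum bursts at ILDs from -40 to
  +40 dB in 2-dB steps), and
* the binaural dynamic random chord stimulus (48 tones, 5-80 kHz at 12 per
  octave, 10-ms patterns, each tone independently ON with probability 0.5,
  the two ears uncorrelated).

"Freezing" a cue means fixing it at its reference value (ITD = 0; equal
ear levels; flat spectrum) for *all* directions while the other cues keep
their natural direction dependence.  The frozen cue is still present --
e.g. a zero ILD is consistent with a midline source -- it just no longer
varies with direction.

All generation is a pure function of (grid, seed, parameters): identical
seeds give bit-identical output.  Per-trial noise seeds are derived from
``(master_seed, direction_index, trial_index)`` so trials are independent
but reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .hrtf import HrirGrid, band_average_level_db

__all__ = [
    "CONDITIONS",
    "StereoStimulus",
    "ChordStimulus",
    "tapered_noise",
    "synthesize_vas",
    "freeze_itd",
    "freeze_ild",
    "freeze_spectrum",
    "make_monaural",
    "frozen_grid",
    "build_extended_ild_set",
    "generate_random_chord",
    "chord_frequencies",
    "trial_seed",
]

CONDITIONS = (
    "original", "control", "frozen_itd", "frozen_ild", "frozen_spectrum",
    "monaural", "monaural_frozen_spectrum", "extended_ild",
)

#: cap used when one ear is silent and the broadband ILD would be infinite;
#: matches the ceiling of the extended-ILD stimulus set.
ILD_CAP_DB = 40.0


@dataclass
class StereoStimulus:
    """A synthesized binaural waveform for one direction and condition."""

    left: np.ndarray
    right: np.ndarray
    sample_rate: float
    direction: tuple
    condition: str
    noise_seed: int
    duration: float = 0.1
    taper: float = 0.005
    ild_db: float | None = None  # only set for extended-ILD stimuli


def trial_seed(master_seed: int, direction_index: int, trial_index: int) -> int:
    """Deterministic per-trial seed below 2**31."""
    ss = np.random.SeedSequence([int(master_seed), int(direction_index),
                                 int(trial_index)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def tapered_noise(sample_rate: float, duration: float = 0.1,
                  taper: float = 0.005, seed: int = 0,
                  band: tuple | None = None) -> np.ndarray:
    """White-noise burst with linear onset/offset tapers.

    If *band* is given the noise is brick-wall band-limited (FFT zeroing)
    before tapering, so the nominal spectrum is flat inside the band and
    empty outside it.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration * sample_rate))
    x = rng.standard_normal(n)
    if band is not None:
        spec = np.fft.rfft(x)
        freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
        spec[(freqs < band[0]) | (freqs > band[1])] = 0.0
        x = np.fft.irfft(spec, n=n)
    n_taper = int(round(taper * sample_rate))
    if n_taper > 0:
        ramp = np.linspace(0.0, 1.0, n_taper, endpoint=False)
        x[:n_taper] *= ramp
        x[-n_taper:] *= ramp[::-1]
    return x


def synthesize_vas(direction, grid: HrirGrid, noise_seed: int = 0,
                   inverse_filter: np.ndarray | None = None,
                   duration: float = 0.1, taper: float = 0.005,
                   condition: str = "original") -> StereoStimulus:
    """Synthesize one VAS noise burst for a grid direction.

    The burst is band-limited white noise (the reproduction band of the
    grid, 5-80 kHz by default), linearly tapered, optionally pre-filtered
    by a zero-phase device-flattening *inverse_filter* (identity when not
    supplied), and finally filtered per ear by the direction's HRIR
    including phase.  The direction must lie exactly on the grid;
    nearest-neighbour substitution is refused.
    """
    idx = grid.index_of(direction)  # raises KeyError off-grid
    x = tapered_noise(grid.sample_rate, duration, taper, noise_seed,
                      band=grid.band)
    if inverse_filter is not None:
        x = signal.fftconvolve(x, np.asarray(inverse_filter, float))[:len(x)]
    left = signal.fftconvolve(x, grid.ir_left[idx])[:len(x)]
    right = signal.fftconvolve(x, grid.ir_right[idx])[:len(x)]
    return StereoStimulus(left=left, right=right, sample_rate=grid.sample_rate,
                          direction=tuple(np.asarray(direction, float)),
                          condition=condition, noise_seed=int(noise_seed),
                          duration=duration, taper=taper)


# ---------------------------------------------------------------------------
# Cue freezing (grid -> grid transforms)
# ---------------------------------------------------------------------------

def freeze_itd(grid: HrirGrid) -> HrirGrid:
    """Zero the ITD of every direction.

    The left impulse response is circularly shifted so its ``|h|`` peak
    coincides in time with the right ear's peak.  A circular shift leaves
    the magnitude spectrum (hence the per-frequency ILD and the spectral
    cues) bit-exactly unchanged.
    """
    out = grid.copy()
    for i in range(out.n_directions):
        t_left = int(np.argmax(np.abs(out.ir_left[i])))
        t_right = int(np.argmax(np.abs(out.ir_right[i])))
        out.ir_left[i] = np.roll(out.ir_left[i], t_right - t_left)
    return out


def freeze_ild(grid: HrirGrid) -> HrirGrid:
    """Equalize the two ears' band-average levels at every direction.

    Each ear is rescaled by a single scalar so both band-average levels
    equal the two-ear mean; spectral shapes and timing are untouched.
    """
    out = grid.copy()
    for i in range(out.n_directions):
        if not np.any(out.ir_left[i]) or not np.any(out.ir_right[i]):
            raise ValueError(f"direction index {i}: silent ear, ILD undefined")
        lv_l = band_average_level_db(out.ir_left[i], out.sample_rate, out.band)
        lv_r = band_average_level_db(out.ir_right[i], out.sample_rate, out.band)
        target = 0.5 * (lv_l + lv_r)
        out.ir_left[i] *= 10.0 ** ((target - lv_l) / 20.0)
        out.ir_right[i] *= 10.0 ** ((target - lv_r) / 20.0)
    return out


def freeze_spectrum(grid: HrirGrid) -> HrirGrid:
    """Flatten the spectrum of every impulse response.

    Each IR is replaced by a single-sample impulse at its original
    ``|h|``-peak position, scaled so the ear's band-average level is
    preserved.  ITD (peak timing) and broadband ILD are therefore kept,
    while all spectral structure is removed.
    """
    out = grid.copy()
    for i in range(out.n_directions):
        for ir in (out.ir_left, out.ir_right):
            level = band_average_level_db(ir[i], out.sample_rate, out.band)
            peak = int(np.argmax(np.abs(ir[i])))
            ir[i] = 0.0
            ir[i, peak] = 10.0 ** (level / 20.0)
    return out


def make_monaural(grid: HrirGrid) -> HrirGrid:
    """Silence the ipsilateral (left) ear for all directions."""
    out = grid.copy()
    out.ir_left[:] = 0.0
    return out


_GRID_TRANSFORMS = {
    "original": lambda g: g.copy(),
    "control": lambda g: g.copy(),
    "frozen_itd": freeze_itd,
    "frozen_ild": freeze_ild,
    "frozen_spectrum": freeze_spectrum,
    "monaural": make_monaural,
    "monaural_frozen_spectrum": lambda g: make_monaural(freeze_spectrum(g)),
}


def frozen_grid(grid: HrirGrid, condition: str) -> HrirGrid:
    """The grid variant corresponding to a stimulus condition."""
    try:
        return _GRID_TRANSFORMS[condition](grid)
    except KeyError:
        raise ValueError(f"unknown condition {condition!r}") from None


# ---------------------------------------------------------------------------
# Extended ILD stimulus
# ---------------------------------------------------------------------------

def build_extended_ild_set(seed: int, sample_rate: float = 500_000.0,
                           n_repeats: int = 30, duration: float = 0.1,
                           taper: float = 0.005,
                           band: tuple = (5_000.0, 80_000.0)) -> list:
    """Flat-spectrum noise bursts spanning ILDs of -40..+40 dB in 2-dB steps.

    Each of the 41 levels is repeated *n_repeats* times; presentation order
    is randomized by *seed*.  The ILD is imposed symmetrically (+ILD/2 on
    the right ear, -ILD/2 on the left) around a fixed reference amplitude.
    """
    rng = np.random.default_rng(seed)
    levels = np.arange(-40.0, 40.0 + 1e-9, 2.0)
    order = np.repeat(levels, n_repeats)
    rng.shuffle(order)
    out = []
    for k, ild in enumerate(order):
        noise_seed = trial_seed(seed, 0, k)
        x = tapered_noise(sample_rate, duration, taper, noise_seed, band=band)
        out.append(StereoStimulus(
            left=x * 10.0 ** (-ild / 40.0),
            right=x * 10.0 ** (+ild / 40.0),
            sample_rate=sample_rate, direction=(np.nan, np.nan),
            condition="extended_ild", noise_seed=noise_seed,
            duration=duration, taper=taper, ild_db=float(ild)))
    return out


# ---------------------------------------------------------------------------
# Dynamic random chord stimulus
# ---------------------------------------------------------------------------

def chord_frequencies(n_tones: int = 48, f_low: float = 5_000.0,
                      steps_per_octave: int = 12) -> np.ndarray:
    """Logarithmic tone grid: ``f_low * 2**(k/steps)`` for k = 0..n-1.

    With the defaults the 48th tone lies at 5 * 2**(47/12) ~ 75.5 kHz, i.e.
    inside the 5-80 kHz reproduction band.
    """
    return f_low * 2.0 ** (np.arange(n_tones) / steps_per_octave)


@dataclass
class ChordStimulus:
    """Binaural dynamic random chord stimulus as binary tone patterns.

    ``patterns_left`` / ``patterns_right`` are ``(n_patterns, n_tones)``
    binary matrices; each tone is independently ON with probability 0.5 and
    the two ears are statistically independent.  One presentation of the
    pattern set lasts ``n_patterns * pattern_duration`` seconds and is
    repeated ``n_repeats`` times with the *identical* pattern set.
    """

    patterns_left: np.ndarray
    patterns_right: np.ndarray
    frequencies_hz: np.ndarray
    pattern_duration: float = 0.010
    taper: float = 0.003
    n_repeats: int = 20
    seed: int = 0

    @property
    def n_patterns(self) -> int:
        return self.patterns_left.shape[0]

    @property
    def n_tones(self) -> int:
        return self.patterns_left.shape[1]

    @property
    def total_duration(self) -> float:
        return self.n_patterns * self.pattern_duration * self.n_repeats

    def patterns(self, ear: str) -> np.ndarray:
        if ear not in ("left", "right"):
            raise ValueError("ear must be 'left' or 'right'")
        return self.patterns_left if ear == "left" else self.patterns_right

    def synthesize_segment(self, sample_rate: float, start: int = 0,
                           n_patterns: int = 10) -> tuple:
        """Render a short waveform excerpt (both ears) for inspection.

        Tones are fixed-amplitude sinusoids with 3-ms linear tapers at the
        start and end of each 10-ms pattern.  Rendering the full stimulus
        at 500 kHz would be tens of millions of samples, so only an excerpt
        is synthesized.
        """
        n_pat = int(round(self.pattern_duration * sample_rate))
        n_taper = int(round(self.taper * sample_rate))
        env = np.ones(n_pat)
        ramp = np.linspace(0.0, 1.0, n_taper, endpoint=False)
        env[:n_taper] = ramp
        env[-n_taper:] = ramp[::-1]
        t = np.arange(n_pat) / sample_rate
        tones = np.sin(2 * np.pi * self.frequencies_hz[:, None] * t[None, :])
        out = []
        for pats in (self.patterns_left, self.patterns_right):
            seg = [env * (pats[start + i] @ tones)
                   for i in range(n_patterns)]
            out.append(np.concatenate(seg))
        return out[0], out[1]


def generate_random_chord(seed: int, total_minutes: float = 2.0,
                          n_repeats: int = 20, n_tones: int = 48,
                          pattern_duration: float = 0.010,
                          taper: float = 0.003) -> ChordStimulus:
    """Generate the binaural random chord pattern set.

    A *total_minutes*-long presentation at 10 ms per pattern contains
    ``total_minutes * 60 / 0.010`` patterns (12,000 for 2 minutes); the
    same set is reused for every repeat.
    """
    if total_minutes <= 0:
        raise ValueError("total_minutes must be positive")
    n_patterns = int(round(total_minutes * 60.0 / pattern_duration))
    rng = np.random.default_rng(seed)
    left = (rng.random((n_patterns, n_tones)) < 0.5).astype(np.int8)
    right = (rng.random((n_patterns, n_tones)) < 0.5).astype(np.int8)
    return ChordStimulus(patterns_left=left, patterns_right=right,
                         frequencies_hz=chord_frequencies(n_tones),
                         pattern_duration=pattern_duration, taper=taper,
                         n_repeats=n_repeats, seed=int(seed))
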