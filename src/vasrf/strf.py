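"""Binaural spectro-temporal receptive fields from random chord stimuli.

The STRF of a neuron is estimated as the spike-triggered average (STA) of
the binary tone patterns: spikes are discretized into the 10-ms pattern
bins, and for each ear, frequency and lag (1..10 patterns before the
spike bin) the count-weighted average of the pattern values is computed
and the per-frequency stimulus mean M subtracted.  M fluctuates around
0.5 because the realized stimulus is random; it is evaluated per ear and
frequency from the presented patterns.

Per-pixel significance is a two-sided binomial test: with N spikes, the
raw STA value S at a pixel corresponds to S*N successes out of N at
success probability M; pixels whose binomial CDF falls above
``1 - alpha / N_pixels / 2`` (below ``alpha / N_pixels / 2``) carry a
significantly positive (negative) structure, a Bonferroni correction over
all N_pixels = lags x frequencies x ears pixels that holds the whole-STA
false-positive rate at alpha.  Neurons with fewer than 20 spikes during
the stimulus are not analyzed.

The binaural similarity index (BSI) is the cosine similarity between the
two ears' STA blocks, and population maps give the per-pixel fraction of
neurons in an RF-azimuth group with significant structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .similarity import cosine_si
from .stimuli import ChordStimulus

__all__ = [
    "Strf",
    "PopulationMap",
    "compute_sta",
    "sta_significance",
    "binaural_si",
    "population_fraction_map",
    "MIN_SPIKES",
]

#: neurons with fewer spikes than this during the chord stimulus are excluded
MIN_SPIKES = 20

#: number of pattern lags before the spike bin entering the STA
DEFAULT_LOOKBACK = 10


@dataclass
class Strf:
    """Binaural STA with per-pixel significance mask.

    ``sta[ear, f, lag]``: mean preceding-pattern value minus the
    per-frequency stimulus mean, for ear in (0=left/ipsi, 1=right/contra),
    the 48 tone frequencies, and lags 1..lookback patterns before the
    spike bin (lag index 0 = the pattern immediately before).
    ``mask`` is +1/-1/0 per pixel once :func:`sta_significance` has run.
    """

    sta: np.ndarray
    stimulus_mean: np.ndarray      # (2, n_freqs) per-ear, per-frequency M
    n_spikes: int
    frequencies_hz: np.ndarray
    lag_s: np.ndarray              # time before spike of each lag bin center
    mask: np.ndarray | None = None
    bsi: float | None = None

    @property
    def n_pixels(self) -> int:
        return self.sta.size


def compute_sta(spike_counts_per_bin, chord: ChordStimulus,
                lookback: int = DEFAULT_LOOKBACK) -> Strf:
    """Spike-triggered average of the chord patterns preceding each spike.

    Parameters
    ----------
    spike_counts_per_bin : array
        Spike counts in each 10-ms pattern bin, aligned to the pattern
        grid and concatenated over repeats (length divisible by the
        number of patterns; repeats reuse the identical pattern set).
        Bins where multiple spikes fell weight their preceding patterns
        by the count.
    chord : ChordStimulus
    lookback : int
        Number of preceding patterns entering the average (lag 0, the
        simultaneous pattern, is excluded; responses at < 10 ms cannot be
        driven by the bin's own pattern onset in this discretization).
    """
    counts = np.asarray(spike_counts_per_bin, dtype=float).ravel()
    n_pat = chord.n_patterns
    if len(counts) % n_pat != 0:
        raise ValueError("spike bins must align to whole pattern repeats")
    n_rep = len(counts) // n_pat
    n_spikes = counts.sum()
    if n_spikes < MIN_SPIKES:
        raise ValueError(
            f"only {int(n_spikes)} spikes; fewer than the minimum of "
            f"{MIN_SPIKES} required for an STA")
    ears = (chord.patterns_left, chord.patterns_right)
    stim_mean = np.array([p.mean(axis=0) for p in ears], dtype=float)
    n_f = chord.n_tones
    sta = np.zeros((2, n_f, lookback))
    counts_by_rep = counts.reshape(n_rep, n_pat)
    for e, pats in enumerate(ears):
        pats = pats.astype(float)
        for lag in range(1, lookback + 1):
            # pattern at (t - lag) weighted by the spike count at t
            w = counts_by_rep[:, lag:]           # spikes with a valid history
            acc = np.einsum("rt,tf->f", w, pats[:n_pat - lag])
            norm = w.sum()
            sta[e, :, lag - 1] = acc / norm - stim_mean[e]
    lag_s = (np.arange(1, lookback + 1) - 0.5) * chord.pattern_duration
    return Strf(sta=sta, stimulus_mean=stim_mean, n_spikes=int(n_spikes),
                frequencies_hz=chord.frequencies_hz, lag_s=lag_s)


def sta_significance(strf: Strf, alpha: float = 0.001) -> np.ndarray:
    """Two-sided Bonferroni-corrected binomial mask for every STA pixel.

    Returns (and stores on *strf*) a ``{-1, 0, +1}`` array of the STA's
    shape; +1 where the binomial CDF of ``S*N`` successes in ``N`` trials
    at probability ``M`` exceeds ``1 - alpha/N_pixels/2``, -1 where it is
    below ``alpha/N_pixels/2``.
    """
    n = strf.n_spikes
    if n < MIN_SPIKES:
        raise ValueError("too few spikes for a significance mask")
    n_pix = strf.n_pixels
    thr = alpha / n_pix / 2.0
    m = strf.stimulus_mean[:, :, None]
    successes = np.floor((strf.sta + m) * n)
    cdf = stats.binom.cdf(successes, n, m)
    mask = np.zeros(strf.sta.shape, dtype=np.int8)
    mask[cdf > 1.0 - thr] = 1
    mask[cdf < thr] = -1
    strf.mask = mask
    return mask


def binaural_si(strf: Strf) -> float:
    """Cosine similarity between the flattened ipsi and contra STA blocks.

    Symmetric binaural tuning gives BSI near +1, anti-symmetric tuning
    (excitation in one ear where the other is suppressed) gives BSI near
    -1, independent tuning gives BSI near 0.
    """
    bsi = cosine_si(strf.sta[0].ravel(), strf.sta[1].ravel()).si
    strf.bsi = bsi
    return bsi


@dataclass
class PopulationMap:
    """Per-pixel fraction of group neurons with significant structure."""

    positive_fraction: np.ndarray  # (2, n_freqs, n_lags)
    negative_fraction: np.ndarray
    group: str
    n_neurons: int


def population_fraction_map(strfs, rf_azimuths_deg,
                            split_deg: float = 35.0) -> dict:
    """Fractions of significant STA pixels by frontal/lateral RF group.

    Neurons are grouped by RF azimuth (frontal < *split_deg*, lateral >=
    *split_deg*); for each group and pixel the fraction of neurons with a
    +1 (separately -1) mask is returned.  Every STRF must already carry a
    significance mask.
    """
    azimuths = np.asarray(rf_azimuths_deg, dtype=float)
    if len(strfs) != len(azimuths):
        raise ValueError("one RF azimuth per STRF is required")
    groups = {"frontal": [s for s, a in zip(strfs, azimuths) if a < split_deg],
              "lateral": [s for s, a in zip(strfs, azimuths) if a >= split_deg]}
    out = {}
    for name, members in groups.items():
        if not members:
            raise ValueError(f"empty {name} group (split at {split_deg} deg)")
        masks = np.array([m.mask for m in members])
        if any(m.mask is None for m in members):
            raise ValueError("all STRFs need a significance mask first")
        out[name] = PopulationMap(
            positive_fraction=(masks == 1).mean(axis=0),
            negative_fraction=(masks == -1).mean(axis=0),
            group=name, n_neurons=len(members))
    return out
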