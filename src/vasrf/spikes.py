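"""Spike-count statistics: PSTHs, analysis windows, quasi-Poisson tests.

Auditory midbrain neurons respond with short latency; the analyses here
use spike counts in a 5-20 ms post-onset window (the fast response
component).  Trial-to-trial counts are overdispersed -- their variance is
phi times the mean with phi well above the Poisson value of 1 -- so
response significance uses quasi-Poisson statistics: the null count
distribution is taken to have mean equal to the baseline expectation and
variance phi times that mean.  Quasi-Poisson is a moment model without a
unique distribution; the concrete tail probabilities here come from a
negative binomial moment-matched to (mean, phi*mean), which reduces to
the exact Poisson at phi = 1 (the choice between these two overdispersed
families has little practical effect on the test).

Fractions of neurons in a category carry binomial errors
``sqrt(p (1 - p) / N)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "Psth",
    "ResponseMatrix",
    "SignificanceResult",
    "build_psth",
    "window_counts",
    "estimate_overdispersion",
    "quasi_poisson_test",
    "response_significance",
    "binomial_fraction_se",
    "ANALYSIS_WINDOW",
]

#: default analysis window, seconds after stimulus onset (half-open)
ANALYSIS_WINDOW = (0.005, 0.020)


# ---------------------------------------------------------------------------
# PSTH
# ---------------------------------------------------------------------------

@dataclass
class Psth:
    """Trial-averaged peri-stimulus time histogram."""

    bin_edges: np.ndarray     # seconds relative to onset
    rate_hz: np.ndarray       # trial-averaged firing rate per bin
    n_trials: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def peak_latency(self) -> float:
        """Center of the highest-rate bin, seconds after onset."""
        return float(self.bin_centers[int(np.argmax(self.rate_hz))])


def build_psth(spike_times, event_times, bin_width: float = 0.005,
               window: tuple = (0.0, 0.1)) -> Psth:
    """PSTH of spike times around stimulus events.

    Parameters
    ----------
    spike_times, event_times : sorted arrays, seconds
    bin_width : float, seconds (default 5 ms)
    window : (start, stop) relative to each event
    """
    spikes = np.asarray(spike_times, dtype=float)
    events = np.asarray(event_times, dtype=float)
    if len(events) == 0:
        raise ValueError("no events supplied")
    edges = np.arange(window[0], window[1] + 0.5 * bin_width, bin_width)
    counts = np.zeros(len(edges) - 1)
    for ev in events:
        rel = spikes[(spikes >= ev + window[0]) & (spikes < ev + window[1])] - ev
        counts += np.histogram(rel, bins=edges)[0]
    rate = counts / (len(events) * bin_width)
    return Psth(bin_edges=edges, rate_hz=rate, n_trials=len(events))


# ---------------------------------------------------------------------------
# Windowed counts
# ---------------------------------------------------------------------------

@dataclass
class ResponseMatrix:
    """Trial x direction spike counts in the analysis window.

    ``counts[t, d]`` is the integer spike count of trial ``t`` of
    direction ``d`` inside the (half-open) analysis window;
    ``baseline_counts`` holds the matching pre-stimulus window counts used
    to estimate the spontaneous rate.
    """

    counts: np.ndarray
    directions: np.ndarray
    condition: str = "original"
    window: tuple = ANALYSIS_WINDOW
    baseline_counts: np.ndarray | None = None
    baseline_window: tuple | None = None
    frame: str = "front-z"

    def __post_init__(self) -> None:
        self.counts = np.atleast_2d(np.asarray(self.counts))
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    @property
    def mean_by_direction(self) -> np.ndarray:
        return self.counts.mean(axis=0)


def window_counts(spike_times, event_times, directions_by_event,
                  directions, window: tuple = ANALYSIS_WINDOW,
                  baseline_window: tuple | None = None,
                  condition: str = "original") -> ResponseMatrix:
    """Per-trial, per-direction spike counts in a half-open window.

    A spike at exactly ``onset + window[0]`` is included; one at exactly
    ``onset + window[1]`` is excluded.  ``directions_by_event[i]`` is the
    row index into *directions* of event ``i``; every direction must have
    the same number of trials.  Overlapping analysis windows across
    consecutive events are rejected.
    """
    spikes = np.asarray(spike_times, dtype=float)
    events = np.asarray(event_times, dtype=float)
    dir_idx = np.asarray(directions_by_event, dtype=int)
    directions = np.asarray(directions, dtype=float)
    if len(events) != len(dir_idx):
        raise ValueError("one direction index per event is required")
    order = np.argsort(events, kind="stable")
    if np.any(np.diff(events[order]) < (window[1] - window[0])):
        raise ValueError("analysis windows of consecutive events overlap")

    def count_in(ev, win):
        lo = np.searchsorted(spikes, ev + win[0], side="left")
        hi = np.searchsorted(spikes, ev + win[1], side="left")
        return hi - lo

    n_dir = len(directions)
    per_dir = [[] for _ in range(n_dir)]
    base_per_dir = [[] for _ in range(n_dir)]
    for ev, d in zip(events, dir_idx):
        per_dir[d].append(count_in(ev, window))
        if baseline_window is not None:
            base_per_dir[d].append(count_in(ev, baseline_window))
    n_trials = {len(c) for c in per_dir}
    if len(n_trials) != 1:
        raise ValueError("unequal trial counts across directions")
    counts = np.array(per_dir).T
    baseline = (np.array(base_per_dir).T if baseline_window is not None
                else None)
    return ResponseMatrix(counts=counts, directions=directions,
                          condition=condition, window=tuple(window),
                          baseline_counts=baseline,
                          baseline_window=(tuple(baseline_window)
                                           if baseline_window else None))


# ---------------------------------------------------------------------------
# Overdispersion and significance
# ---------------------------------------------------------------------------

def estimate_overdispersion(counts) -> float:
    """Overdispersion phi = sample variance / sample mean of the counts.

    phi is 1 for a Poisson neuron; bursting and behavioural state push it
    well above 1.
    """
    y = np.asarray(counts, dtype=float).ravel()
    if y.size < 2:
        raise ValueError("need at least 2 counts")
    m = y.mean()
    if m <= 0:
        raise ValueError("overdispersion undefined for zero-mean counts")
    return float(y.var(ddof=1) / m)


@dataclass
class SignificanceResult:
    p_value: float
    phi: float
    is_significant: bool
    alpha: float = 0.001


def quasi_poisson_test(evoked_count, baseline_mean: float, phi: float,
                       alpha: float = 0.001) -> SignificanceResult:
    """Upper-tail test of a spike count against an overdispersed baseline.

    ``p = 1 - CDF(N)`` where the CDF is that of a count distribution with
    mean *baseline_mean* and variance ``phi * baseline_mean`` (negative
    binomial moment matching; exact Poisson at phi = 1).  phi below 1 is
    clamped to 1.
    """
    n = float(evoked_count)
    if n < 0:
        raise ValueError("counts must be nonnegative")
    if baseline_mean < 0:
        raise ValueError("baseline mean must be nonnegative")
    phi = max(float(phi), 1.0)
    if baseline_mean == 0:
        p = 0.0 if n > 0 else 1.0
    elif phi <= 1.0 + 1e-9:
        p = float(stats.poisson.sf(np.floor(n), baseline_mean))
    else:
        r = baseline_mean / (phi - 1.0)
        p = float(stats.nbinom.sf(np.floor(n), r, 1.0 / phi))
    return SignificanceResult(p_value=p, phi=phi,
                              is_significant=bool(p < alpha), alpha=alpha)


def response_significance(response: ResponseMatrix,
                          alpha: float = 0.001) -> SignificanceResult:
    """Significance of a neuron's total evoked count given its baseline.

    The baseline mean is estimated from the pre-stimulus window of the
    same trials, scaled to the analysis-window length, and multiplied by
    the total number of trials; phi comes from the trial-by-trial evoked
    counts (it needs >= 2 counts and a nonzero mean -- silent neurons are
    never significant).
    """
    if response.baseline_counts is None:
        raise ValueError("response matrix carries no baseline counts")
    total = float(response.counts.sum())
    if total <= 0:
        return SignificanceResult(p_value=1.0, phi=1.0, is_significant=False,
                                  alpha=alpha)
    phi = estimate_overdispersion(response.counts)
    win_len = response.window[1] - response.window[0]
    base_mean_per_trial = response.baseline_counts.mean()
    # baseline window may have a different length; scale rates
    base_win = (response.baseline_window[1] - response.baseline_window[0]
                if response.baseline_window else win_len)
    expected_total = base_mean_per_trial * (win_len / base_win) \
        * response.counts.size
    return quasi_poisson_test(total, expected_total, phi, alpha)


def binomial_fraction_se(k: int, n: int) -> tuple:
    """Fraction of a category and its binomial error, both in percent.

    ``p = k/n``, ``se = sqrt(p (1-p) / n)``; returned rounded to one
    decimal in percent (reporting precision).
    """
    if not (0 <= k <= n) or n < 1:
        raise ValueError("need 0 <= k <= n with n >= 1")
    p = k / n
    se = np.sqrt(p * (1.0 - p) / n)
    return round(100.0 * p, 1), round(100.0 * se, 1)
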