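"""Cosine similarity indices for receptive-field comparison.

The directional response of a neuron (mean firing over the 85 virtual
source locations) is treated as a vector; to compare two conditions the
vectors are mean-subtracted, scaled to unit norm, and their inner product
taken (cosine similarity index, SI).  Identical RF structure gives SI = 1,
uncorrelated structure gives SI ~ 0.  The SI between the control and
original presentations of the *same* stimulus measures reproducibility;
neurons whose control SI is not significantly positive are excluded.
Frozen-cue SIs are normalized by the control SI (NSI = SI / SI_control)
and reported as a loss, 1 - NSI: the dependence of the RF on that cue.

Per-direction count errors (Poisson) are propagated to the SI by the
first-order delta method; :func:`bootstrap_si_error` provides an
independent resampling cross-check.

The extended-ILD stimulus classifies ILD response curves as flat,
monotonic (sigmoid-like) or peaked (tuned to an intermediate ILD).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "SimilarityResult",
    "IldTuningClass",
    "cosine_si",
    "nsi_loss",
    "reproducibility_filter",
    "bootstrap_si_error",
    "ild_tuning_classify",
    "FRONTAL_LATERAL_SPLIT_DEG",
    "STRF_GROUP_SPLIT_DEG",
]

#: azimuth threshold splitting frontal from lateral RFs in cue-freezing
#: summaries, degrees
FRONTAL_LATERAL_SPLIT_DEG = 45.0
#: azimuth threshold used for STRF population groups (chosen to balance
#: group sizes), degrees
STRF_GROUP_SPLIT_DEG = 35.0


@dataclass
class SimilarityResult:
    si: float
    si_error: float


def _center_unit(a: np.ndarray):
    c = a - a.mean()
    norm = np.linalg.norm(c)
    if norm <= 0:
        raise ValueError("zero-variance response vector; SI undefined")
    return c / norm, norm


def cosine_si(responses_a, responses_b, errors_a=None, errors_b=None
              ) -> SimilarityResult:
    """Cosine similarity of two direction-response vectors.

    Both vectors are mean-subtracted then unit-normalized (in that order);
    the SI is their inner product, in [-1, 1].  If per-direction count
    errors are given (e.g. ``sqrt(total count)`` under Poisson statistics)
    they are propagated to the SI by the delta method; otherwise the error
    is reported as 0.
    """
    a = np.asarray(responses_a, dtype=float)
    b = np.asarray(responses_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("response vectors must be 1-D and of equal length")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("response vectors must be finite")
    ua, norm_a = _center_unit(a)
    ub, norm_b = _center_unit(b)
    si = float(ua @ ub)

    var = 0.0
    n = len(a)
    for u_self, u_other, norm, err in ((ua, ub, norm_a, errors_a),
                                       (ub, ua, norm_b, errors_b)):
        if err is None:
            continue
        err = np.asarray(err, dtype=float)
        # d si / d a = (I - 1 1^T/n) (u_b - si u_a) / ||a - mean||
        g = u_other - si * u_self
        g = g - g.mean()
        var += float(np.sum((g / norm) ** 2 * err ** 2))
    return SimilarityResult(si=si, si_error=float(np.sqrt(var)))


def nsi_loss(si_cue: float, si_control: float) -> float:
    """Loss of normalized similarity, ``1 - si_cue / si_control``.

    0 means the cue manipulation left the RF untouched; 1 means the RF
    structure is gone.  Only defined for a positive control SI (neurons
    failing the reproducibility filter are excluded upstream).
    """
    if si_control <= 0:
        raise ValueError("nsi_loss requires a positive control SI")
    return 1.0 - si_cue / si_control


def reproducibility_filter(si_control: float, si_error: float,
                           alpha: float = 0.01) -> bool:
    """One-sided z-test that the control SI is positive.

    Neurons pass when their RF is reproducible across the two original
    presentations: SI significantly greater than 0 at *alpha*.
    """
    if si_error <= 0:
        raise ValueError("si_error must be positive")
    z = si_control / si_error
    return bool(stats.norm.sf(z) < alpha)


def bootstrap_si_error(counts_a, counts_b, n_boot: int = 500,
                       seed: int = 0) -> float:
    """Resampling cross-check of the delta-method SI error.

    Trial rows of both count matrices (trials x directions) are resampled
    with replacement; returns the standard deviation of the SI across
    resamples.
    """
    rng = np.random.default_rng(seed)
    a = np.atleast_2d(np.asarray(counts_a, dtype=float))
    b = np.atleast_2d(np.asarray(counts_b, dtype=float))
    sis = []
    for _ in range(n_boot):
        ia = rng.integers(0, a.shape[0], a.shape[0])
        ib = rng.integers(0, b.shape[0], b.shape[0])
        try:
            sis.append(cosine_si(a[ia].mean(axis=0), b[ib].mean(axis=0)).si)
        except ValueError:
            continue
    return float(np.std(sis, ddof=1))


# ---------------------------------------------------------------------------
# Extended-ILD tuning classification
# ---------------------------------------------------------------------------

@dataclass
class IldTuningClass:
    """Shape of the firing rate vs ILD curve: flat, monotonic or peaked."""

    label: str                      # "flat" | "monotonic" | "peaked"
    chi2_flat: float
    p_flat: float
    peak_p_values: np.ndarray | None = None


def ild_tuning_classify(mean_counts, n_trials, phi: float,
                        alpha: float = 0.01) -> IldTuningClass:
    """Classify a neuron's response curve over the 41 ILD levels.

    Flatness: chi-square of the per-level mean counts against the grand
    mean with quasi-Poisson variances ``phi * mean / n_trials`` (dof =
    n_levels - 1); non-flat at ``p < alpha``.  A non-flat neuron is
    "peaked" if some interior level's rate significantly (Bonferroni over
    the tested levels) exceeds the rate at *both* extreme levels (+-40
    dB); otherwise it is "monotonic".
    """
    m = np.asarray(mean_counts, dtype=float)
    nt = np.broadcast_to(np.asarray(n_trials, dtype=float), m.shape)
    if m.ndim != 1 or len(m) < 3:
        raise ValueError("need mean counts for the full set of ILD levels")
    if np.any(~np.isfinite(m)) or np.any(nt < 1):
        raise ValueError("missing levels or empty trials")
    phi = max(float(phi), 1.0)
    grand = m.mean()
    var_mean = phi * np.maximum(grand, 1e-12) / nt
    chi2 = float(np.sum((m - grand) ** 2 / var_mean))
    dof = len(m) - 1
    p_flat = float(stats.chi2.sf(chi2, dof))
    if p_flat >= alpha:
        return IldTuningClass(label="flat", chi2_flat=chi2, p_flat=p_flat)

    # peak test: interior level vs both extremes, quasi-Poisson z-tests
    var_lvl = phi * np.maximum(m, 1e-12) / nt
    interior = np.arange(1, len(m) - 1)
    p_peak = np.ones(len(interior))
    for k, i in enumerate(interior):
        zs = [(m[i] - m[j]) / np.sqrt(var_lvl[i] + var_lvl[j])
              for j in (0, len(m) - 1)]
        # must beat BOTH edges: the larger of the two one-sided p-values
        p_peak[k] = max(stats.norm.sf(z) for z in zs)
    bonferroni = len(interior)
    label = "peaked" if np.any(p_peak * bonferroni < alpha) else "monotonic"
    return IldTuningClass(label=label, chi2_flat=chi2, p_flat=p_flat,
                          peak_p_values=p_peak)
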