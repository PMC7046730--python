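"""Topographic-map regression with statistical plus systematic errors.

The azimuthal auditory map is characterized by regressing fitted RF
azimuths on the anteroposterior (A-P) position of the neurons in the
superior colliculus.  Per-neuron statistical errors (from the Kent fit
Hessian) understate the scatter: animal-to-animal HRTF differences, pinna
and eye movement contribute an estimated +-19 deg systematic error which
is added in quadrature to every point before the chi-square line fit.
Only neurons with low-elevation RFs (< 30 deg, where the front-z and
top-z frames nearly coincide) enter the azimuthal map.

A-P positions across recordings are registered by the visual map of the
overlying superficial layers: the visual RF azimuth measured on each probe
shank is extrapolated to its zero crossing, which defines the A-P origin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TopographicMapModel",
    "TopographicMapResults",
    "fit_topographic_map",
    "estimate_ap_positions",
]

#: default quadrature-combined systematic pointing error per neuron, degrees
DEFAULT_SYSTEMATIC_ERROR_DEG = 19.0


class TopographicMapModel:
    """Weighted straight-line model ``azimuth = offset + slope * position``.

    Parameters
    ----------
    positions_mm : array
        A-P positions of the neurons (mm; positive inside the SC).
    azimuths_deg : array
        Fitted RF azimuths (top-z frame, degrees).
    stat_errors_deg : array
        Per-neuron statistical errors of the azimuth.
    systematic_error_deg : float
        Added in quadrature to every point (default 19 deg).
    """

    def __init__(self, positions_mm, azimuths_deg, stat_errors_deg,
                 systematic_error_deg: float = DEFAULT_SYSTEMATIC_ERROR_DEG):
        x = np.asarray(positions_mm, dtype=float)
        y = np.asarray(azimuths_deg, dtype=float)
        se = np.asarray(stat_errors_deg, dtype=float)
        if not (len(x) == len(y) == len(se)):
            raise ValueError("positions, azimuths and errors must align")
        if len(x) < 3:
            raise ValueError("need at least 3 points for a map fit")
        if np.ptp(x) <= 0:
            raise ValueError("positions are degenerate (all identical)")
        self.x, self.y = x, y
        self.sigma = np.sqrt(se ** 2 + systematic_error_deg ** 2)
        self.systematic_error_deg = float(systematic_error_deg)

    def fit(self) -> "TopographicMapResults":
        w = 1.0 / self.sigma ** 2
        s = w.sum()
        sx = (w * self.x).sum()
        sy = (w * self.y).sum()
        sxx = (w * self.x ** 2).sum()
        sxy = (w * self.x * self.y).sum()
        delta = s * sxx - sx ** 2
        slope = (s * sxy - sx * sy) / delta
        offset = (sxx * sy - sx * sxy) / delta
        slope_err = np.sqrt(s / delta)
        offset_err = np.sqrt(sxx / delta)
        resid = self.y - offset - slope * self.x
        chi2 = float(np.sum((resid / self.sigma) ** 2))
        dof = len(self.x) - 2
        r = float(np.corrcoef(self.x, self.y)[0, 1])
        return TopographicMapResults(
            slope=float(slope), offset=float(offset),
            slope_error=float(slope_err), offset_error=float(offset_err),
            chi2=chi2, dof=dof, pearson_r=r,
            systematic_error_deg=self.systematic_error_deg, n_points=len(self.x))


@dataclass
class TopographicMapResults:
    """Map slope/offset with errors, chi-square quality and correlation."""

    slope: float            # deg / mm
    offset: float           # deg
    slope_error: float
    offset_error: float
    chi2: float
    dof: int
    pearson_r: float
    systematic_error_deg: float
    n_points: int

    @property
    def chi2_per_dof(self) -> float:
        return self.chi2 / self.dof

    def to_dict(self) -> dict:
        return {
            "slope_deg_per_mm": self.slope, "slope_error": self.slope_error,
            "offset_deg": self.offset, "offset_error": self.offset_error,
            "chi2": self.chi2, "dof": self.dof,
            "chi2_per_dof": self.chi2_per_dof, "pearson_r": self.pearson_r,
            "systematic_error_deg": self.systematic_error_deg,
            "n_points": self.n_points,
        }

    def summary(self) -> str:
        return "\n".join([
            "Topographic map fit (weighted least squares)",
            "=" * 46,
            f"{'points':<24}{self.n_points:>10d}",
            f"{'slope (deg/mm)':<24}{self.slope:>10.1f} +- {self.slope_error:.1f}",
            f"{'offset (deg)':<24}{self.offset:>10.1f} +- {self.offset_error:.1f}",
            f"{'chi2 / dof':<24}{self.chi2_per_dof:>10.2f}",
            f"{'Pearson r':<24}{self.pearson_r:>10.2f}",
            f"{'systematic error (deg)':<24}{self.systematic_error_deg:>10.1f}",
        ])


def fit_topographic_map(positions_mm, azimuths_deg, stat_errors_deg,
                        systematic_error_deg: float = DEFAULT_SYSTEMATIC_ERROR_DEG
                        ) -> TopographicMapResults:
    """Convenience wrapper around :class:`TopographicMapModel`."""
    return TopographicMapModel(positions_mm, azimuths_deg, stat_errors_deg,
                               systematic_error_deg).fit()


def estimate_ap_positions(shank_positions_mm, visual_rf_azimuths_deg,
                          neuron_positions_mm=None):
    """Register A-P positions to the visual-map zero crossing.

    A line is fitted to (shank position, visual RF azimuth); the position
    where the visual azimuth extrapolates to 0 deg defines the A-P origin.
    Returns the neuron positions (default: the shank positions) shifted so
    the origin is at 0.  Neurons at negative positions should be excluded
    downstream (they lie outside the mapped structure).
    """
    x = np.asarray(shank_positions_mm, dtype=float)
    y = np.asarray(visual_rf_azimuths_deg, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 shanks with visual azimuths")
    slope, intercept = np.polyfit(x, y, 1)
    if abs(slope) < 1e-12:
        raise ValueError("visual azimuths are constant; zero crossing undefined")
    origin = -intercept / slope
    pos = x if neuron_positions_mm is None else np.asarray(neuron_positions_mm,
                                                           dtype=float)
    return pos - origin
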