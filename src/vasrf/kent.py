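"""Kent-distribution receptive-field model fitted by maximum quasi-likelihood.

The spatial receptive field (RF) of an auditory neuron is modelled as a
Kent (Fisher-Bingham 5-parameter) distribution on the sphere,

    f(x) = exp(-kappa) * exp{ kappa g1.x + beta [ (g2.x)^2 - (g3.x)^2 ] },

where ``x`` is a unit direction vector, ``kappa > 0`` is the concentration
(RF size), ``beta`` the ellipticity (fit-restricted to ``4 beta < kappa``),
``g1`` the RF center and ``g2``/``g3`` the major/minor axes (an orthonormal
triple).  The density is normalized to 1 at ``x = g1``, so it acts as a
dimensionless spatial gain on top of a baseline rate:

    mu(direction) = b + A * f(direction).

Trial-by-trial spike counts of midbrain neurons are overdispersed
(variance = phi * mean with phi ~ 5 rather than the Poissonian phi = 1),
so the likelihood is a quasi-Poisson one: a negative-binomial likelihood
moment-matched to (mean mu, variance phi*mu) with a fixed plug-in phi,
reducing to the exact Poisson likelihood at phi = 1.  An RF is called
significant when the Kent rate model beats a flat (direction-independent)
rate model by BIC.

The Kent distribution was preferred over a two-dimensional Gaussian
because RFs span a large part of the sphere, where the curvature of the
coordinate system matters; at large kappa the two coincide.  Fits are done
in the top-Z frame (polar axis dorsal) to keep the azimuth continuous
across the midline, while HRIR grids are measured in the front-Z frame
(polar axis rostral); the model converts internally and the Kent density
itself is frame-independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, gammaln

__all__ = [
    "KentParams",
    "kent_density",
    "radius_from_kappa",
    "direction_to_vector",
    "vector_to_direction",
    "convert_frame",
    "KentReceptiveFieldModel",
    "KentReceptiveFieldResults",
    "fit_kent",
]

FRAMES = ("front-z", "top-z")


# ---------------------------------------------------------------------------
# Spherical coordinate frames
# ---------------------------------------------------------------------------
#
# Common Cartesian axes: X rostral (front), Y left, Z dorsal (up).
# Azimuth is positive toward the contralateral (right) side, elevation 0 is
# the horizontal plane in both frames.
#
# top-z  : polar axis Z.  v = (cos e cos a, -cos e sin a, sin e)
# front-z: polar axis X; the azimuth is the (signed) angle from the rostral
#          axis and the elevation rotates the direction about that axis:
#          v = (cos a, -sin|a| cos e * sign(a), sin|a| sin e)
#
# On the horizontal plane (e = 0) the two frames agree.

def direction_to_vector(direction, frame: str = "top-z") -> np.ndarray:
    """Unit vector(s) for (azimuth_deg, elevation_deg) pairs."""
    d = np.atleast_2d(np.asarray(direction, dtype=float))
    az = np.radians(d[:, 0])
    el = np.radians(d[:, 1])
    if frame == "top-z":
        v = np.column_stack([np.cos(el) * np.cos(az),
                             -np.cos(el) * np.sin(az),
                             np.sin(el)])
    elif frame == "front-z":
        s = np.sin(np.abs(az))
        v = np.column_stack([np.cos(az),
                             -np.sign(az) * s * np.cos(el),
                             s * np.sin(el)])
    else:
        raise ValueError(f"unknown frame {frame!r}; expected one of {FRAMES}")
    return v[0] if np.ndim(direction) == 1 else v


def vector_to_direction(v, frame: str = "top-z") -> np.ndarray:
    """(azimuth_deg, elevation_deg) for unit vector(s); inverse of above.

    At a frame's pole the azimuth (front-z: elevation) is undefined and is
    canonicalized to 0.
    """
    w = np.atleast_2d(np.asarray(v, dtype=float))
    w = w / np.linalg.norm(w, axis=1, keepdims=True)
    x, y, z = w[:, 0], w[:, 1], w[:, 2]
    if frame == "top-z":
        el = np.degrees(np.arcsin(np.clip(z, -1, 1)))
        az = np.degrees(np.arctan2(-y, x))
        az = np.where(np.isclose(np.abs(z), 1.0), 0.0, az)
    elif frame == "front-z":
        mag = np.degrees(np.arccos(np.clip(x, -1, 1)))
        sign = np.where(y > 0, -1.0, 1.0)
        az = sign * mag
        lat = np.hypot(y, z)
        el = np.where(lat > 1e-12, np.degrees(np.arctan2(z, np.abs(y))), 0.0)
    else:
        raise ValueError(f"unknown frame {frame!r}; expected one of {FRAMES}")
    out = np.column_stack([az, el])
    return out[0] if np.ndim(v) == 1 else out


def convert_frame(direction, from_frame: str, to_frame: str):
    """Exact change of spherical frame; round-trip is the identity."""
    return vector_to_direction(direction_to_vector(direction, from_frame),
                               to_frame)


def _tangent_basis(az_deg: float, el_deg: float, frame: str = "top-z"):
    """Orthonormal (east, north) tangent vectors at a top-z direction."""
    az, el = np.radians(az_deg), np.radians(el_deg)
    if frame != "top-z":
        raise ValueError("tangent basis is defined in the top-z frame")
    # d/daz (normalized) and d/del of the top-z embedding
    e_az = np.array([-np.sin(az), -np.cos(az), 0.0])
    e_el = np.array([-np.sin(el) * np.cos(az), np.sin(el) * np.sin(az),
                     np.cos(el)])
    return e_az, e_el


# ---------------------------------------------------------------------------
# Kent parameters and density
# ---------------------------------------------------------------------------

@dataclass
class KentParams:
    """Parameters of a Kent RF: concentration, ellipticity, axis triple."""

    kappa: float
    beta: float
    gamma1: np.ndarray
    gamma2: np.ndarray
    gamma3: np.ndarray

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if not (0 <= 2 * self.beta < self.kappa + 1e-12):
            raise ValueError("ellipticity must satisfy 0 <= 2*beta < kappa")
        g = np.array([self.gamma1, self.gamma2, self.gamma3], dtype=float)
        if not np.allclose(g @ g.T, np.eye(3), atol=1e-8):
            raise ValueError("gamma1..3 must form an orthonormal triple")
        self.gamma1, self.gamma2, self.gamma3 = g

    @classmethod
    def from_angles(cls, azimuth_deg: float, elevation_deg: float,
                    psi_deg: float, kappa: float, beta: float,
                    frame: str = "top-z") -> "KentParams":
        """Build the axis triple from center angles and an orientation."""
        if frame != "top-z":
            azimuth_deg, elevation_deg = convert_frame(
                (azimuth_deg, elevation_deg), frame, "top-z")
        g1 = direction_to_vector((azimuth_deg, elevation_deg), "top-z")
        e_az, e_el = _tangent_basis(azimuth_deg, elevation_deg)
        psi = np.radians(psi_deg)
        g2 = np.cos(psi) * e_az + np.sin(psi) * e_el
        g3 = -np.sin(psi) * e_az + np.cos(psi) * e_el
        return cls(kappa=float(kappa), beta=float(beta),
                   gamma1=g1, gamma2=g2, gamma3=g3)

    @property
    def center(self) -> np.ndarray:
        """(azimuth, elevation) of the RF center in the top-z frame."""
        return vector_to_direction(self.gamma1, "top-z")


def kent_density(x, params: KentParams):
    """Kent density normalized to 1 at the center direction ``gamma1``.

    ``x`` is a unit 3-vector or an (N, 3) array of unit vectors.
    """
    v = np.atleast_2d(np.asarray(x, dtype=float))
    norms = np.linalg.norm(v, axis=1)
    if not np.allclose(norms, 1.0, atol=1e-6):
        raise ValueError("x must be a unit vector (or unit rows)")
    expo = (params.kappa * (v @ params.gamma1)
            + params.beta * ((v @ params.gamma2) ** 2 - (v @ params.gamma3) ** 2))
    out = np.exp(expo - params.kappa)
    return float(out[0]) if np.ndim(x) == 1 else out


def radius_from_kappa(kappa: float) -> float:
    """RF radius (degrees) from the concentration parameter.

    Defined by ``rho = arccos(1 - 1/(2 kappa))``: for negligible beta the
    density falls to exp(-1/2) of its peak at angular distance rho, the
    analogue of one Gaussian sigma.  For kappa <= 0.5 the radius is
    clipped at 90 degrees (with a warning): the RF is wider than a
    hemifield and the definition saturates.
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    if kappa <= 0.5:
        warnings.warn("kappa <= 0.5: RF radius clipped at 90 degrees",
                      stacklevel=2)
        return 90.0
    return float(np.degrees(np.arccos(1.0 - 1.0 / (2.0 * kappa))))


# ---------------------------------------------------------------------------
# Quasi-likelihood for overdispersed counts
# ---------------------------------------------------------------------------

def _count_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> float:
    """Log-likelihood of counts with mean mu and variance phi*mu.

    phi == 1: exact Poisson.  phi > 1: negative binomial moment-matched to
    (mu, phi*mu), i.e. r = mu/(phi-1), p = 1/phi.
    """
    mu = np.maximum(mu, 1e-12)
    if phi <= 1.0 + 1e-9:
        return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1)))
    r = mu / (phi - 1.0)
    logp = -np.log(phi)
    log1mp = np.log1p(-1.0 / phi)
    return float(np.sum(gammaln(y + r) - gammaln(r) - gammaln(y + 1)
                        + r * logp + y * log1mp))


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

_PARAM_NAMES = ("azimuth", "elevation", "psi", "kappa", "beta",
                "baseline", "amplitude")


class KentReceptiveFieldModel:
    """Kent rate model ``mu(dir) = b + A * Kent(dir)`` for trial counts.

    Parameters
    ----------
    counts : (n_trials, n_directions) array of int
        Spike counts in the analysis window, one column per direction.
    directions : (n_directions, 2) array
        ``(azimuth_deg, elevation_deg)`` in *frame*.
    phi : float
        Plug-in overdispersion (variance/mean ratio) used by the
        quasi-likelihood; estimate it with
        :func:`vasrf.spikes.estimate_overdispersion`.
    frame : str
        Frame of *directions*; converted to top-z internally.
    """

    #: fit constraint: beta < kappa / BETA_DIVISOR (stability restriction)
    BETA_DIVISOR = 4.0
    AZ_RANGE = (-144.0, 144.0)
    EL_RANGE = (0.0, 90.0)

    def __init__(self, counts, directions, phi: float = 1.0,
                 frame: str = "front-z"):
        counts = np.atleast_2d(np.asarray(counts, dtype=float))
        directions = np.asarray(directions, dtype=float)
        if counts.shape[1] != len(directions):
            raise ValueError("counts must be (n_trials, n_directions)")
        if counts.shape[0] < 2:
            raise ValueError("need at least 2 trials per direction")
        if len(np.unique(directions[:, 1])) < 2:
            raise ValueError("directions must span at least 2 elevations")
        if np.any(counts < 0):
            raise ValueError("counts must be nonnegative")
        self.counts = counts
        self.directions = directions
        self.frame = frame
        self.phi = max(float(phi), 1.0)
        self.vectors = direction_to_vector(directions, frame)
        self._y = counts.ravel(order="F")  # grouped by direction
        self._dir_index = np.repeat(np.arange(len(directions)), counts.shape[0])
        self.nobs = self._y.size

    # -- likelihood ---------------------------------------------------------

    def _mu_by_direction(self, theta: np.ndarray) -> np.ndarray:
        # unvalidated density evaluation: finite-difference probes may step
        # just outside the (kappa, beta) constraint region
        az, el, psi, kappa, beta, b, amp = theta
        g1 = direction_to_vector((az, el), "top-z")
        e_az, e_el = _tangent_basis(az, el)
        sp, cp = np.sin(np.radians(psi)), np.cos(np.radians(psi))
        g2 = cp * e_az + sp * e_el
        g3 = -sp * e_az + cp * e_el
        v = self.vectors
        dens = np.exp(kappa * (v @ g1 - 1.0)
                      + beta * ((v @ g2) ** 2 - (v @ g3) ** 2))
        return b + amp * dens

    def loglike(self, theta: np.ndarray) -> float:
        """Quasi-log-likelihood at natural parameters
        (azimuth, elevation, psi, kappa, beta, baseline, amplitude)."""
        mu = self._mu_by_direction(theta)[self._dir_index]
        return _count_loglik(self._y, mu, self.phi)

    def loglike_flat(self) -> float:
        mu = np.full_like(self._y, self._y.mean())
        return _count_loglik(self._y, mu, self.phi)

    # -- optimization -------------------------------------------------------

    def _theta_from_opt(self, x: np.ndarray) -> np.ndarray:
        az, el, psi, log_kappa, v, log_b, log_a = x
        kappa = np.exp(log_kappa)
        beta = kappa / self.BETA_DIVISOR * expit(v)
        return np.array([az, el, psi, kappa, beta,
                         np.exp(log_b), np.exp(log_a)])

    def _objective(self, x: np.ndarray) -> float:
        ll = self.loglike(self._theta_from_opt(x))
        return -ll if np.isfinite(ll) else 1e12

    def _starts(self):
        """Initial points: top response directions +- neighbors, two kappas.

        The argmax of the mean per-direction response seeds the center
        (ties broken by the lowest direction index, np.argsort stability).
        """
        mean_by_dir = self.counts.mean(axis=0)
        order = np.argsort(-mean_by_dir, kind="stable")
        tops = order[:3]
        b0 = max(mean_by_dir.min(), 1e-3)
        a0 = max(mean_by_dir.max() - mean_by_dir.min(), 1e-2)
        starts = []
        for i in tops:
            az, el = convert_frame(self.directions[i], self.frame, "top-z")
            az = np.clip(az, *self.AZ_RANGE)
            el = np.clip(el, *self.EL_RANGE)
            for kappa0 in (3.0, 15.0):
                starts.append(np.array([az, el, 0.0, np.log(kappa0), -2.0,
                                        np.log(b0), np.log(a0)]))
        return starts

    def fit(self, maxiter: int = 300) -> "KentReceptiveFieldResults":
        bounds = [self.AZ_RANGE, self.EL_RANGE, (-90.0, 90.0),
                  (np.log(0.2), np.log(500.0)), (-12.0, 12.0),
                  (np.log(1e-4), np.log(1e3)), (np.log(1e-4), np.log(1e4))]
        best = None
        for x0 in self._starts():
            res = minimize(self._objective, x0, method="L-BFGS-B",
                           bounds=bounds, options={"maxiter": maxiter})
            if best is None or res.fun < best.fun:
                best = res
        converged = best is not None and np.isfinite(best.fun) and best.fun < 1e11
        theta = self._theta_from_opt(best.x)
        llf = -best.fun
        bic_kent = -2.0 * llf + len(theta) * np.log(self.nobs)
        llf_flat = self.loglike_flat()
        bic_flat = -2.0 * llf_flat + 1.0 * np.log(self.nobs)
        bse = self._hessian_errors(theta) if converged else np.full(7, np.nan)
        return KentReceptiveFieldResults(
            model=self, theta=theta, bse=bse, llf=llf, llf_flat=llf_flat,
            bic=bic_kent, bic_flat=bic_flat, converged=converged)

    def _hessian_errors(self, theta: np.ndarray) -> np.ndarray:
        """Central-difference Hessian of -loglike; errors = sqrt(diag(H^-1))."""
        steps = np.array([0.5, 0.5, 1.0, max(1e-3 * theta[3], 1e-4),
                          max(1e-3 * theta[3], 1e-4),
                          max(1e-3 * theta[5], 1e-5),
                          max(1e-3 * theta[6], 1e-5)])
        n = len(theta)
        h = np.zeros((n, n))

        def f(t):
            ll = self.loglike(t)
            return -ll if np.isfinite(ll) else 1e12

        f0 = f(theta)
        for i in range(n):
            for j in range(i, n):
                ei = np.zeros(n); ei[i] = steps[i]
                ej = np.zeros(n); ej[j] = steps[j]
                if i == j:
                    val = (f(theta + ei) - 2 * f0 + f(theta - ei)) / steps[i] ** 2
                else:
                    val = (f(theta + ei + ej) - f(theta + ei - ej)
                           - f(theta - ei + ej) + f(theta - ei - ej)) \
                        / (4 * steps[i] * steps[j])
                h[i, j] = h[j, i] = val
        with np.errstate(invalid="ignore"):
            cov = np.linalg.pinv(h)
            var = np.clip(np.diag(cov), 0.0, None)
        return np.sqrt(var)


@dataclass
class KentReceptiveFieldResults:
    """Fitted Kent RF: estimates, Hessian errors, BIC pair, radius."""

    model: KentReceptiveFieldModel
    theta: np.ndarray
    bse: np.ndarray
    llf: float
    llf_flat: float
    bic: float
    bic_flat: float
    converged: bool

    @property
    def params(self) -> KentParams:
        az, el, psi, kappa, beta, _, _ = self.theta
        return KentParams.from_angles(az, el, psi, kappa, beta)

    @property
    def azimuth(self) -> float:
        """RF center azimuth, degrees, top-z frame."""
        return float(self.theta[0])

    @property
    def elevation(self) -> float:
        return float(self.theta[1])

    @property
    def kappa(self) -> float:
        return float(self.theta[3])

    @property
    def beta(self) -> float:
        return float(self.theta[4])

    @property
    def baseline(self) -> float:
        return float(self.theta[5])

    @property
    def amplitude(self) -> float:
        return float(self.theta[6])

    @property
    def azimuth_error(self) -> float:
        return float(self.bse[0])

    @property
    def elevation_error(self) -> float:
        return float(self.bse[1])

    @property
    def radius_deg(self) -> float:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return radius_from_kappa(self.kappa)

    @property
    def significant(self) -> bool:
        """Kent rate model preferred over a flat rate model by BIC."""
        return bool(self.converged and self.bic < self.bic_flat)

    def predicted_rates(self) -> np.ndarray:
        """Model mean count per direction at the fitted parameters."""
        return self.model._mu_by_direction(self.theta)

    def to_dict(self) -> dict:
        d = {name: float(v) for name, v in zip(_PARAM_NAMES, self.theta)}
        d.update({f"{name}_error": float(e)
                  for name, e in zip(_PARAM_NAMES, self.bse)})
        d.update(llf=float(self.llf), bic_kent=float(self.bic),
                 bic_flat=float(self.bic_flat), radius_deg=self.radius_deg,
                 significant=self.significant, converged=self.converged,
                 frame="top-z", phi=self.model.phi)
        return d

    def summary(self) -> str:
        lines = ["Kent receptive-field fit (top-z frame)",
                 "=" * 46,
                 f"{'observations':<22}{self.model.nobs:>10d}",
                 f"{'overdispersion phi':<22}{self.model.phi:>10.3f}",
                 f"{'log quasi-likelihood':<22}{self.llf:>10.2f}",
                 f"{'BIC (Kent / flat)':<22}{self.bic:>10.1f} / {self.bic_flat:.1f}",
                 f"{'significant RF':<22}{str(self.significant):>10}",
                 "-" * 46,
                 f"{'parameter':<12}{'estimate':>12}{'std err':>12}"]
        for name, v, e in zip(_PARAM_NAMES, self.theta, self.bse):
            lines.append(f"{name:<12}{v:>12.3f}{e:>12.3f}")
        lines.append(f"{'radius (deg)':<12}{self.radius_deg:>12.2f}")
        return "\n".join(lines)


def fit_kent(counts, directions, phi: float = 1.0,
             frame: str = "front-z") -> KentReceptiveFieldResults:
    """Convenience wrapper: build the model and fit in one call."""
    return KentReceptiveFieldModel(counts, directions, phi=phi,
                                   frame=frame).fit()
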