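"""Kent density identities, coordinate frames, RF fitting and topography."""

import numpy as np
import pytest

from vasrf.kent import (KentParams, KentReceptiveFieldModel, convert_frame,
                        direction_to_vector, fit_kent, kent_density,
                        radius_from_kappa, vector_to_direction)
from vasrf.synth import SyntheticNeuron, simulate_kent_responses
from vasrf.topography import (estimate_ap_positions, fit_topographic_map)


def _params(az=30.0, el=20.0, psi=0.0, kappa=10.0, beta=0.0):
    return KentParams.from_angles(az, el, psi, kappa, beta)


class TestKentDensity:
    def test_normalized_to_one_at_center(self):
        p = _params()
        assert kent_density(p.gamma1, p) == pytest.approx(1.0)

    def test_half_gaussian_contour_at_defined_radius(self):
        # with beta = 0 the density is exp(-1/2) where g1.x = 1 - 1/(2 kappa)
        for kappa in (0.7, 2.0, 25.0):
            p = _params(kappa=kappa)
            rho = np.radians(radius_from_kappa(kappa))
            x = direction_to_vector(
                (p.center[0], p.center[1] - np.degrees(rho)))
            assert kent_density(x, p) == pytest.approx(np.exp(-0.5), rel=1e-9)

    def test_antipode_value(self):
        p = _params(kappa=3.0)
        assert kent_density(-p.gamma1, p) == pytest.approx(np.exp(-6.0))

    def test_non_unit_vector_rejected(self):
        with pytest.raises(ValueError):
            kent_density(np.array([0.5, 0.0, 0.0]), _params())

    def test_invariant_under_axis_sign_flip(self, rng):
        p = _params(psi=25.0, kappa=8.0, beta=1.5)
        flipped = KentParams(kappa=p.kappa, beta=p.beta, gamma1=p.gamma1,
                             gamma2=-p.gamma2, gamma3=-p.gamma3)
        v = rng.standard_normal((50, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        assert np.allclose(kent_density(v, p), kent_density(v, flipped))

    def test_gaussian_limit_at_large_kappa(self):
        """Inside one radius of the center, kappa >= 50 matches the 2-D
        Gaussian exp(-kappa theta^2 / 2) within 1%."""
        kappa = 50.0
        p = _params(az=0.0, el=0.0, kappa=kappa)
        rho = np.radians(radius_from_kappa(kappa))
        for theta in np.linspace(0.0, rho, 8):
            x = direction_to_vector((np.degrees(theta), 0.0))
            gauss = np.exp(-kappa * theta ** 2 / 2.0)
            assert kent_density(x, p) == pytest.approx(gauss, rel=0.01)

    def test_ellipticity_constraint_enforced(self):
        with pytest.raises(ValueError):
            _params(kappa=2.0, beta=1.5)


class TestRadius:
    def test_kappa_half_is_90_degrees(self):
        with pytest.warns(UserWarning):
            assert radius_from_kappa(0.5) == 90.0

    def test_kappa_2_matches_closed_form(self):
        assert radius_from_kappa(2.0) == pytest.approx(
            np.degrees(np.arccos(0.75)))
        assert radius_from_kappa(2.0) == pytest.approx(41.41, abs=0.01)

    def test_monotone_decreasing_to_zero(self):
        kappas = np.array([1.0, 5.0, 50.0, 5000.0])
        radii = [radius_from_kappa(k) for k in kappas]
        assert np.all(np.diff(radii) < 0)
        assert radii[-1] < 1.0

    def test_nonpositive_kappa_rejected(self):
        with pytest.raises(ValueError):
            radius_from_kappa(0.0)


class TestFrames:
    def test_round_trip_identity(self, rng):
        az = rng.uniform(-170, 170, 1000)
        el = rng.uniform(-85, 85, 1000)
        d = np.column_stack([az, el])
        for frame in ("top-z", "front-z"):
            back = vector_to_direction(direction_to_vector(d, frame), frame)
            assert np.allclose(back, d, atol=1e-10)

    def test_cross_frame_round_trip(self, rng):
        az = rng.uniform(-140, 140, 300)
        el = rng.uniform(1.0, 80.0, 300)
        d = np.column_stack([az, el])
        there = convert_frame(d, "front-z", "top-z")
        back = convert_frame(there, "top-z", "front-z")
        assert np.allclose(back, d, atol=1e-9)

    def test_horizontal_plane_azimuth_preserved(self):
        for az in (-120.0, -30.0, 0.0, 75.0):
            out = convert_frame((az, 0.0), "front-z", "top-z")
            assert out[0] == pytest.approx(az, abs=1e-9)
            assert out[1] == pytest.approx(0.0, abs=1e-9)

    def test_pole_canonicalization(self):
        # the top-z pole has no defined azimuth; canonicalized to 0
        out = vector_to_direction(np.array([0.0, 0.0, 1.0]), "top-z")
        assert out[0] == 0.0 and out[1] == pytest.approx(90.0)
        # the front-z pole (straight ahead) has no defined elevation
        out = vector_to_direction(np.array([1.0, 0.0, 0.0]), "front-z")
        assert out[0] == pytest.approx(0.0) and out[1] == 0.0

    def test_unknown_frame_rejected(self):
        with pytest.raises(ValueError):
            convert_frame((0.0, 0.0), "side-z", "top-z")


class TestKentFit:
    def test_center_recovered_within_fitted_errors(self, grid):
        """Known-center synthetic neurons are recovered within 2 sigma in
        at least 90% of seeded runs."""
        hits = trials = 0
        for seed in range(12):
            rng = np.random.default_rng(seed)
            az = float(rng.uniform(10, 110))
            el = float(rng.uniform(5, 25))
            nrn = SyntheticNeuron(azimuth_deg=az, elevation_deg=el,
                                  kappa=4.0, phi=5.0)
            counts = simulate_kent_responses([nrn], grid.directions,
                                             n_trials=30, seed=seed + 100,
                                             frame=grid.frame)[0]
            fit = fit_kent(counts, grid.directions, phi=5.0, frame=grid.frame)
            if not fit.converged:
                continue
            trials += 1
            err = max(fit.azimuth_error, 1e-6)
            if abs(fit.azimuth - az) < 2 * max(err, 2.0):
                hits += 1
        assert trials >= 10
        assert hits / trials >= 0.9

    def test_flat_rates_prefer_flat_model(self, grid, rng):
        counts = rng.poisson(1.0, size=(20, grid.n_directions))
        fit = fit_kent(counts, grid.directions, phi=1.0, frame=grid.frame)
        assert fit.bic_flat < fit.bic
        assert not fit.significant

    def test_error_shrinks_with_sqrt_trials(self, grid):
        nrn = SyntheticNeuron(azimuth_deg=40.0, elevation_deg=10.0,
                              kappa=5.0, phi=1.0)
        errs = []
        for n_trials in (20, 80):  # 4x trials -> half the error
            counts = simulate_kent_responses([nrn], grid.directions,
                                             n_trials=n_trials, seed=7,
                                             frame=grid.frame)[0]
            fit = fit_kent(counts, grid.directions, phi=1.0, frame=grid.frame)
            errs.append(fit.azimuth_error)
        assert errs[1] / errs[0] == pytest.approx(0.5, abs=0.2)

    def test_rotation_invariance_of_concentration(self, grid):
        """Rigidly rotating all stimulus directions leaves kappa and the
        likelihood unchanged and moves the center correspondingly."""
        nrn = SyntheticNeuron(azimuth_deg=50.0, elevation_deg=10.0,
                              kappa=5.0, phi=1.0)
        counts = simulate_kent_responses([nrn], grid.directions, n_trials=30,
                                         seed=3, frame=grid.frame)[0]
        fit = fit_kent(counts, grid.directions, phi=1.0, frame=grid.frame)
        # a top-z azimuth shift is a rigid rotation about the dorsal axis
        shift = 18.0
        rotated = convert_frame(grid.directions, grid.frame, "top-z")
        rotated[:, 0] -= shift
        fit_rot = fit_kent(counts, rotated, phi=1.0, frame="top-z")
        assert fit_rot.kappa == pytest.approx(fit.kappa, rel=0.05)
        assert fit_rot.llf == pytest.approx(fit.llf, abs=1.0)
        assert fit_rot.azimuth == pytest.approx(fit.azimuth - shift, abs=1.0)

    def test_requires_two_elevations(self):
        with pytest.raises(ValueError):
            KentReceptiveFieldModel(np.ones((5, 3)),
                                    [(0, 0), (18, 0), (36, 0)])

    def test_summary_mentions_key_quantities(self, grid):
        nrn = SyntheticNeuron(azimuth_deg=40.0, elevation_deg=10.0, phi=1.0)
        counts = simulate_kent_responses([nrn], grid.directions, n_trials=10,
                                         seed=0, frame=grid.frame)[0]
        s = fit_kent(counts, grid.directions, phi=1.0, frame=grid.frame)
        text = s.summary()
        for key in ("kappa", "BIC", "radius", "azimuth"):
            assert key in text


class TestTopography:
    def test_noiseless_collinear_points_exact(self):
        x = np.array([0.1, 0.5, 0.9, 1.3])
        y = 14.0 + 58.0 * x
        res = fit_topographic_map(x, y, np.full(4, 3.0))
        assert res.slope == pytest.approx(58.0)
        assert res.offset == pytest.approx(14.0)
        assert res.chi2 == pytest.approx(0.0, abs=1e-18)
        assert res.pearson_r == pytest.approx(1.0)

    def test_jittered_map_recovered_with_unit_chi2(self, rng):
        x = rng.uniform(0, 1.8, 120)
        y = 14.0 + 58.0 * x + rng.normal(0, 19.0, 120)
        res = fit_topographic_map(x, y, np.full(120, 3.0),
                                  systematic_error_deg=19.0)
        assert abs(res.slope - 58.0) < 2 * res.slope_error + 4.0
        assert 0.5 < res.chi2_per_dof < 1.5

    def test_omitting_systematic_error_inflates_chi2(self, rng):
        x = rng.uniform(0, 1.8, 120)
        y = 14.0 + 58.0 * x + rng.normal(0, 19.0, 120)
        res = fit_topographic_map(x, y, np.full(120, 3.0),
                                  systematic_error_deg=0.0)
        assert res.chi2_per_dof > 10.0

    def test_degenerate_positions_rejected(self):
        with pytest.raises(ValueError):
            fit_topographic_map([1.0, 1.0, 1.0], [0, 10, 20], [1, 1, 1])


class TestApRegistration:
    def test_zero_crossing_by_interpolation(self):
        out = estimate_ap_positions([0.0, 0.4], [-10.0, 10.0])
        assert out == pytest.approx([-0.2, 0.2])

    def test_constant_azimuths_rejected(self):
        with pytest.raises(ValueError):
            estimate_ap_positions([0.0, 0.4, 0.8], [5.0, 5.0, 5.0])

    def test_known_origin_recovered_noiselessly(self):
        shanks = np.array([0.0, 0.4, 0.8, 1.2])
        origin = 0.3
        visual = 73.0 * (shanks - origin)
        neurons = np.array([0.1, 0.9])
        out = estimate_ap_positions(shanks, visual, neurons)
        assert out == pytest.approx(neurons - origin)
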