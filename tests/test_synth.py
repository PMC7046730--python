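"""Ground-truth structure of the synthetic HRTFs and simulated neurons."""

import numpy as np
import pytest

from vasrf.hrtf import compute_ild, compute_itd, magnitude_spectrum_db
from vasrf.similarity import cosine_si, nsi_loss, reproducibility_filter
from vasrf.stimuli import chord_frequencies, frozen_grid, synthesize_vas
from vasrf.synth import (SyntheticHrtfSpec, SyntheticNeuron, grid_cues,
                         make_population, make_synthetic_hrtf, sample_counts,
                         simulate_cue_population, simulate_neuron_response,
                         synthetic_spectrum_db)


class TestSyntheticHrtf:
    def test_max_itd_matches_path_difference(self, grid, hrtf_spec):
        itds = [compute_itd(grid.ir_left[i], grid.ir_right[i],
                            grid.sample_rate)
                for i in range(grid.n_directions)]
        expected = (hrtf_spec.ear_separation_m
                    / hrtf_spec.sound_speed_m_s * 1e6)  # ~29 us
        assert np.max(np.abs(itds)) == pytest.approx(expected, abs=2.1)

    def test_ild_peaks_at_configured_azimuth(self, horizontal_grid):
        ct = compute_ild(horizontal_grid)
        horiz = ct.directions[:, 1] == 0.0
        peak = ct.directions[horiz][np.argmax(ct.ild_broadband_db[horiz])]
        assert peak[0] == 65.0

    def test_frontal_band_contrast(self, grid, hrtf_spec):
        i0 = grid.index_of((0.0, 0.0))
        f, db = magnitude_spectrum_db(grid.ir_right[i0], grid.sample_rate)
        amplified = db[(f >= 48e3) & (f <= 60e3)].mean()
        attenuated = db[(f >= 63e3) & (f <= 76e3)].mean()
        assert amplified - attenuated >= hrtf_spec.notch_depth_db / 2

    def test_out_of_range_grid_rejected(self):
        with pytest.raises(ValueError):
            SyntheticHrtfSpec(azimuths_deg=np.array([0.0, 150.0]))
        with pytest.raises(ValueError):
            SyntheticHrtfSpec(elevations_deg=np.array([0.0, 85.0]))


class TestNeuronDrives:
    def test_spectral_drive_peaks_at_preferred_direction(self, grid,
                                                         hrtf_spec):
        cues = grid_cues(grid)
        for az0 in (0.0, 54.0, 126.0):
            nrn = SyntheticNeuron(
                azimuth_deg=az0, elevation_deg=0.0,
                template_db=synthetic_spectrum_db(hrtf_spec, az0, 0.0,
                                                  "right",
                                                  chord_frequencies()))
            drive = nrn.spec_drive(cues)
            assert cues.directions[np.argmax(drive)][0] == az0

    def test_poisson_limit_at_phi_one(self, rng):
        draws = sample_counts(rng, np.full(10_000, 2.0), 1.0)
        phi_hat = draws.var(ddof=1) / draws.mean()
        assert abs(phi_hat - 1.0) < 3 * np.sqrt(2 / len(draws))

    def test_phi_below_one_rejected(self):
        with pytest.raises(ValueError):
            SyntheticNeuron(azimuth_deg=0.0, phi=0.5)
        with pytest.raises(ValueError):
            sample_counts(np.random.default_rng(0), np.ones(3), 0.9)

    def test_spectral_neuron_flat_under_frozen_spectrum(self, grid,
                                                        hrtf_spec):
        """With the spectrum frozen, a pure-spectral neuron's response
        carries no direction information (chi-square flatness holds)."""
        nrn = SyntheticNeuron(
            azimuth_deg=18.0, elevation_deg=0.0, w_spec=1.0, w_ild=0.0,
            phi=1.0,
            template_db=synthetic_spectrum_db(hrtf_spec, 18.0, 0.0, "right",
                                              chord_frequencies()))
        cues = grid_cues(frozen_grid(grid, "frozen_spectrum"))
        lam = nrn.expected_counts(cues)
        assert np.ptp(lam) < 1e-9  # identical expected rate everywhere
        rng = np.random.default_rng(0)
        counts = sample_counts(rng, np.tile(lam, (40, 1)), 1.0)
        m = counts.mean(axis=0)
        chi2 = np.sum((m - m.mean()) ** 2 / (m.mean() / 40))
        from scipy import stats
        assert stats.chi2.sf(chi2, len(m) - 1) > 0.001

    def test_ild_neuron_peaks_at_ild_maximum_under_frozen_spectrum(
            self, horizontal_grid):
        nrn = SyntheticNeuron(azimuth_deg=90.0, w_spec=0.0, w_ild=1.0)
        cues = grid_cues(frozen_grid(horizontal_grid, "frozen_spectrum"))
        lam = nrn.expected_counts(cues)
        horiz = cues.directions[:, 1] == 0.0
        best = cues.directions[horiz][np.argmax(lam[horiz])]
        assert best[0] == 65.0  # the grid's ILD-max azimuth

    def test_single_stimulus_cues_drive_counts(self, grid, hrtf_spec):
        nrn = SyntheticNeuron(
            azimuth_deg=0.0, elevation_deg=0.0, phi=1.0, gain_hz=400.0,
            template_db=synthetic_spectrum_db(hrtf_spec, 0.0, 0.0, "right",
                                              chord_frequencies()))
        pref = synthesize_vas((0.0, 0.0), grid, noise_seed=1)
        null = synthesize_vas((-144.0, 80.0), grid, noise_seed=1)
        c_pref = simulate_neuron_response(nrn, pref, seed=2, n_trials=200)
        c_null = simulate_neuron_response(nrn, null, seed=2, n_trials=200)
        assert c_pref.mean() > 2 * max(c_null.mean(), 0.1)


class TestPopulation:
    def test_zero_jitter_recovers_slope_exactly(self):
        neurons = make_population(2, map_slope_deg_mm=58.0,
                                  map_offset_deg=14.0, jitter_deg=0.0,
                                  positions_mm=[0.0, 1.0], seed=0)
        assert neurons[1].azimuth_deg - neurons[0].azimuth_deg \
            == pytest.approx(58.0)

    def test_regression_on_true_azimuths_recovers_slope(self):
        neurons = make_population(20, map_slope_deg_mm=58.0,
                                  map_offset_deg=14.0, jitter_deg=0.0,
                                  positions_mm=np.linspace(0.05, 1.6, 20),
                                  seed=0)
        x = [n.ap_position_mm for n in neurons]
        y = [n.azimuth_deg for n in neurons]
        slope = np.polyfit(x, y, 1)[0]
        assert slope == pytest.approx(58.0)

    def test_weights_cross_fade_with_azimuth(self):
        neurons = make_population(40, jitter_deg=0.0,
                                  positions_mm=np.linspace(0.0, 1.8, 40),
                                  seed=0)
        az = np.array([n.azimuth_deg for n in neurons])
        w_spec = np.array([n.w_spec for n in neurons])
        assert np.corrcoef(az, w_spec)[0, 1] < -0.9

    def test_kappa_decreases_with_azimuth(self):
        neurons = make_population(40, jitter_deg=0.0,
                                  positions_mm=np.linspace(0.0, 1.8, 40),
                                  seed=0)
        az = np.array([abs(n.azimuth_deg) for n in neurons])
        kappa = np.array([n.kappa for n in neurons])
        assert np.corrcoef(az, kappa)[0, 1] < -0.7

    def test_needs_at_least_one_neuron(self):
        with pytest.raises(ValueError):
            make_population(0)


@pytest.fixture(scope="module")
def nsi_table(grid, hrtf_spec):
    neurons = make_population(24, seed=5, hrtf_spec=hrtf_spec)
    conds = ("original", "control", "frozen_itd", "frozen_ild",
             "frozen_spectrum", "monaural_frozen_spectrum")
    rec = simulate_cue_population(neurons, grid, conds, n_trials=20,
                                  seed=6)
    rows = []
    for i, nrn in enumerate(neurons):
        ma = rec.counts["original"][i].mean(axis=0)
        ea = np.sqrt(np.maximum(rec.counts["original"][i].sum(axis=0),
                                1)) / 20
        sis = {}
        for c in conds[1:]:
            mb = rec.counts[c][i].mean(axis=0)
            eb = np.sqrt(np.maximum(rec.counts[c][i].sum(axis=0), 1)) / 20
            sis[c] = cosine_si(ma, mb, ea, eb)
        if not reproducibility_filter(sis["control"].si,
                                      max(sis["control"].si_error, 1e-9)):
            continue
        rows.append({
            "az": abs(nrn.azimuth_deg),
            "loss_itd": nsi_loss(sis["frozen_itd"].si,
                                 sis["control"].si),
            "loss_ild": nsi_loss(sis["frozen_ild"].si,
                                 sis["control"].si),
            "loss_spec": nsi_loss(sis["frozen_spectrum"].si,
                                  sis["control"].si),
            "loss_both": nsi_loss(sis["monaural_frozen_spectrum"].si,
                                  sis["control"].si),
        })
    assert len(rows) >= 10
    return rows


class TestCueDependenceStructure:
    """The qualitative fingerprint of the cue-freezing experiments."""

    def test_itd_freezing_harmless(self, nsi_table):
        losses = [r["loss_itd"] for r in nsi_table]
        assert abs(np.mean(losses)) < 0.15

    def test_loss_difference_anticorrelated_with_azimuth(self, nsi_table):
        az = [r["az"] for r in nsi_table]
        diff = [r["loss_spec"] - r["loss_ild"] for r in nsi_table]
        assert np.corrcoef(az, diff)[0, 1] < -0.3

    def test_combined_freezing_destroys_rfs(self, nsi_table):
        losses = [r["loss_both"] for r in nsi_table]
        assert np.mean(losses) > 0.8
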