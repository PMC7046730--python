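"""VAS synthesis, cue freezing, extended-ILD set and random chords."""

import numpy as np
import pytest

from vasrf.hrtf import HrirGrid, compute_ild, compute_itd, magnitude_spectrum_db
from vasrf.stimuli import (build_extended_ild_set, freeze_ild, freeze_itd,
                           freeze_spectrum, generate_random_chord,
                           make_monaural, synthesize_vas, tapered_noise)
from vasrf.synth import grid_cues


def _delta_grid(notch_hz=None):
    """Two-direction grid of near-delta HRIRs, optionally with a notch."""
    fs = 500e3
    n = 1024
    freqs = np.fft.rfftfreq(n, 1 / fs)
    gain = np.ones_like(freqs)
    if notch_hz is not None:
        # smooth-edged -30 dB notch (sharp edges would ring into the stopband)
        depth_db = -30.0 * np.exp(-((freqs - notch_hz) / 3e3) ** 2)
        gain = 10 ** (depth_db / 20)
    h = np.fft.irfft(gain * np.exp(-2j * np.pi * freqs * (64 / fs)), n)
    ir = np.vstack([h, h])
    return HrirGrid(sample_rate=fs, directions=[(0.0, 0.0), (18.0, 0.0)],
                    ir_left=ir.copy(), ir_right=ir.copy())


class TestVasSynthesis:
    def test_duration_and_linear_tapers(self):
        fs = 500e3
        x = tapered_noise(fs, duration=0.1, taper=0.005, seed=1)
        assert len(x) == int(0.1 * fs)
        # a linear ramp scales the leading samples by k/n_taper
        raw = tapered_noise(fs, duration=0.1, taper=0.0, seed=1)
        n_taper = int(0.005 * fs)
        ramp = x[:n_taper] / np.where(raw[:n_taper] == 0, 1, raw[:n_taper])
        assert np.allclose(ramp, np.arange(n_taper) / n_taper, atol=1e-12)

    def test_flat_hrir_keeps_band_spectrum_flat(self):
        g = _delta_grid()
        s = synthesize_vas((0.0, 0.0), g, noise_seed=3)
        f, db = magnitude_spectrum_db(s.right, g.sample_rate)
        band = db[(f > 10e3) & (f < 70e3)]
        # smoothed octave-scale flatness, not bin-to-bin noise
        coarse = [band[i:i + 200].mean() for i in range(0, len(band) - 200, 200)]
        assert np.ptp(coarse) < 3.0

    def test_hrir_notch_appears_in_output(self):
        g = _delta_grid(notch_hz=40e3)
        s = synthesize_vas((0.0, 0.0), g, noise_seed=3)
        f, db = magnitude_spectrum_db(s.right, g.sample_rate)
        notch = db[np.abs(f - 40e3) < 1.5e3].mean()
        ref = db[(np.abs(f - 30e3) < 2e3) | (np.abs(f - 50e3) < 2e3)].mean()
        assert ref - notch > 24.0  # ~30 dB notch, tolerant of leakage

    def test_off_grid_direction_refused(self):
        g = _delta_grid()
        with pytest.raises(KeyError):
            synthesize_vas((17.0, 0.0), g)

    def test_identical_seed_bit_identical(self, grid):
        a = synthesize_vas((36.0, 20.0), grid, noise_seed=9)
        b = synthesize_vas((36.0, 20.0), grid, noise_seed=9)
        assert np.array_equal(a.left, b.left)
        assert np.array_equal(a.right, b.right)


class TestFreezeItd:
    def test_zero_itd_everywhere(self, grid):
        frozen = freeze_itd(grid)
        for i in range(frozen.n_directions):
            assert compute_itd(frozen.ir_left[i], frozen.ir_right[i],
                               frozen.sample_rate) == 0.0

    def test_already_zero_grid_unchanged(self, grid):
        once = freeze_itd(grid)
        twice = freeze_itd(once)
        assert np.array_equal(once.ir_left, twice.ir_left)

    def test_per_frequency_ild_preserved(self, grid):
        before = compute_ild(grid)
        after = compute_ild(freeze_itd(grid))
        assert np.max(np.abs(before.ild_by_frequency_db
                             - after.ild_by_frequency_db)) < 1e-9


class TestFreezeIld:
    def test_broadband_ild_zeroed(self, grid):
        ct = compute_ild(freeze_ild(grid))
        assert np.max(np.abs(ct.ild_broadband_db)) < 1e-6

    def test_flat_plus_minus_6db_meet_at_zero(self):
        g = _delta_grid()
        g.ir_left *= 10 ** (6 / 20)
        g.ir_right *= 10 ** (-6 / 20)
        ct = compute_ild(freeze_ild(g))
        assert np.allclose(ct.ild_broadband_db, 0.0, atol=1e-9)

    def test_spectral_notch_position_preserved(self):
        g = _delta_grid(notch_hz=40e3)
        g.ir_right *= 3.0
        frozen = freeze_ild(g)
        f, db = magnitude_spectrum_db(frozen.ir_right[0], g.sample_rate)
        sel = (f > 10e3) & (f < 75e3)
        assert abs(f[sel][np.argmin(db[sel])] - 40e3) < 2e3

    def test_itd_untouched(self, grid):
        before = compute_ild(grid).itd_us
        after = compute_ild(freeze_ild(grid)).itd_us
        assert np.array_equal(before, after)

    def test_silent_ear_rejected(self):
        g = _delta_grid()
        g.ir_left[:] = 0.0
        with pytest.raises(ValueError):
            freeze_ild(g)


class TestFreezeSpectrum:
    def test_spectra_flat(self, grid):
        frozen = freeze_spectrum(grid)
        f, db = magnitude_spectrum_db(frozen.ir_right, frozen.sample_rate)
        assert np.max(np.ptp(db, axis=1)) < 1e-9

    def test_broadband_ild_preserved(self, grid):
        before = compute_ild(grid)
        after = compute_ild(freeze_spectrum(grid))
        assert np.max(np.abs(before.ild_broadband_db
                             - after.ild_broadband_db)) < 1e-6

    def test_itd_preserved_exactly(self, grid):
        before = compute_ild(grid)
        after = compute_ild(freeze_spectrum(grid))
        assert np.array_equal(before.itd_us, after.itd_us)


class TestMonaural:
    def test_left_zeroed_right_untouched(self, grid):
        mono = make_monaural(grid)
        assert not np.any(mono.ir_left)
        assert np.array_equal(mono.ir_right, grid.ir_right)

    def test_left_waveform_silent(self, grid):
        mono = make_monaural(grid)
        s = synthesize_vas((0.0, 0.0), mono, noise_seed=4)
        assert not np.any(s.left)
        ref = synthesize_vas((0.0, 0.0), grid, noise_seed=4)
        assert np.array_equal(s.right, ref.right)

    def test_broadband_ild_capped(self, grid):
        cues = grid_cues(make_monaural(grid))
        assert np.all(cues.ild_broadband_db == 40.0)
        assert np.all(cues.silent_ear[:, 0])


class TestExtendedIld:
    def test_levels_and_repeats(self):
        stims = build_extended_ild_set(seed=5, sample_rate=200e3, n_repeats=30)
        levels = np.array([s.ild_db for s in stims])
        uniq, counts = np.unique(levels, return_counts=True)
        assert len(uniq) == 41
        assert np.allclose(np.diff(uniq), 2.0)
        assert uniq[0] == -40.0 and uniq[-1] == 40.0
        assert np.all(counts == 30)

    def test_measured_level_difference_matches_label(self):
        stims = build_extended_ild_set(seed=5, sample_rate=200e3, n_repeats=1)
        s = next(x for x in stims if x.ild_db == 10.0)
        measured = 20 * np.log10(np.sqrt(np.mean(s.right ** 2))
                                 / np.sqrt(np.mean(s.left ** 2)))
        assert measured == pytest.approx(10.0, abs=0.1)


class TestRandomChord:
    def test_two_minutes_is_12000_patterns(self):
        chord = generate_random_chord(seed=6, total_minutes=2.0)
        assert chord.n_patterns == 12_000
        assert chord.n_tones == 48

    def test_tone_grid_is_12_per_octave_from_5khz(self):
        chord = generate_random_chord(seed=6, total_minutes=0.01)
        f = chord.frequencies_hz
        assert f[0] == 5_000.0
        assert np.allclose(f[1:] / f[:-1], 2 ** (1 / 12))
        assert f[-1] < 80_000.0

    def test_on_probability_near_half(self):
        chord = generate_random_chord(seed=6, total_minutes=1.0)
        n = chord.patterns_left.size
        p_hat = chord.patterns_left.mean()
        sigma = np.sqrt(0.25 / n)
        assert abs(p_hat - 0.5) < 3 * sigma

    def test_ears_uncorrelated(self):
        chord = generate_random_chord(seed=6, total_minutes=1.0)
        a = chord.patterns_left.ravel().astype(float)
        b = chord.patterns_right.ravel().astype(float)
        r = np.corrcoef(a, b)[0, 1]
        assert abs(r) < 3 / np.sqrt(len(a))

    def test_repeats_reuse_identical_pattern_set(self):
        chord = generate_random_chord(seed=6, total_minutes=0.05, n_repeats=20)
        assert chord.n_repeats == 20
        assert chord.total_duration == pytest.approx(0.05 * 60 * 20)


class TestFreezingAltersExactlyOneCue:
    """Each freezing operation changes its own cue and leaves the others."""

    def test_on_random_synthetic_grids(self):
        from vasrf.synth import SyntheticHrtfSpec, make_synthetic_hrtf
        for seed, ild_max in ((0, 20.0), (1, 35.0)):
            spec = SyntheticHrtfSpec(
                ild_max_db=ild_max,
                azimuths_deg=np.arange(-108.0, 109.0, 36.0),
                elevations_deg=np.array([0.0, 40.0]))
            g = make_synthetic_hrtf(spec, seed=seed)
            base = compute_ild(g)
            fi = compute_ild(freeze_itd(g))
            assert np.allclose(fi.ild_by_frequency_db,
                               base.ild_by_frequency_db, atol=1e-9)
            fl = compute_ild(freeze_ild(g))
            assert np.array_equal(fl.itd_us, base.itd_us)
            fs_ = compute_ild(freeze_spectrum(g))
            assert np.array_equal(fs_.itd_us, base.itd_us)
            assert np.allclose(fs_.ild_broadband_db, base.ild_broadband_db,
                               atol=1e-6)
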