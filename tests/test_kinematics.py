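"""Orbit estimation, beat-frequency extraction, motion classification."""

import numpy as np
import pytest

from chlamyorbit import (EstimationError, OrbitParams, TranslatorParams,
                         classify_motion, count_motile,
                         estimate_beat_frequency, estimate_revolution,
                         generate_orbit_track, generate_translator_track,
                         summarize_population)
from chlamyorbit.config import PipelineConfig
from chlamyorbit.pipeline import simulate_population


class TestEstimateRevolution:
    def test_exact_on_noiseless_orbit(self):
        params = OrbitParams(center=(3.0, -2.0), R=1.16, omega=22.75,
                             beat_amp=0.0, noise_sigma=0.0, duration=1.0)
        kin = estimate_revolution(generate_orbit_track(params, seed=0))
        assert abs(kin.R - 1.16) / 1.16 < 1e-6
        assert abs(kin.omega - 22.75) / 22.75 < 1e-6
        assert kin.direction == "ccw"
        np.testing.assert_allclose(kin.center, (3.0, -2.0), atol=1e-9)
        assert kin.fit_residual < 1e-9

    def test_negative_omega_reports_cw_magnitude(self):
        params = OrbitParams(R=1.0, omega=-15.0, beat_amp=0.0,
                             noise_sigma=0.0, duration=1.0)
        kin = estimate_revolution(generate_orbit_track(params, seed=0))
        assert kin.direction == "cw"
        assert kin.omega == pytest.approx(15.0, rel=1e-6)

    def test_sub_revolution_arc_rejected(self):
        params = OrbitParams(R=1.0, omega=2.0, beat_amp=0.0, noise_sigma=0.0,
                             duration=1.0)  # 0.32 revolutions
        with pytest.raises(EstimationError, match="revolution"):
            estimate_revolution(generate_orbit_track(params, seed=0))

    def test_collinear_points_rejected(self):
        tr = generate_translator_track(
            TranslatorParams(speed=100.0, noise_sigma=0.0, duration=0.1),
            seed=0)
        with pytest.raises(EstimationError):
            estimate_revolution(tr)

    def test_short_track_rejected(self):
        params = OrbitParams(R=1.0, omega=22.75, beat_amp=0.0,
                             noise_sigma=0.0, duration=0.005)
        with pytest.raises(EstimationError, match="samples"):
            estimate_revolution(generate_orbit_track(params, seed=0))

    @pytest.mark.parametrize("seed", range(5))
    def test_noisy_beat_orbit_within_tolerance(self, seed):
        # beat + localisation noise: R within 5%, omega within 2%
        # (Monte-Carlo over the reference parameter ranges puts median
        # errors near 0.1%; see the population-recovery test below)
        params = OrbitParams(R=1.16, omega=22.75, beat_freq=49.0,
                             beat_amp=0.2, noise_sigma=0.05, duration=1.0)
        kin = estimate_revolution(generate_orbit_track(params, seed=seed))
        assert abs(kin.R - 1.16) / 1.16 < 0.05
        assert abs(kin.omega - 22.75) / 22.75 < 0.02

    def test_median_recovery_error_under_two_percent(self):
        rng = np.random.default_rng(7)
        err_R, err_w = [], []
        for seed in range(30):
            R = float(rng.uniform(0.68, 1.87))
            w = float(rng.uniform(9.5, 34.4))
            params = OrbitParams(R=R, omega=w, beat_freq=49.0, beat_amp=0.2,
                                 noise_sigma=0.05, duration=2.0)
            kin = estimate_revolution(generate_orbit_track(params, seed=seed))
            err_R.append(abs(kin.R - R) / R)
            err_w.append(abs(kin.omega - w) / w)
        assert np.median(err_R) < 0.02
        assert np.median(err_w) < 0.02

    def test_rigid_motion_invariance(self):
        params = OrbitParams(R=1.4, omega=18.0, beat_freq=49.0, beat_amp=0.2,
                             noise_sigma=0.05, duration=1.0)
        tr = generate_orbit_track(params, seed=4)
        kin = estimate_revolution(tr)
        moved = tr.transformed(rotation=0.7, translation=(12.0, -5.0))
        kin2 = estimate_revolution(moved)
        assert abs(kin2.R - kin.R) / kin.R < 1e-9
        assert abs(kin2.omega - kin.omega) / kin.omega < 1e-9
        bf = estimate_beat_frequency(tr, kin)
        bf2 = estimate_beat_frequency(moved, kin2)
        assert abs(bf2 - bf) / bf < 1e-9

    def test_time_reversal_flips_direction_only(self):
        from chlamyorbit import Track
        params = OrbitParams(R=1.2, omega=20.0, beat_amp=0.0,
                             noise_sigma=0.0, duration=1.0)
        tr = generate_orbit_track(params, seed=0)
        rev = Track(tr.track_id, tr.frame, tr.t,
                    tr.x[::-1].copy(), tr.y[::-1].copy())
        kin, kin_r = estimate_revolution(tr), estimate_revolution(rev)
        assert kin.direction != kin_r.direction
        assert kin_r.R == pytest.approx(kin.R, rel=1e-9)
        assert kin_r.omega == pytest.approx(kin.omega, rel=1e-9)


class TestBeatFrequency:
    @pytest.mark.parametrize("freq", [30.0, 49.0])
    def test_injected_frequency_recovered_within_one_bin(self, freq):
        params = OrbitParams(R=1.16, omega=22.75, beat_freq=freq,
                             beat_amp=0.2, noise_sigma=0.05, duration=0.5)
        tr = generate_orbit_track(params, seed=1)
        kin = estimate_revolution(tr)
        bf = estimate_beat_frequency(tr, kin)
        bin_width = 1.0 / tr.duration
        assert bf is not None
        assert abs(bf - freq) <= bin_width

    def test_no_modulation_gives_absent(self):
        params = OrbitParams(R=1.16, omega=22.75, beat_amp=0.0,
                             noise_sigma=0.05, duration=0.5)
        tr = generate_orbit_track(params, seed=2)
        kin = estimate_revolution(tr)
        assert estimate_beat_frequency(tr, kin) is None

    def test_noiseless_beat_free_gives_absent(self):
        params = OrbitParams(R=1.16, omega=22.75, beat_amp=0.0,
                             noise_sigma=0.0, duration=0.5)
        tr = generate_orbit_track(params, seed=0)
        kin = estimate_revolution(tr)
        assert estimate_beat_frequency(tr, kin) is None

    def test_undersampled_track_names_nyquist(self):
        # 20 Hz sampling cannot search above twice the 3.6 Hz revolution
        params = OrbitParams(R=1.16, omega=22.75, beat_amp=0.2,
                             beat_freq=8.0, noise_sigma=0.0, duration=2.0,
                             frame_interval=0.05)
        tr = generate_orbit_track(params, seed=0)
        kin = estimate_revolution(tr)
        with pytest.raises(EstimationError, match="Nyquist"):
            estimate_beat_frequency(tr, kin, min_freq_factor=4.0)


class TestClassifyMotion:
    def test_stationary_track_is_immotile(self):
        tr = generate_translator_track(
            TranslatorParams(speed=0.0, noise_sigma=0.0, duration=0.5), seed=0)
        assert classify_motion(tr) == "immotile"

    def test_noisy_stationary_track_is_immotile(self):
        tr = generate_translator_track(
            TranslatorParams(speed=0.0, noise_sigma=0.05, duration=0.5),
            seed=1)
        assert classify_motion(tr) == "immotile"

    def test_swimmer_is_translating(self):
        tr = generate_translator_track(
            TranslatorParams(speed=105.0, noise_sigma=0.05, duration=0.5),
            seed=0)
        assert classify_motion(tr) == "translating"

    def test_orbiting_cell_is_revolving(self):
        params = OrbitParams(R=1.16, omega=22.75, beat_freq=49.0,
                             beat_amp=0.2, noise_sigma=0.05, duration=1.0)
        tr = generate_orbit_track(params, seed=0)
        assert classify_motion(tr) == "revolving"

    def test_confusion_matrix_is_diagonal(self):
        cfg = PipelineConfig(seed=23)
        cfg.simulate.n_revolving = 4
        cfg.simulate.n_translating = 3
        cfg.simulate.n_immotile = 3
        tracks = simulate_population(cfg)
        expected = ["revolving"] * 4 + ["translating"] * 3 + ["immotile"] * 3
        got = [classify_motion(tr) for tr in tracks]
        assert got == expected


class TestPopulation:
    def test_reference_means_match_published_values(self, reference_cells):
        pop = summarize_population(reference_cells)
        assert pop.n_cells == 12
        assert round(pop.mean_omega, 2) == 22.75
        assert round(pop.mean_R, 2) == 1.16

    def test_mean_equals_arithmetic_oracle(self, reference_cells):
        pop = summarize_population(reference_cells)
        assert pop.mean_R == pytest.approx(
            sum(k.R for k in reference_cells) / len(reference_cells))
        assert pop.mean_omega == pytest.approx(
            sum(k.omega for k in reference_cells) / len(reference_cells))

    def test_single_cell_summary_is_that_cell(self, reference_cells):
        pop = summarize_population(reference_cells[:1])
        assert pop.mean_R == reference_cells[0].R
        assert pop.mean_omega == reference_cells[0].omega

    def test_duplication_leaves_means_unchanged(self, reference_cells):
        pop = summarize_population(reference_cells)
        dup = summarize_population(list(reference_cells) * 2)
        assert dup.mean_R == pytest.approx(pop.mean_R)
        assert dup.mean_omega == pytest.approx(pop.mean_omega)

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            summarize_population([])


class TestCountMotile:
    def _population(self, n_swim, n_still, seed0=0):
        tracks = []
        for i in range(n_swim):
            tracks.append(generate_translator_track(
                TranslatorParams(start=(30.0 * i, 0.0), speed=105.0,
                                 noise_sigma=0.05, duration=0.5),
                seed=seed0 + i, track_id=i))
        for j in range(n_still):
            tracks.append(generate_translator_track(
                TranslatorParams(start=(0.0, 30.0 * (j + 1)), speed=0.0,
                                 noise_sigma=0.05, duration=0.5),
                seed=seed0 + 100 + j, track_id=n_swim + j))
        return tracks

    def test_mixed_population(self):
        assert count_motile(self._population(5, 3)) == 5

    def test_all_stationary(self):
        assert count_motile(self._population(0, 4)) == 0

    def test_count_matches_generated_labels(self):
        cfg = PipelineConfig(seed=31)
        cfg.simulate.n_revolving = 3
        cfg.simulate.n_translating = 2
        cfg.simulate.n_immotile = 4
        tracks = simulate_population(cfg)
        assert count_motile(tracks, window=0.5) == 5
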