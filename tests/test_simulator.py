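import numpy as np
import pytest

from beamfov import beam_model, click_processing, simulator
from beamfov.beam_model import PistonSpec
from beamfov.simulator import (
    PistonSource,
    TrajectoryPoint,
    click_spectrum,
    channel_efd,
    propagate_click,
    schedule_approach,
    synth_click_waveform,
    synthesize_trial,
)

FS = 500e3


class TestClickWaveform:
    def test_spectral_centroid(self, default_click):
        fc = click_processing.centroid_frequency(default_click, FS)
        assert fc == pytest.approx(130e3, abs=1e3)

    def test_parseval(self, default_click):
        t_energy = np.sum(default_click**2)
        spec = np.fft.rfft(default_click)
        # rfft doubles all bins except DC/Nyquist
        f_energy = (np.abs(spec[0]) ** 2 + 2 * np.sum(np.abs(spec[1:-1]) ** 2)
                    + np.abs(spec[-1]) ** 2) / len(default_click)
        assert t_energy == pytest.approx(f_energy, rel=1e-9)

    def test_energy_inside_window(self):
        src = PistonSource(click_duration=80e-6)
        w = synth_click_waveform(src, FS)
        peak = int(np.argmax(np.abs(w)))
        lo, hi = peak - 15, peak + 45
        assert np.sum(w[lo:hi] ** 2) / np.sum(w**2) >= 0.99

    def test_window_energy_matches_source_level(self):
        src = PistonSource(source_level=163.0)
        w = synth_click_waveform(src, FS)
        peak = int(np.argmax(np.abs(w)))
        efd = click_processing.click_energy(w, peak, FS)
        assert efd == pytest.approx(163.0, abs=0.1)

    def test_aliasing_guard(self):
        with pytest.raises(ValueError):
            synth_click_waveform(PistonSource(), fs=300e3)


class TestSchedule:
    def test_click_count_constant_ici(self):
        track = schedule_approach(7.0, 2.0, 1.0, 0.05, 8.2)
        assert len(track) == 100

    def test_constant_beamwidth_constant_diameter(self):
        track = schedule_approach(5.0, 3.0, 2.0, 0.05, 9.1)
        diam = {round(p.diameter, 9) for p in track}
        assert len(diam) == 1
        spec = PistonSpec(track[0].diameter, frequency=130e3)
        assert beam_model.piston_beamwidth(spec) == pytest.approx(9.1, abs=0.01)

    def test_buzz_switch_range(self):
        ici = lambda r: 0.05 if r >= 2.0 else 0.005
        track = schedule_approach(3.0, 1.0, 1.0, ici, 8.2)
        for p in track:
            if p.position[1] < 2.0:
                assert p.ici <= 0.013

    def test_invalid_ranges(self):
        with pytest.raises(ValueError):
            schedule_approach(2.0, 3.0, 1.0, 0.05, 8.2)


class TestPropagation:
    def test_on_axis_1m_equals_sl(self, star_small, default_source):
        pos = np.array([0.0, 1.0, 0.0])
        efd = channel_efd(default_source, pos, -pos, star_small)
        centre = int(np.argmin(np.linalg.norm(star_small.positions, axis=1)))
        assert efd[centre] == pytest.approx(default_source.source_level, abs=1e-9)

    def test_on_axis_2m_minus_6db(self, star_small, default_source):
        pos = np.array([0.0, 2.0, 0.0])
        efd = channel_efd(default_source, pos, -pos, star_small)
        centre = int(np.argmin(np.linalg.norm(star_small.positions, axis=1)))
        assert default_source.source_level - efd[centre] == pytest.approx(
            20 * np.log10(2), abs=1e-9
        )

    def test_half_power_angle_is_3db_down(self, default_source):
        # custom two-hydrophone geometry: one on-axis, one at the -3 dB angle
        from beamfov.geometry import ArrayGeometry, Hydrophone

        bw = beam_model.piston_beamwidth(
            PistonSpec(default_source.diameter, frequency=default_source.click_centroid)
        )
        r = 2.0
        x = r * np.tan(np.radians(bw / 2))
        g = ArrayGeometry(
            [Hydrophone(0, (0.0, 0.0, 0.0)), Hydrophone(1, (float(x), 0.0, 0.0))],
            (0.0, 1.0, 0.0),
            "linear",
        )
        pos = np.array([0.0, r, 0.0])
        efd = channel_efd(default_source, pos, -pos, g)
        # channel 1 sits at bw/2 off-axis but slightly farther away
        spread = 20 * np.log10(np.hypot(x, r) / r)
        assert efd[0] - (efd[1] + spread) == pytest.approx(3.0, abs=0.02)

    def test_sensitivity_offset_applied(self, default_source):
        from beamfov.geometry import ArrayGeometry, Hydrophone

        g = ArrayGeometry(
            [Hydrophone(0, (0.0, 0.0, 0.0), 0.0), Hydrophone(1, (0.0, 0.0, 0.0), 2.5)],
            (0.0, 1.0, 0.0),
            "linear",
        )
        pos = np.array([0.0, 1.0, 0.0])
        efd = channel_efd(default_source, pos, -pos, g)
        assert efd[1] - efd[0] == pytest.approx(2.5)

    def test_too_close_raises(self, star_small, default_source):
        pos = np.array([0.0, 0.01, 0.0])
        with pytest.raises(ValueError):
            propagate_click(default_source, pos, -pos, star_small)


class TestSynthesizeTrial:
    def test_determinism(self, star_small, default_source):
        track = schedule_approach(1.0, 0.9, 2.0, 0.05, 8.2)
        t1 = synthesize_trial(star_small, track, default_source, seed=3,
                              noise_level=100.0, tail_s=0.005)
        t2 = synthesize_trial(star_small, track, default_source, seed=3,
                              noise_level=100.0, tail_s=0.005)
        assert np.array_equal(t1.audio, t2.audio)
        assert np.array_equal(t1.tag_audio, t2.tag_audio)

    def test_noise_free_levels_match_propagation(self, noise_free_star_trial):
        trial = noise_free_star_trial
        g = trial.geometry
        fs = trial.fs
        pt = trial.track[0]
        spectrum = click_spectrum(synth_click_waveform(trial.source, fs), fs)
        expected = trial.source.source_level + propagate_click(
            trial.source, pt.position, pt.orientation, g,
            diameter=pt.diameter, spectrum=spectrum,
        )[1]
        centre = int(np.argmin(np.linalg.norm(g.positions, axis=1)))
        env = click_processing.envelope(trial.audio[centre], fs)
        n0 = int(pt.time * fs)
        peak = n0 + int(np.argmax(env[n0:n0 + 2000]))
        measured = click_processing.click_energy(trial.audio[centre], peak, fs)
        assert measured == pytest.approx(expected[centre], abs=0.1)

    def test_snr_calibration(self, star_small, default_source):
        track = schedule_approach(1.0, 0.9, 2.0, 0.05, 8.2)
        noise_level = 120.0
        trial = synthesize_trial(star_small, track, default_source, seed=9,
                                 noise_level=noise_level, tail_s=0.005)
        centre = int(np.argmin(np.linalg.norm(star_small.positions, axis=1)))
        fs = trial.fs
        pt = trial.track[0]
        env = click_processing.envelope(trial.audio[centre], fs)
        n0 = int(pt.time * fs)
        peak = n0 + int(np.argmax(env[n0:n0 + 2000]))
        sig = click_processing.click_energy(trial.audio[centre], peak, fs)
        expected = trial.source.source_level + propagate_click(
            default_source, pt.position, pt.orientation, star_small,
            diameter=pt.diameter,
        )[1][centre]
        assert sig - noise_level == pytest.approx(expected - noise_level, abs=1.0)

    def test_truth_table_columns(self, noise_free_star_trial):
        cols = set(noise_free_star_trial.truth.columns)
        assert {"click_id", "emission_time_s", "range_m", "diameter_m",
                "beamwidth_deg", "ici_s"} <= cols

    def test_audio_lengths_equal(self, noise_free_star_trial):
        t = noise_free_star_trial
        assert t.audio.shape[1] == t.tag_audio.shape[0]

    def test_empty_track_raises(self, star_small, default_source):
        with pytest.raises(ValueError):
            synthesize_trial(star_small, [], default_source)


class TestTrajectoryPoint:
    def test_orientation_normalized(self):
        p = TrajectoryPoint(0.0, np.zeros(3), np.array([0.0, -2.0, 0.0]), 0.083, 0.05)
        assert np.linalg.norm(p.orientation) == pytest.approx(1.0)

    def test_nonpositive_ici(self):
        with pytest.raises(ValueError):
            TrajectoryPoint(0.0, np.zeros(3), np.array([0, 1, 0]), 0.083, 0.0)


class TestEnergyDomainRoute:
    def test_matches_audio_route(self, noise_free_star_trial):
        """The fast energy route and the rendered audio agree channel-wise."""
        trial = noise_free_star_trial
        g, fs = trial.geometry, trial.fs
        pt = trial.track[0]
        spectrum = click_spectrum(synth_click_waveform(trial.source, fs), fs)
        analytic = channel_efd(trial.source, pt.position, pt.orientation, g,
                               diameter=pt.diameter, spectrum=spectrum)
        n0 = int(pt.time * fs)
        for ch in range(0, g.n_channels, 7):
            env = click_processing.envelope(trial.audio[ch], fs)
            peak = n0 + int(np.argmax(env[n0:n0 + 2000]))
            measured = click_processing.click_energy(trial.audio[ch], peak, fs)
            assert measured == pytest.approx(analytic[ch], abs=0.25)
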