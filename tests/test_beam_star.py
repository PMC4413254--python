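import numpy as np
import pytest

from beamfov import beam_model, beam_star, simulator
from beamfov.beam_model import PistonSpec
from beamfov.beam_star import (
    apply_inclusion_criteria,
    candidate_diameters,
    fit_energy_surface,
    fit_piston_star,
    select_channels,
)


class TestCandidateDiameters:
    def test_step(self):
        d = candidate_diameters()
        assert np.allclose(np.diff(d), 0.001)

    def test_range_one_third_to_three_times(self):
        d = candidate_diameters()
        assert d[0] >= 0.083 / 3
        assert d[0] - 0.083 / 3 < 0.001
        assert d[-1] == pytest.approx(0.249, abs=1e-9)

    def test_contains_reference(self):
        assert np.any(np.isclose(candidate_diameters(), 0.083))


class TestSelectChannels:
    def test_retained(self):
        assert select_channels(np.full(6, 120.0), 100.0).all()

    def test_strict_threshold(self):
        levels = np.array([120.0, 113.9, 114.0, 120.0, 120.0, 120.0])
        mask = select_channels(levels, 100.0)
        assert mask.tolist() == [True, False, True, True, True, True]

    def test_noise_free_all_pass(self, star_small, default_source):
        pos = np.array([0.0, 1.0, 0.0])
        efd = simulator.channel_efd(default_source, pos, -pos, star_small)
        mask = select_channels(efd, -1e9)
        assert mask.sum() == 48

    def test_too_few_raises(self):
        with pytest.raises(ValueError):
            select_channels(np.array([120.0] * 4 + [100.0] * 4), 110.0)


class TestEnergySurface:
    def test_axis_recovery_off_centre(self, star_small, default_source):
        pos = np.array([0.0, 1.0, 0.0])
        aim = np.array([0.03, 0.0, -0.02])
        efd = simulator.channel_efd(default_source, pos, aim - pos, star_small)
        surf = fit_energy_surface(efd, star_small, 1.0)
        assert abs(surf.axis_position[0] - 0.03) <= 0.005
        assert abs(surf.axis_position[1] + 0.02) <= 0.005

    def test_axis_at_centre(self, star_small, default_source):
        pos = np.array([0.0, 1.0, 0.0])
        efd = simulator.channel_efd(default_source, pos, -pos, star_small)
        surf = fit_energy_surface(efd, star_small, 1.0)
        assert np.hypot(*surf.axis_position) <= 0.005

    def test_grid_on_half_cm_lattice(self, star_small, default_source):
        pos = np.array([0.0, 1.0, 0.0])
        efd = simulator.channel_efd(default_source, pos, -pos, star_small)
        surf = fit_energy_surface(efd, star_small, 1.0)
        assert np.allclose(np.diff(surf.xnodes), 0.005)

    def test_too_few_channels(self, star_small):
        efd = np.full(48, -np.inf)
        efd[:4] = 150.0
        with pytest.raises(ValueError):
            fit_energy_surface(efd, star_small, 1.0, mask=efd > 0)


class TestPistonFitStar:
    def test_round_trip_reference(self, star_small, default_source):
        pos = np.array([0.0, 1.0, 0.0])
        efd = simulator.channel_efd(default_source, pos, -pos, star_small)
        surf = fit_energy_surface(efd, star_small, 1.0)
        fit = fit_piston_star(efd, star_small, surf.axis_position, pos,
                              frequency=130e3)
        assert fit.best_diameter == pytest.approx(0.083, abs=0.001)
        assert fit.r_squared > 0.999

    def test_self_fit_zero_lse(self, star_small, default_source):
        # energies generated exactly from a candidate piston, known axis
        pos = np.array([0.0, 1.0, 0.0])
        efd = simulator.channel_efd(default_source, pos, -pos, star_small)
        fit = fit_piston_star(efd, star_small, (0.0, 0.0), pos, frequency=130e3)
        assert fit.lse == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_round_trip_across_ranges(self, star_small, star_large):
        # acceptance property 5b at three diameters over the range envelope
        for d in (0.0415, 0.083, 0.166):
            src = simulator.PistonSource(diameter=d)
            for r, geom in ((0.55, star_small), (2.0, star_small), (7.0, star_large)):
                bw = beam_model.piston_beamwidth(PistonSpec(d, frequency=130e3))
                from beamfov.geometry import effective_angular_resolution

                if bw < effective_angular_resolution(0.05, r):
                    continue  # sub-resolution at this range
                pos = np.array([0.0, r, 0.0])
                efd = simulator.channel_efd(src, pos, -pos, geom)
                surf = fit_energy_surface(efd, geom, r)
                fit = fit_piston_star(efd, geom, surf.axis_position, pos,
                                      frequency=130e3)
                # within one candidate-grid step (0.1 cm)
                assert fit.best_diameter == pytest.approx(d, abs=0.00101)

    def test_spread_contains_best(self, star_small, default_source):
        pos = np.array([0.0, 1.0, 0.0])
        efd = simulator.channel_efd(default_source, pos, -pos, star_small)
        fit = fit_piston_star(efd, star_small, (0.0, 0.0), pos, frequency=130e3)
        lo, hi = fit.spread_deg
        assert lo <= fit.beamwidth_deg <= hi

    def test_r2_gate_flags_bad_fit(self, star_small):
        rng = np.random.default_rng(0)
        efd = 150.0 + rng.normal(0, 6.0, 48)  # incoherent energies
        fit = fit_piston_star(efd, star_small, (0.0, 0.0),
                              np.array([0.0, 1.0, 0.0]), frequency=130e3)
        assert not fit.included
        assert "r_squared_gate" in fit.reasons

    def test_r2_degrades_with_noise(self, star_small, default_source):
        pos = np.array([0.0, 1.0, 0.0])
        clean = simulator.channel_efd(default_source, pos, -pos, star_small)
        r2 = []
        for sigma in (0.0, 0.5, 2.0):
            vals = []
            for seed in range(5):
                rng = np.random.default_rng(seed)
                noisy = clean + rng.normal(0, sigma, 48)
                vals.append(
                    fit_piston_star(noisy, star_small, (0.0, 0.0), pos,
                                    frequency=130e3).r_squared
                )
            r2.append(np.mean(vals))
        assert r2[0] > r2[1] > r2[2]

    def test_broadband_spectrum_route(self, star_small, default_source):
        w = simulator.synth_click_waveform(default_source, 500e3)
        spectrum = simulator.click_spectrum(w, 500e3)
        pos = np.array([0.0, 1.0, 0.0])
        efd = simulator.channel_efd(default_source, pos, -pos, star_small,
                                    spectrum=spectrum)
        fit = fit_piston_star(efd, star_small, (0.0, 0.0), pos, spectrum=spectrum)
        assert fit.best_diameter == pytest.approx(0.083, abs=0.001)


class TestInclusionCriteria:
    def _fit(self, axis_cm=(0.0, 0.0)):
        return beam_star.PistonFit(axis_cm, 0.083, 8.2, 0.99, 0.0, (8.0, 8.4), 48)

    def test_bearing_excluded(self):
        ok, reasons = apply_inclusion_criteria(self._fit(), 16.0, 0.0, "large")
        assert not ok and "bearing_bound" in reasons

    def test_large_axis_11cm_included(self):
        ok, _ = apply_inclusion_criteria(self._fit((11.0, 0.0)), 0.0, 0.0, "large")
        assert ok

    def test_small_buzz_7cm_excluded(self):
        ok, reasons = apply_inclusion_criteria(
            self._fit((7.0, 0.0)), 0.0, 0.0, "small", phase="buzz"
        )
        assert not ok and "axis_displacement_bound" in reasons

    def test_small_prebuzz_7cm_included(self):
        ok, _ = apply_inclusion_criteria(
            self._fit((7.0, 0.0)), 0.0, 0.0, "small", phase="pre_buzz"
        )
        assert ok

    def test_missing_phase_conservative(self):
        ok, _ = apply_inclusion_criteria(self._fit((7.0, 0.0)), 0.0, 0.0, "small")
        assert not ok

    def test_unknown_config(self):
        with pytest.raises(ValueError):
            apply_inclusion_criteria(self._fit(), 0.0, 0.0, "tiny")


class TestCrossMethodAgreement:
    def test_linear_and_star_agree(self, linear_geom, star_small, default_source):
        """Acceptance property 5c: both methods on the same source agree
        within the larger of the two effective angular resolutions."""
        from beamfov import beam_linear
        from beamfov.geometry import effective_angular_resolution
        from beamfov.localization import SourceFix

        # linear array: source at 3 m
        pos = np.array([0.0, 3.0, 0.0])
        efd = simulator.channel_efd(default_source, pos, -pos, linear_geom)
        fix = SourceFix(pos, 3.0, 0.0, 0.0, 0.0)
        pat = beam_linear.build_radiation_pattern(efd, fix, linear_geom)
        fit_lin = beam_linear.fit_piston_to_pattern(
            pat, frequency=default_source.click_centroid
        )
        # star array: same source at 1 m
        pos2 = np.array([0.0, 1.0, 0.0])
        efd2 = simulator.channel_efd(default_source, pos2, -pos2, star_small)
        surf = fit_energy_surface(efd2, star_small, 1.0)
        fit_star = fit_piston_star(efd2, star_small, surf.axis_position, pos2,
                                   frequency=default_source.click_centroid)
        tol = max(
            effective_angular_resolution(0.6, 3.0),
            effective_angular_resolution(0.05, 1.0),
        )
        assert abs(fit_lin.beamwidth_deg - fit_star.beamwidth_deg) <= tol
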