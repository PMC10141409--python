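"""Generator physics: polarizability, OU trap dynamics, gating process,
band-limited noise, and the composed signal model."""

import math

import numpy as np
import pytest
from scipy.constants import Boltzmann as K_B
from scipy.constants import c as C_LIGHT
from scipy.constants import epsilon_0 as EPS0

import ferrotrace as ft
from ferrotrace.synthetic import TraceConfig, TrapPhysics


class TestPolarizability:
    def test_index_matched_particle_has_zero_polarizability(self):
        assert ft.polarizability(6e-9, 1.77, 1.77, 0.0) == 0

    def test_volume_scaling(self):
        a1 = ft.polarizability(6e-9, 2.1, 1.77)
        a2 = ft.polarizability(12e-9, 2.1, 1.77)
        assert abs(a2) / abs(a1) == pytest.approx(8.0, rel=1e-12)

    def test_closed_form_hand_evaluation(self):
        # independent direct evaluation of the Clausius-Mossotti sphere formula
        r, eps_p, eps_m, lam = 6e-9, 2.1, 1.77, 852e-9
        expected = 4 * math.pi * EPS0 * r ** 3 * (eps_p - eps_m) / (eps_p + 2 * eps_m)
        got = ft.polarizability(r, eps_p, eps_m, 0.0, lam)
        assert got.real == pytest.approx(expected, rel=1e-10)
        assert got.imag == 0

    def test_conductivity_strictly_increases_magnitude(self):
        mags = [abs(ft.polarizability(6e-9, 2.1, 1.77, sigma))
                for sigma in (0.0, 10.0, 100.0, 1000.0, 1e4)]
        assert all(b > a for a, b in zip(mags, mags[1:]))

    def test_conductive_sphere_complex_permittivity(self):
        # the Drude term enters as sigma/(omega eps0) in the imaginary part
        r, lam, sigma = 7e-9, 852e-9, 100.0
        omega = 2 * math.pi * C_LIGHT / lam
        eps_t = 2.06 + 1j * sigma / (omega * EPS0)
        expected = 4 * math.pi * EPS0 * r ** 3 * (eps_t - 1.77) / (eps_t + 2 * 1.77)
        got = ft.polarizability(r, 2.06, 1.77, sigma, lam)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            ft.polarizability(-1e-9, 2.1, 1.77)
        with pytest.raises(ValueError):
            ft.polarizability(6e-9, 2.1, 1.77, wavelength=0)


class TestDeltaFromPolarizability:
    def test_zero_polarizability_gives_zero_step(self):
        assert ft.delta_from_polarizability(0j, 1.0) == 0

    def test_linear_in_responsivity(self):
        alpha = ft.polarizability(6e-9, 2.1, 1.77)
        assert ft.delta_from_polarizability(alpha, 2e-3) == pytest.approx(
            2 * ft.delta_from_polarizability(alpha, 1e-3), rel=1e-12)

    def test_forty_one_percent_larger_polarizability_scales_delta(self):
        # responsivity chosen so the apo polarizability maps to delta = 0.05;
        # a 41% larger Re(alpha) must then map to 0.0705 by linearity
        alpha_apo = ft.polarizability(6e-9, 2.1, 1.77)
        resp = 0.05 / ft.delta_from_polarizability(alpha_apo, 1.0)
        alpha_holo = 1.41 * alpha_apo
        assert ft.delta_from_polarizability(alpha_holo, resp) == pytest.approx(
            0.0705, rel=1e-12)


class TestOrnsteinUhlenbeck:
    KAPPA, GAMMA, TEMP, FS = 2e-6, 1.0e-10, 298.0, 10_000.0

    def test_stationary_variance_matches_equipartition(self):
        x = ft.simulate_ou(self.KAPPA, self.GAMMA, self.TEMP, self.FS, 10 ** 6, 7)
        assert np.var(x) == pytest.approx(K_B * self.TEMP / self.KAPPA, rel=0.03)

    def test_lag_one_autocorrelation_is_exact_discretization_factor(self):
        # oversample (fs >> corner frequency) so the sampling error of the
        # autocorrelation estimate is far below the 1% tolerance
        fs = 200_000.0
        x = ft.simulate_ou(self.KAPPA, self.GAMMA, self.TEMP, fs, 10 ** 6, 7)
        expected = math.exp(-(self.KAPPA / self.GAMMA) / fs)
        r1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert r1 == pytest.approx(expected, rel=0.01)

    def test_stiff_trap_limit_collapses_motion(self):
        x = ft.simulate_ou(self.KAPPA * 1e6, self.GAMMA, self.TEMP, self.FS,
                           10 ** 4, 7)
        loose = ft.simulate_ou(self.KAPPA, self.GAMMA, self.TEMP, self.FS,
                               10 ** 4, 7)
        assert np.std(x) < 1e-3 * np.std(loose)

    def test_rejects_nonpositive_parameters(self):
        with pytest.raises(ValueError):
            ft.simulate_ou(-1.0, self.GAMMA, self.TEMP, self.FS, 100, 0)


class TestGatingProcess:
    def test_infinite_off_dwell_yields_single_on_segment(self):
        kin = ft.GatingKinetics(tau_on=math.inf, tau_off=3.5)
        series, boundaries = ft.simulate_gating(kin, 50.0, 1000.0, 3)
        assert len(boundaries) == 0
        assert np.all(series == 1)

    def test_mean_dwells_obey_law_of_large_numbers(self):
        kin = ft.GatingKinetics(tau_on=3.5, tau_off=3.5)
        _, boundaries = ft.simulate_gating(kin, 10_000.0, 100.0, 11)
        dwells = np.diff(boundaries)
        on_dwells, off_dwells = dwells[1::2], dwells[0::2]
        assert np.mean(on_dwells) == pytest.approx(3.5, rel=0.05)
        assert np.mean(off_dwells) == pytest.approx(3.5, rel=0.05)

    def test_boundary_count_equals_segments_minus_one(self):
        kin = ft.GatingKinetics()
        series, boundaries = ft.simulate_gating(kin, 100.0, 1000.0, 5)
        n_segments = 1 + np.count_nonzero(np.diff(series))
        assert len(boundaries) == n_segments - 1


class TestBandLimitedNoise:
    def test_unit_rms_is_enforced(self):
        z = ft.band_limited_noise(3.0, 150.0, 10_000.0, 50_000, 9)
        assert math.sqrt(np.mean(z * z)) == pytest.approx(1.0, abs=1e-9)

    def test_power_confined_to_band(self):
        fs, n = 2000.0, 100_000
        z = ft.band_limited_noise(3.0, 150.0, fs, n, 9)
        spectrum = np.abs(np.fft.rfft(z)) ** 2
        freqs = np.fft.rfftfreq(n, 1 / fs)
        in_band = spectrum[(freqs >= 3.0) & (freqs <= 150.0)].sum()
        assert in_band / spectrum.sum() >= 0.95

    def test_seed_controls_realization(self):
        a = ft.band_limited_noise(3.0, 150.0, 1000.0, 1000, 1)
        b = ft.band_limited_noise(3.0, 150.0, 1000.0, 1000, 1)
        c = ft.band_limited_noise(3.0, 150.0, 1000.0, 1000, 2)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            ft.band_limited_noise(3.0, 600.0, 1000.0, 1000, 0)


def _quiet_config(**kw):
    defaults = dict(fs=10_000.0, duration=12.0, seed=0, t_trap=2.0,
                    instrument_noise=0.0)
    defaults.update(kw)
    return TraceConfig(**defaults)


def _silent_preset(conf_amp=0.0, delta=0.05):
    import dataclasses
    return dataclasses.replace(ft.apo_preset(), conf_amp_trapped=conf_amp,
                               step_contrast=delta)


class TestSynthesize:
    def test_no_protein_no_noise_gives_constant_baseline(self):
        cfg = _quiet_config(t_trap=0.0, t_release=None, duration=2.0)
        cfg.t_trap = 0.0
        physics = TrapPhysics.for_radius(6.0, position_responsivity=0.0)
        out = ft.synthesize(_quiet_config(duration=2.0, t_trap=1.9999),
                            _silent_preset(delta=0.0), physics)
        assert np.allclose(out.trace.values, 1.0, atol=1e-15)

    def test_noise_free_step_height_is_exact(self):
        physics = TrapPhysics.for_radius(6.0, position_responsivity=0.0)
        out = ft.synthesize(_quiet_config(), _silent_preset(delta=0.05), physics)
        pre = out.trace.values[: int(2.0 * 10_000)]
        post = out.trace.values[int(2.0 * 10_000):]
        assert np.mean(post) - np.mean(pre) == pytest.approx(0.05 * 1.0, abs=1e-12)

    def test_gating_switches_conformational_rms_by_programmed_amplitudes(self):
        # isolate the conformational term; compare per-state RMS in segments
        # of at least 1 s against the programmed on/off amplitudes
        physics = TrapPhysics.for_radius(6.0, position_responsivity=0.0)
        kin = ft.GatingKinetics(tau_on=4.0, tau_off=4.0, amp_on=1.0, amp_off=0.3,
                                mineralization_tau=math.inf, loading_start=0.0)
        cfg = _quiet_config(duration=300.0, t_trap=0.0, seed=4)
        out = ft.synthesize(cfg, _silent_preset(conf_amp=5e-3, delta=0.0),
                            physics, kin)
        resid = out.trace.values - 1.0
        edges = np.concatenate(([0.0], out.true_boundaries, [300.0]))
        rms_on, rms_off = [], []
        for a, b in zip(edges[:-1], edges[1:]):
            if b - a < 1.0:
                continue
            i0, i1 = int(a * cfg.fs) + 100, int(b * cfg.fs) - 100
            seg = resid[i0:i1]
            state = out.gating_state[i0]
            (rms_on if state == 1 else rms_off).append(
                math.sqrt(np.mean(seg ** 2)))
        assert np.mean(rms_on) == pytest.approx(5e-3, rel=0.05)
        assert np.mean(rms_off) == pytest.approx(1.5e-3, rel=0.05)

    def test_bit_identical_for_same_config_and_seed(self):
        cfg_a = TraceConfig(duration=3.0, seed=77, t_trap=1.0)
        cfg_b = TraceConfig(duration=3.0, seed=77, t_trap=1.0)
        a = ft.synthesize(cfg_a, ft.apo_preset())
        b = ft.synthesize(cfg_b, ft.apo_preset())
        assert np.array_equal(a.trace.values, b.trace.values)
        assert np.array_equal(a.position, b.position)
        c = ft.synthesize(TraceConfig(duration=3.0, seed=78, t_trap=1.0),
                          ft.apo_preset())
        assert not np.array_equal(a.trace.values, c.trace.values)

    def test_ground_truth_boundaries_on_grid_inside_trapped_span(self):
        out, kin = ft.gating_experiment(seed=5, duration=60.0)
        b = out.true_boundaries
        assert np.all(np.diff(b) > 0)
        assert np.allclose(b * 10_000, np.round(b * 10_000), atol=1e-6)
        assert b.min() > 2.0 and b.max() < 60.0

    def test_occupancy_zero_outside_trapped_span(self):
        cfg = TraceConfig(duration=10.0, seed=1, t_trap=2.0, t_release=8.0)
        out = ft.synthesize(cfg, ft.apo_preset())
        t = out.trace.times()
        assert np.all(out.occupancy[(t < 2.0) | (t >= 8.0)] == 0)
        assert np.all(out.occupancy[(t >= 2.0) & (t < 8.0)] == 1)

    def test_trapped_variance_matches_ou_energy_bookkeeping(self):
        # instrument and conformational noise off: trapped-segment variance
        # must equal c^2 kB T / kappa (OU stationary variance through the
        # position responsivity)
        physics = TrapPhysics.for_radius(6.0)
        cfg = _quiet_config(duration=102.0, seed=13)
        out = ft.synthesize(cfg, _silent_preset(), physics)
        trapped = out.trace.values[int(2.0 * cfg.fs):]
        expected = (physics.position_responsivity ** 2
                    * K_B * physics.temperature / physics.stiffness)
        assert len(trapped) == 10 ** 6
        assert np.var(trapped) == pytest.approx(expected, rel=0.03)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            ft.synthesize(TraceConfig(duration=2.0, fs=200.0, t_trap=1.0),
                          ft.apo_preset())


class TestPresets:
    def test_holo_step_contrast_is_41_percent_larger(self):
        assert ft.holo_preset().step_contrast == pytest.approx(
            1.41 * ft.apo_preset().step_contrast, rel=1e-12)

    def test_holo_is_larger_and_conductive_with_lower_fluctuation(self):
        apo, holo = ft.apo_preset(), ft.holo_preset()
        assert holo.radius_nm == apo.radius_nm + 1.0
        assert holo.core_conductivity > apo.core_conductivity == 0.0
        assert holo.conf_amp_trapped < apo.conf_amp_trapped

    def test_trap_corner_frequency_below_nyquist(self):
        for preset in (ft.apo_preset(), ft.holo_preset()):
            physics = TrapPhysics.for_radius(preset.radius_nm)
            assert physics.corner_frequency < 10_000.0 / 2
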