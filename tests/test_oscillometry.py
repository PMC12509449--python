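import math

import numpy as np
import pytest

import capnovent as cv
from capnovent.errors import AliasingError, SingularFrequencyError


class TestForcingSpec:
    def test_default_grid_counts_and_band(self, spec):
        f = spec.frequency_array()
        assert len(f) == 23
        assert f.min() == pytest.approx(0.5)
        assert f.max() == pytest.approx(20.75)

    def test_pairwise_non_integer_multiples(self, spec):
        f = spec.frequency_array()
        for i in range(len(f)):
            for j in range(len(f)):
                if i == j:
                    continue
                ratio = f[i] / f[j]
                assert abs(ratio - round(ratio)) > 1e-9, (f[i], f[j])

    def test_bin_alignment(self, spec):
        k = spec.frequency_array() * spec.duration
        assert np.allclose(k, np.round(k))

    def test_low_sample_rate_rejected(self):
        with pytest.raises(AliasingError):
            cv.ForcingSpec(sample_rate=100.0)

    def test_integer_multiple_grid_rejected(self):
        freqs = tuple(np.arange(1, 24) * 0.5)  # 1.0/0.5 is integer
        with pytest.raises(ValueError):
            cv.ForcingSpec(frequencies=freqs, f_min=0.5, f_max=11.5)


class TestForcingSignal:
    def test_duration_and_determinism(self, spec):
        x = cv.make_forcing_signal(spec, seed=7)
        assert x.size == spec.n_samples == 2048
        assert np.array_equal(x, cv.make_forcing_signal(spec, seed=7))
        assert not np.array_equal(x, cv.make_forcing_signal(spec, seed=8))

    def test_spectral_mass_only_at_component_bins(self, spec):
        x = cv.make_forcing_signal(spec, seed=1)
        mag = np.abs(np.fft.rfft(x))
        bins = np.round(spec.frequency_array() * spec.duration).astype(int)
        peak = mag[bins].max()
        off = np.delete(mag, bins)
        assert off.max() < 0.01 * peak


class TestEstimateImpedance:
    def test_pure_resistor(self, spec):
        p = cv.make_forcing_signal(spec, seed=2)
        z = cv.estimate_impedance(p, p / 30.0, spec)
        assert np.allclose(z.values.real, 30.0, atol=0.1)
        assert np.all(np.abs(z.values.imag) < 0.1)
        assert z.ensemble_count == 1

    def test_rc_compartment(self, spec, synth_flow):
        r, c = 20.0, 0.005
        f = spec.frequency_array()
        z_true = r - 1j / (2 * np.pi * f * c)
        p = cv.make_forcing_signal(spec, seed=3)
        flow = synth_flow(p, z_true, spec)
        z = cv.estimate_impedance(p, flow, spec)
        assert np.all(np.abs(z.values - z_true) <= 0.01 * np.abs(z_true))

    def test_zero_flow_is_singular(self, spec):
        p = cv.make_forcing_signal(spec, seed=4)
        with pytest.raises(SingularFrequencyError):
            cv.estimate_impedance(p, np.zeros_like(p), spec)

    def test_short_series_rejected(self, spec):
        p = cv.make_forcing_signal(spec, seed=5)[:256]
        with pytest.raises(ValueError):
            cv.estimate_impedance(p, p / 10.0, spec)


class TestTubeSubtractionAndAveraging:
    def test_zero_tube_is_identity(self, spec, canonical_mech):
        f = spec.frequency_array()
        z = cv.cpm_impedance(canonical_mech, f)
        zero = cv.ImpedanceSpectrum(f, np.zeros_like(z.values))
        assert np.array_equal(cv.subtract_tube_impedance(z, zero).values, z.values)

    def test_self_subtraction_is_zero(self, spec, canonical_mech):
        z = cv.cpm_impedance(canonical_mech, spec.frequency_array())
        assert np.allclose(cv.subtract_tube_impedance(z, z).values, 0.0)

    def test_tube_round_trip(self, spec, canonical_mech):
        f = spec.frequency_array()
        lung = cv.cpm_impedance(canonical_mech, f)
        tube = cv.tube_impedance(f, resistance=2.0, inertance=0.01)
        total = cv.ImpedanceSpectrum(f, lung.values + tube.values)
        back = cv.subtract_tube_impedance(total, tube)
        assert np.all(np.abs(back.values - lung.values) < 1e-9)

    def test_grid_mismatch(self, spec, canonical_mech):
        f = spec.frequency_array()
        z = cv.cpm_impedance(canonical_mech, f)
        other = cv.cpm_impedance(canonical_mech, f + 0.125)
        with pytest.raises(ValueError):
            cv.subtract_tube_impedance(z, other)

    def test_average_single_is_identity(self, spec, canonical_mech):
        z = cv.cpm_impedance(canonical_mech, spec.frequency_array())
        avg = cv.ensemble_average([z])
        assert np.array_equal(avg.values, z.values)
        assert avg.ensemble_count == 1

    def test_average_conjugate_pair_is_real(self, spec, canonical_mech):
        f = spec.frequency_array()
        z = cv.cpm_impedance(canonical_mech, f)
        conj = cv.ImpedanceSpectrum(f, np.conj(z.values))
        avg = cv.ensemble_average([z, conj])
        assert np.allclose(avg.values.imag, 0.0)
        assert avg.ensemble_count == 2

    def test_average_empty_rejected(self):
        with pytest.raises(ValueError):
            cv.ensemble_average([])

    def test_noise_shrinks_as_sqrt_n(self, spec, canonical_mech):
        f = spec.frequency_array()
        truth = cv.cpm_impedance(canonical_mech, f).values
        rng = np.random.default_rng(11)

        def noisy():
            eps = rng.standard_normal(f.size) + 1j * rng.standard_normal(f.size)
            return cv.ImpedanceSpectrum(f, truth + 2.0 * eps)

        singles = [noisy() for _ in range(20)]
        single_rms = np.mean(
            [np.sqrt(np.mean(np.abs(s.values - truth) ** 2)) for s in singles]
        )
        avg = cv.ensemble_average(singles)
        avg_rms = np.sqrt(np.mean(np.abs(avg.values - truth) ** 2))
        ratio = avg_rms / single_rms
        assert 0.1 < ratio < 0.4  # expected ~ 1/sqrt(20) = 0.224


class TestConstantPhaseModel:
    def test_alpha_half_when_g_equals_h(self):
        m = cv.MechanicalState(raw=10.0, iaw=0.05, g=200.0, h=200.0)
        assert m.alpha == pytest.approx(0.5)
        assert m.eta == pytest.approx(1.0)

    def test_alpha_limit_elastic(self):
        m = cv.MechanicalState(raw=10.0, iaw=0.05, g=1e-6, h=1000.0)
        assert m.alpha == pytest.approx(1.0, abs=1e-6)

    def test_hand_evaluated_value(self, canonical_mech):
        # independent hand evaluation of the formula at f = 5 Hz
        omega = 2.0 * math.pi * 5.0
        alpha = (2.0 / math.pi) * math.atan(1500.0 / 300.0)
        denom = omega**alpha
        expected = complex(
            25.0 + 300.0 / denom, omega * 0.1 - 1500.0 / denom
        )
        z = cv.cpm_impedance(canonical_mech, [5.0])
        assert z.values[0] == pytest.approx(expected, rel=1e-12)
        assert expected.real == pytest.approx(39.7, abs=0.05)
        assert expected.imag == pytest.approx(-70.5, abs=0.05)

    def test_nonpositive_frequency_rejected(self, canonical_mech):
        with pytest.raises(ValueError):
            cv.cpm_impedance(canonical_mech, [0.0, 5.0])

    def test_invalid_state_rejected(self):
        with pytest.raises(ValueError):
            cv.MechanicalState(raw=-1.0, iaw=0.1, g=300.0, h=1500.0)
        with pytest.raises(ValueError):
            cv.MechanicalState(raw=1.0, iaw=-0.1, g=300.0, h=1500.0)


class TestFitConstantPhase:
    def test_noiseless_recovery(self, spec, canonical_mech):
        z = cv.cpm_impedance(canonical_mech, spec.frequency_array())
        fit = cv.fit_constant_phase(z)
        assert fit.converged
        for name, truth in (
            ("raw", 25.0), ("iaw", 0.1), ("g", 300.0), ("h", 1500.0)
        ):
            assert getattr(fit.state, name) == pytest.approx(truth, rel=5e-3)

    def test_eta_is_derived_exactly(self, spec, canonical_mech):
        f = spec.frequency_array()
        truth = cv.cpm_impedance(canonical_mech, f).values
        rng = np.random.default_rng(0)
        noisy = truth * (1 + 0.05 * (rng.standard_normal(f.size) + 1j * rng.standard_normal(f.size)))
        fit = cv.fit_constant_phase(cv.ImpedanceSpectrum(f, noisy))
        assert fit.state.eta == fit.state.g / fit.state.h

    def test_noisy_recovery_small(self, spec, canonical_mech):
        f = spec.frequency_array()
        truth = cv.cpm_impedance(canonical_mech, f).values
        errs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            noisy = truth * (
                1 + 0.05 * (rng.standard_normal(f.size) + 1j * rng.standard_normal(f.size))
            )
            fit = cv.fit_constant_phase(
                cv.ImpedanceSpectrum(f, noisy), weights=1.0 / np.abs(noisy) ** 2
            )
            errs.append(abs(fit.state.h - 1500.0) / 1500.0)
        assert np.median(errs) < 0.05

    @pytest.mark.parametrize("subset_seed", [0, 1, 2])
    def test_frequency_subset_stability(self, spec, canonical_mech, subset_seed):
        f = spec.frequency_array()
        rng = np.random.default_rng(subset_seed)
        sub = np.sort(rng.choice(f.size, size=12, replace=False))
        z = cv.cpm_impedance(canonical_mech, f[sub])
        fit = cv.fit_constant_phase(z)
        for name, truth in (
            ("raw", 25.0), ("iaw", 0.1), ("g", 300.0), ("h", 1500.0)
        ):
            assert getattr(fit.state, name) == pytest.approx(truth, rel=0.02)

    def test_round_trip_idempotent(self, spec, canonical_mech):
        f = spec.frequency_array()
        z = cv.cpm_impedance(canonical_mech, f)
        fit = cv.fit_constant_phase(z)
        z2 = cv.cpm_impedance(fit.state, f)
        fit2 = cv.fit_constant_phase(z2)
        z3 = cv.cpm_impedance(fit2.state, f)
        assert np.allclose(z2.values, z3.values, rtol=1e-6)

    def test_too_few_frequencies(self, canonical_mech):
        z = cv.cpm_impedance(canonical_mech, [1.0, 2.1, 5.3])
        with pytest.raises(ValueError):
            cv.fit_constant_phase(z)

    def test_coarse_grid_oracle_small(self, spec, canonical_mech):
        # 7^4 grid sanity version of the full acceptance oracle
        f = spec.frequency_array()
        omega = 2 * np.pi * f
        rng = np.random.default_rng(42)
        noisy = cv.cpm_impedance(canonical_mech, f).values * (
            1 + 0.05 * (rng.standard_normal(f.size) + 1j * rng.standard_normal(f.size))
        )
        z = cv.ImpedanceSpectrum(f, noisy)
        fit = cv.fit_constant_phase(z)
        axes = [
            np.geomspace(v / 10, v * 10, 7)
            for v in (25.0, 0.1, 300.0, 1500.0)
        ]
        rr, ii, gg, hh = np.meshgrid(*axes, indexing="ij")
        alpha = (2 / np.pi) * np.arctan(hh / gg)
        cost = np.zeros(rr.shape)
        for wi, zi in zip(omega, noisy):
            cost += np.abs(rr + 1j * wi * ii + (gg - 1j * hh) / wi**alpha - zi) ** 2
        assert fit.cost <= cost.min() + 1e-9


class TestSpectrumIO:
    def test_csv_round_trip(self, tmp_path, spec, canonical_mech):
        z = cv.cpm_impedance(canonical_mech, spec.frequency_array())
        path = tmp_path / "z.csv"
        z.to_csv(path)
        back = cv.ImpedanceSpectrum.from_csv(path)
        assert np.allclose(back.values, z.values)
        assert back.ensemble_count == z.ensemble_count

    def test_invalid_spectrum_rejected(self):
        with pytest.raises(ValueError):
            cv.ImpedanceSpectrum(np.array([2.0, 1.0]), np.array([1 + 0j, 2 + 0j]))
        with pytest.raises(ValueError):
            cv.ImpedanceSpectrum(np.array([1.0, 2.0]), np.array([1 + 0j, 2 + 0j]), 0)
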