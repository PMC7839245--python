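import numpy as np
import pytest

from varvent.fot_mechanics import (DEFAULT_FREQUENCIES, FitError,
                                   ForcingDesign, ImpedanceSpectrum,
                                   MechanicsParams, average_epochs,
                                   constant_phase_model, cp_impedance,
                                   design_forcing_signal, estimate_impedance,
                                   fit_constant_phase,
                                   subtract_circuit_impedance,
                                   validate_nonharmonic)

FS = 1000.0


def _synthesize_flow_through(pressure, z_of_f, fs):
    """Drive a known impedance with a pressure signal: flow = P/Z per bin."""
    P = np.fft.rfft(pressure)
    f = np.fft.rfftfreq(len(pressure), 1.0 / fs)
    z = z_of_f(np.maximum(f, 1e-9))
    return np.fft.irfft(P / z, n=len(pressure))


class TestForcingDesign:
    def test_single_component_peak_to_peak_exact(self):
        d = ForcingDesign(frequencies=np.array([1.0]), amplitude_pp=2.0)
        _, x, _ = design_forcing_signal(d, FS, seed=0)
        assert x.max() - x.min() == pytest.approx(2.0, abs=1e-12)

    def test_default_design_has_fifteen_components(self, default_forcing):
        design, t, x = default_forcing
        X = np.abs(np.fft.rfft(x))
        f = np.fft.rfftfreq(len(x), 1.0 / FS)
        band = (f >= 0.5) & (f <= 21.0)
        thr = 0.01 * X.max()
        peaks = [i for i in np.flatnonzero(band)
                 if X[i] > thr and X[i] >= X[i - 1] and X[i] >= X[i + 1]]
        assert len(peaks) == 15

    def test_energy_confined_to_design_frequencies(self, default_forcing):
        design, t, x = default_forcing
        X2 = np.abs(np.fft.rfft(x)) ** 2
        f = np.fft.rfftfreq(len(x), 1.0 / FS)
        on = np.zeros(len(f), dtype=bool)
        for fd in design.frequencies:
            on |= np.abs(f - fd) < 0.15
        assert X2[~on].sum() / X2.sum() < 0.01

    def test_nonharmonic_validation(self):
        with pytest.raises(ValueError, match="integer multiple"):
            validate_nonharmonic([1.0, 2.0, 3.3])
        validate_nonharmonic(DEFAULT_FREQUENCIES)

    def test_realized_peak_to_peak_scaled(self, default_forcing):
        _, _, x = default_forcing
        assert x.max() - x.min() == pytest.approx(2.0, rel=1e-9)

    def test_aliasing_rejected(self):
        with pytest.raises(ValueError, match="aliasing"):
            design_forcing_signal(ForcingDesign(), sampling_rate=30.0)


class TestImpedanceEstimation:
    def test_pure_resistance(self, default_forcing):
        design, t, x = default_forcing
        spec = estimate_impedance(x, x / 25.0, FS, design)
        assert np.abs(spec.z_real - 25.0).max() < 0.1
        assert np.abs(spec.z_imag).max() < 0.1

    def test_pure_elastance_reactance(self, default_forcing):
        design, t, x = default_forcing
        E = 400.0
        flow = _synthesize_flow_through(x, lambda f: -1j * E / (2 * np.pi * f),
                                        FS)
        spec = estimate_impedance(x, flow, FS, design)
        expected = -E / (2 * np.pi * design.frequencies)
        assert np.abs(spec.z_imag - expected).max() < 0.1
        assert np.abs(spec.z_real).max() < 0.1

    def test_pure_inertance_reactance(self, default_forcing):
        design, t, x = default_forcing
        I = 0.02
        flow = _synthesize_flow_through(x, lambda f: 1j * 2 * np.pi * f * I, FS)
        spec = estimate_impedance(x, flow, FS, design)
        expected = 2 * np.pi * design.frequencies * I
        assert np.abs(spec.z_imag - expected).max() < 0.1

    def test_noise_robustness(self, default_forcing):
        """20 dB SNR: |Z - true| < 3% at every frequency, coherence > 0.95."""
        design, t, x = default_forcing
        truth = MechanicsParams(raw=25.0, iaw=0.01, g=45.0, h=420.0)
        flow = _synthesize_flow_through(
            x, lambda f: cp_impedance(25.0, 0.01, 45.0, 420.0, f), FS)
        rng = np.random.default_rng(8)
        snr_amp = 10 ** (-20 / 20)
        p_noisy = x + snr_amp * x.std() * rng.standard_normal(len(x))
        f_noisy = flow + snr_amp * flow.std() * rng.standard_normal(len(flow))
        spec = estimate_impedance(p_noisy, f_noisy, FS, design)
        z_true = cp_impedance(25.0, 0.01, 45.0, 420.0, design.frequencies)
        rel = np.abs(spec.z - z_true) / np.abs(z_true)
        assert rel.max() < 0.03
        assert spec.coherence.min() > 0.95

    def test_zero_flow_power_errors(self, default_forcing):
        design, t, x = default_forcing
        with pytest.raises(ValueError, match="no flow power"):
            estimate_impedance(x, np.zeros_like(x), FS, design)

    def test_record_shorter_than_window_errors(self, default_forcing):
        design, _, _ = default_forcing
        with pytest.raises(ValueError):
            estimate_impedance(np.ones(100), np.ones(100), FS, design)


class TestEpochsAndCircuit:
    def _spec(self, zr, zi=None):
        f = DEFAULT_FREQUENCIES
        zr = np.full(len(f), float(zr))
        zi = np.zeros(len(f)) if zi is None else np.full(len(f), float(zi))
        return ImpedanceSpectrum(f, zr, zi)

    def test_identical_epochs_average_to_themselves(self):
        s = self._spec(25.0, -3.0)
        out = average_epochs([s, s, s])
        assert np.array_equal(out.z, s.z)

    def test_arithmetic_mean_and_permutation_invariance(self):
        specs = [self._spec(v) for v in (20.0, 25.0, 30.0)]
        fwd = average_epochs(specs)
        rev = average_epochs(specs[::-1])
        assert np.allclose(fwd.z_real, 25.0)
        assert np.array_equal(fwd.z, rev.z)

    def test_grid_mismatch_errors(self):
        s1 = self._spec(25.0)
        s2 = ImpedanceSpectrum(DEFAULT_FREQUENCIES + 0.1,
                               np.full(15, 25.0), np.zeros(15))
        with pytest.raises(ValueError):
            average_epochs([s1, s2])

    def test_circuit_subtraction_inverse(self):
        lung = constant_phase_model(
            MechanicsParams(raw=25.0, iaw=0.01, g=45.0, h=420.0),
            DEFAULT_FREQUENCIES)
        tube = self._spec(5.0, 2.0)
        composite = ImpedanceSpectrum(DEFAULT_FREQUENCIES,
                                      lung.z_real + tube.z_real,
                                      lung.z_imag + tube.z_imag)
        back = subtract_circuit_impedance(composite, tube)
        assert np.allclose(back.z, lung.z, atol=1e-9)
        zero = self._spec(0.0)
        assert np.array_equal(subtract_circuit_impedance(lung, zero).z, lung.z)


class TestConstantPhaseModel:
    def test_alpha_half_when_g_equals_h(self):
        assert MechanicsParams(raw=1, iaw=0, g=50.0, h=50.0).alpha == \
            pytest.approx(0.5)

    def test_alpha_limit_small_h(self):
        p = MechanicsParams(raw=1, iaw=0, g=50.0, h=1e-9)
        assert p.alpha < 1e-9
        z = cp_impedance(p.raw, p.iaw, p.g, p.h, np.array([1.0, 5.0, 20.0]))
        # tissue term degenerates to a frequency-independent real g
        assert np.allclose(z.real, 1.0 + 50.0, rtol=1e-6)

    def test_hand_computed_value(self):
        """Independent complex arithmetic at f = 5 Hz."""
        import cmath
        import math
        alpha = (2 / math.pi) * math.atan(10.0)
        omega = 2 * math.pi * 5.0
        expected = 20.0 + 1j * omega * 0.01 + \
            (40.0 - 400.0j) / cmath.exp(alpha * cmath.log(omega))
        got = cp_impedance(20.0, 0.01, 40.0, 400.0, np.array([5.0]))[0]
        assert got == pytest.approx(expected, abs=1e-9)
        assert alpha == pytest.approx(0.93655, abs=1e-5)

    def test_zero_frequency_singular(self):
        with pytest.raises(ValueError):
            cp_impedance(20.0, 0.01, 40.0, 400.0, np.array([0.0]))


class TestInverseFit:
    def test_inverse_crime_recovery(self):
        """Noise-free spectra from random admissible draws recovered within
        0.5% for every parameter."""
        rng = np.random.default_rng(4)
        for _ in range(10):
            truth = MechanicsParams(raw=rng.uniform(5, 80),
                                    iaw=rng.uniform(0.002, 0.2),
                                    g=rng.uniform(10, 200),
                                    h=rng.uniform(100, 1200))
            spec = constant_phase_model(truth, DEFAULT_FREQUENCIES)
            fit = fit_constant_phase(spec, n_starts=20, seed=1)
            for name in ("raw", "iaw", "g", "h"):
                assert getattr(fit, name) == pytest.approx(
                    getattr(truth, name), rel=5e-3), name

    def test_fit_invariant_to_frequency_ordering(self):
        truth = MechanicsParams(raw=25.0, iaw=0.01, g=45.0, h=420.0)
        spec = constant_phase_model(truth, DEFAULT_FREQUENCIES)
        perm = np.random.default_rng(0).permutation(15)
        shuffled = ImpedanceSpectrum(spec.frequencies[perm],
                                     spec.z_real[perm], spec.z_imag[perm])
        f1 = fit_constant_phase(spec, n_starts=8, seed=3)
        f2 = fit_constant_phase(shuffled, n_starts=8, seed=3)
        assert f1.h == pytest.approx(f2.h, rel=1e-6)

    def test_pure_resistor_flags_boundary(self):
        spec = ImpedanceSpectrum(DEFAULT_FREQUENCIES, np.full(15, 30.0),
                                 np.zeros(15))
        fit = fit_constant_phase(spec, n_starts=12, seed=2)
        assert fit.boundary_flag
        assert fit.raw + fit.g / (2 * np.pi * 10.0) ** fit.alpha == \
            pytest.approx(30.0, abs=1.5)

    def test_noise_never_improves_median_residual(self):
        truth = MechanicsParams(raw=25.0, iaw=0.01, g=45.0, h=420.0)
        clean = constant_phase_model(truth, DEFAULT_FREQUENCIES)
        rng = np.random.default_rng(6)
        residuals = []
        for noise in (0.0, 0.02, 0.08):
            meds = []
            for _ in range(5):
                z = clean.z * (1 + noise * (rng.standard_normal(15)
                                            + 1j * rng.standard_normal(15)))
                fit = fit_constant_phase(
                    ImpedanceSpectrum(clean.frequencies, z.real, z.imag),
                    n_starts=6, seed=0)
                meds.append(fit.fit_residual)
            residuals.append(np.median(meds))
        assert residuals[0] <= residuals[1] <= residuals[2]

    def test_too_few_frequencies_errors(self):
        spec = ImpedanceSpectrum(DEFAULT_FREQUENCIES[:4], np.full(4, 30.0),
                                 np.zeros(4))
        with pytest.raises(ValueError):
            fit_constant_phase(spec)
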