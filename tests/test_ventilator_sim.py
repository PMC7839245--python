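import numpy as np
import pytest

from varvent.synthetic_data import (GasExchangeSimParams, LungModelState,
                                    evolve_lung_state)
from varvent.ventilator_sim import (PressureFlowSignal, VentSettings,
                                    adapt_rr_for_normocapnia, apply_to_lung,
                                    delivered_vt_closed_form,
                                    detect_auto_peep, make_breath_waveform,
                                    recruitment_maneuver, run_ventilation,
                                    _effective_re)


def _settings(**kw):
    defaults = dict(peep=3.0, driving_pressure=10.0, rr=24.0, rise_time=0.0)
    defaults.update(kw)
    return VentSettings(**defaults)


class TestWaveform:
    def test_timing_arithmetic(self):
        t, p = make_breath_waveform(_settings(), sampling_rate=1000.0)
        assert len(t) == 2500                      # 2.5 s period at RR 24
        plateau = np.isclose(p, 13.0)
        assert plateau.sum() == 625                # I:E 1:3 -> 0.625 s at PIP
        assert p[-1] == pytest.approx(3.0)

    def test_zero_pressure_ratio_is_apneic(self):
        t, p = make_breath_waveform(_settings(), breath=(0.0, 1.0),
                                    sampling_rate=500.0)
        assert np.allclose(p, 3.0)

    def test_pvv_loop_mean_drive_equals_pcv(self, pvv_pattern):
        """Unit-mean ratios: mean per-breath driving pressure over one loop
        equals the PCV setting."""
        s = _settings()
        drives = s.driving_pressure * pvv_pattern.pressure_ratios
        assert drives.mean() == pytest.approx(s.driving_pressure, rel=1e-9)

    def test_too_short_inspiration_errors(self):
        with pytest.raises(ValueError):
            make_breath_waveform(_settings(rr=59.0), breath=(1.0, 0.01),
                                 sampling_rate=200.0)


class TestForwardModel:
    def test_rc_charging_oracle(self):
        """Sampled solver against (dP/E)(1 - exp(-T.E/R)) within 0.5%."""
        lung = LungModelState(raw=20.0, g_tissue=40.0, h_tissue=400.0)
        s = _settings()
        t, p = make_breath_waveform(s, sampling_rate=1000.0)
        _, vt = apply_to_lung(t, p, lung, s)
        r_eff, e_eff = _effective_re(lung, 0.4)
        vt_expected = (10.0 / e_eff) * (1 - np.exp(-0.625 * e_eff / r_eff))
        vt_expected *= 1000.0 / s.weight_kg
        assert vt == pytest.approx(vt_expected, rel=5e-3)

    def test_quasi_static_limit(self):
        """R -> 0: full equilibration, VT = dP/E exactly."""
        lung = LungModelState(raw=1e-3, g_tissue=1e-3, h_tissue=400.0)
        vt, _ = delivered_vt_closed_form(10.0, 400.0, 1e-4, 0.625, 1.875)
        assert vt == pytest.approx(10.0 / 400.0, rel=1e-9)

    def test_vt_halves_when_elastance_doubles(self):
        vt1, _ = delivered_vt_closed_form(10.0, 400.0, 1e-4, 0.625, 1.875)
        vt2, _ = delivered_vt_closed_form(10.0, 800.0, 1e-4, 0.625, 1.875)
        assert vt2 == pytest.approx(vt1 / 2.0, rel=1e-6)

    def test_volume_conservation(self):
        """Inspired minus expired volume equals the trapped volume, and the
        integrator agrees with the state trajectory to 0.1%."""
        lung = LungModelState()
        s = _settings(rr=40.0)                     # short expiration traps gas
        t, p = make_breath_waveform(s, sampling_rate=1000.0)
        sig, _ = apply_to_lung(t, p, lung, s)
        dt = 1.0 / sig.sampling_rate
        inspired = np.trapezoid(np.clip(sig.flow, 0, None), dx=dt)
        expired = np.trapezoid(np.clip(-sig.flow, 0, None), dx=dt)
        trapped = sig.volume[-1] - sig.volume[0]
        assert inspired - expired == pytest.approx(trapped, abs=1e-3 * inspired)


class TestControllersAndManeuvers:
    def test_rr_unchanged_inside_band(self):
        rr, pinned = adapt_rr_for_normocapnia(24.0, 0.0575)
        assert rr == 24.0 and not pinned

    def test_rr_rises_under_hypercapnia(self):
        rr, _ = adapt_rr_for_normocapnia(24.0, 0.07)
        assert rr == 25.0

    def test_rr_falls_under_hypocapnia_and_clamps(self):
        rr, _ = adapt_rr_for_normocapnia(24.0, 0.04)
        assert rr == 23.0
        rr, pinned = adapt_rr_for_normocapnia(10.0, 0.04)
        assert rr == 10.0 and pinned

    def test_closed_loop_holds_normocapnia(self):
        """With elastance rising through derecruitment, the RR controller
        keeps EtCO2 within the band (+/-0.2 points) for >=90% of epochs
        after burn-in."""
        res = run_ventilation(LungModelState(), VentSettings(mode="PCV"),
                              GasExchangeSimParams(), hours=6.0)
        etco2_pct = 100.0 * res.etco2_trace[6:]    # skip 30-min burn-in
        in_band = (etco2_pct >= 5.5 - 0.2) & (etco2_pct <= 6.0 + 0.2)
        assert in_band.mean() >= 0.9

    def test_recruitment_maneuver(self):
        lung = LungModelState(open_fraction=0.7)
        out = recruitment_maneuver(lung)
        assert out.open_fraction == 1.0
        assert recruitment_maneuver(out) == out    # idempotent
        assert out.effective_elastance == out.h_tissue

    def test_settings_validation(self):
        with pytest.raises(ValueError):
            VentSettings(mode="PVV")               # pattern required
        with pytest.raises(ValueError):
            VentSettings(driving_pressure=-1.0)


class TestAutoPeep:
    def _breath_signal(self, lung, t_exp_factor):
        """One square breath whose expiratory time is t_exp_factor time
        constants (R-E mapping pinned at 0.4 Hz)."""
        r_eff, e_eff = _effective_re(lung, 0.4)
        tau = r_eff / e_eff
        t_insp = 10 * tau                          # complete charge
        t_exp = t_exp_factor * tau
        fs = 5000.0
        n_i, n_e = int(t_insp * fs), int(t_exp * fs)
        t = np.arange(n_i + n_e) / fs
        p = np.full_like(t, 3.0)
        p[:n_i] += 10.0
        s = _settings()
        sig, _ = apply_to_lung(t, p, lung, s, breathing_freq=0.4)
        return sig, e_eff

    def test_long_expiration_not_flagged(self):
        lung = LungModelState()
        sig, _ = self._breath_signal(lung, t_exp_factor=8.0)
        out = detect_auto_peep(sig, lung)
        assert not out["flag"]
        assert out["magnitude"] < 0.05

    def test_single_time_constant_traps_e_minus_one(self):
        lung = LungModelState()
        sig, e_eff = self._breath_signal(lung, t_exp_factor=1.0)
        out = detect_auto_peep(sig, lung)
        assert out["flag"]
        trapped_frac = sig.volume[-1] / sig.volume.max()
        assert trapped_frac == pytest.approx(np.exp(-1), rel=0.02)
        assert out["magnitude"] == pytest.approx(e_eff * sig.volume[-1],
                                                 rel=1e-9)

    def test_zero_flow_not_flagged(self):
        n = 1000
        sig = PressureFlowSignal(np.arange(n) / 1000.0, np.full(n, 3.0),
                                 np.zeros(n), np.zeros(n), 1000.0)
        assert not detect_auto_peep(sig, LungModelState())["flag"]


class TestSixHourRun:
    def test_settings_held_constant(self, pvv_pattern):
        res = run_ventilation(LungModelState(),
                              VentSettings(mode="PVV", pattern=pvv_pattern),
                              hours=2.0)
        for col in ("driving_pressure", "peep", "fio2"):
            assert res.hourly[col].nunique() == 1

    def test_hourly_cadence(self):
        res = run_ventilation(LungModelState(), VentSettings(mode="PCV"),
                              hours=6.0)
        assert list(res.hourly["hour_label"]) == [f"H{i}" for i in range(7)]

    def test_monotonous_ventilation_derecruits(self):
        res = run_ventilation(LungModelState(), VentSettings(mode="PCV"),
                              hours=6.0)
        loss = 1.0 - res.final_state.open_fraction
        assert 0.10 < loss < 0.25
        assert res.hourly["effective_elastance"].is_monotonic_increasing
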