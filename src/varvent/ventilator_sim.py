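"""Six-hour pressure-controlled and variable ventilation on the synthetic lung.

The ventilator delivers square-ish pressure profiles (configurable rise time)
on top of PEEP; under PVV each breath's driving pressure and period are scaled
by the pattern ratios, under PCV every breath is identical.  The lung is a
single-compartment R–E system: ``P_aw(t) = R.V'(t) + E_eff.V(t) + PEEP`` with

* ``E_eff = h_tissue / open_fraction`` (derecruitment stiffens the lung), and
* ``R = raw + g_tissue / (2*pi*f_b)**alpha`` evaluated at the breathing
  frequency ``f_b`` — the low-frequency tissue-damping contribution of the
  constant-phase tissue compartment folded into a Newtonian resistance.

The long runs use the exact per-breath solution of this linear system
(charging/discharging exponentials with end-expiratory volume carry-over);
:func:`apply_to_lung` provides the sampled waveform solution and is checked
against the same closed form.  Respiratory rate is adapted by a bounded
proportional controller to keep end-tidal CO2 inside the normocapnia band
(5.5–6%), and recruitment maneuvers (25 cmH2O held twice for 10 s) normalize
volume history.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .breath_pattern import VentilationPattern
from .synthetic_data import (GasExchangeSimParams, LungModelState,
                             evolve_lung_state, generate_blood_gas)

__all__ = [
    "VentSettings",
    "PressureFlowSignal",
    "RunResult",
    "make_breath_waveform",
    "apply_to_lung",
    "delivered_vt_closed_form",
    "adapt_rr_for_normocapnia",
    "recruitment_maneuver",
    "detect_auto_peep",
    "run_ventilation",
]


@dataclass
class VentSettings:
    """Ventilator settings shared by both modes.

    ``ie_ratio`` is T_insp/T_exp (1:3 by default, i.e. 1/3).  ``driving_pressure``
    is peak inspiratory pressure minus PEEP; under PVV the per-breath driving
    pressure is ``driving_pressure * pressure_ratio`` so its mean over one
    pattern loop equals the set value.  ``weight_kg`` converts the absolute
    compartment volume (L) to mL/kg.
    """

    peep: float = 3.0                 # cmH2O
    driving_pressure: float = 9.0     # cmH2O
    ie_ratio: float = 1.0 / 3.0
    fio2: float = 0.4
    target_vt: float = 7.0            # mL/kg
    rr: float = 24.0                  # breaths/min
    mode: str = "PCV"
    pattern: VentilationPattern | None = None
    rise_time: float = 0.05           # s
    weight_kg: float = 3.4

    def __post_init__(self) -> None:
        if self.peep < 0:
            raise ValueError("peep must be non-negative")
        if self.driving_pressure <= 0:
            raise ValueError("driving_pressure must be positive")
        if self.ie_ratio <= 0:
            raise ValueError("ie_ratio must be positive")
        if not 0.21 < self.fio2 <= 1.0:
            raise ValueError("fio2 must lie in (0.21, 1.0]")
        if self.mode not in ("PCV", "PVV"):
            raise ValueError("mode must be 'PCV' or 'PVV'")
        if self.mode == "PVV" and self.pattern is None:
            raise ValueError("PVV requires a ventilation pattern")

    def breath_times(self, period_ratio: float = 1.0) -> tuple[float, float]:
        """(inspiratory time, expiratory time) for one breath, seconds."""
        period = 60.0 / self.rr * period_ratio
        t_insp = period * self.ie_ratio / (1.0 + self.ie_ratio)
        return t_insp, period - t_insp


@dataclass
class PressureFlowSignal:
    """Sampled airway pressure, flow and integrated volume."""

    time: np.ndarray           # s
    airway_pressure: np.ndarray  # cmH2O
    flow: np.ndarray           # L/s
    volume: np.ndarray         # L above end-expiratory lung volume
    sampling_rate: float       # Hz

    def __post_init__(self) -> None:
        n = len(self.time)
        if not (len(self.airway_pressure) == len(self.flow) == len(self.volume) == n):
            raise ValueError("signal arrays must share one length")
        if self.sampling_rate < 100.0:
            raise ValueError("sampling_rate below 100 Hz is too coarse for "
                             "simulation fidelity")


def _effective_re(lung: LungModelState, breathing_freq: float) -> tuple[float, float]:
    """Map (raw, g, h, open_fraction) to the single-compartment (R, E)."""
    alpha = (2.0 / np.pi) * np.arctan(lung.h_tissue / lung.g_tissue)
    omega = 2.0 * np.pi * breathing_freq
    r_eff = lung.raw + lung.g_tissue / omega**alpha
    return r_eff, lung.effective_elastance


# ---------------------------------------------------------------------------
# waveforms and the forward solve
# ---------------------------------------------------------------------------

def make_breath_waveform(settings: VentSettings,
                         breath: tuple[float, float] = (1.0, 1.0),
                         sampling_rate: float = 1000.0,
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Pressure profile for one breath: linear rise, plateau, return to PEEP.

    ``breath`` carries the (pressure_ratio, period_ratio) pair; PCV uses
    (1, 1) for every breath.  A pressure_ratio of 0 yields a flat PEEP trace
    (apneic breath).
    """
    pr, tr = breath
    if pr < 0 or tr <= 0:
        raise ValueError("pressure_ratio must be >= 0 and period_ratio > 0")
    t_insp, t_exp = settings.breath_times(tr)
    n_insp = int(round(t_insp * sampling_rate))
    if n_insp < 2:
        raise ValueError("inspiratory time shorter than 2 samples")
    n = int(round((t_insp + t_exp) * sampling_rate))
    t = np.arange(n) / sampling_rate
    p = np.full(n, settings.peep)
    plateau = settings.driving_pressure * pr
    rise = min(settings.rise_time, t_insp / 2.0)
    insp = t < t_insp
    if rise > 0:
        ramp = np.clip(t / rise, 0.0, 1.0)
    else:
        ramp = np.ones(n)
    p[insp] += plateau * ramp[insp]
    # symmetric fall at the start of expiration
    fall = min(settings.rise_time, t_exp / 2.0)
    if fall > 0:
        exp = ~insp
        decay = np.clip(1.0 - (t[exp] - t_insp) / fall, 0.0, 1.0)
        p[exp] += plateau * decay
    return t, p


def apply_to_lung(t: np.ndarray, pressure: np.ndarray, lung: LungModelState,
                  settings: VentSettings, v0: float = 0.0,
                  breathing_freq: float | None = None,
                  ) -> tuple[PressureFlowSignal, float]:
    """Solve the single-compartment equation for a sampled pressure trace.

    Integrates ``V' = (P_aw - PEEP - E_eff V) / R`` with the exact exponential
    update on each sampling interval (pressure held at the midpoint value),
    starting from volume ``v0`` (L above FRC).  ``breathing_freq`` fixes the
    frequency at which the tissue damping folds into the Newtonian resistance
    (default: one cycle per record).  Returns the sampled signal and the
    delivered tidal volume in mL/kg (inspired volume above the starting
    volume).
    """
    t = np.asarray(t, dtype=float)
    pressure = np.asarray(pressure, dtype=float)
    if len(t) < 2:
        raise ValueError("need at least two samples")
    fs = 1.0 / (t[1] - t[0])
    period = t[-1] - t[0] + 1.0 / fs
    r_eff, e_eff = _effective_re(lung, breathing_freq or 1.0 / period)
    tau = r_eff / e_eff
    v = np.empty_like(t)
    v[0] = v0
    dt = np.diff(t)
    pm = 0.5 * (pressure[1:] + pressure[:-1])
    decay = np.exp(-dt / tau)
    vinf = (pm - settings.peep) / e_eff
    for i in range(len(t) - 1):
        v[i + 1] = vinf[i] + (v[i] - vinf[i]) * decay[i]
    flow = np.gradient(v, t)
    sig = PressureFlowSignal(time=t, airway_pressure=pressure, flow=flow,
                             volume=v, sampling_rate=fs)
    vt_ml_kg = (v.max() - v0) * 1000.0 / settings.weight_kg
    return sig, vt_ml_kg


def delivered_vt_closed_form(dp: float, e_eff: float, r_eff: float,
                             t_insp: float, t_exp: float,
                             v0: float = 0.0) -> tuple[float, float]:
    """Exact RC charging/discharging solution for one square breath.

    Returns ``(delivered VT in L, end-expiratory volume in L)`` for a breath
    that holds PEEP + dp for ``t_insp`` then PEEP for ``t_exp``, starting from
    volume ``v0`` above FRC.
    """
    tau = r_eff / e_eff
    v_end_insp = dp / e_eff + (v0 - dp / e_eff) * np.exp(-t_insp / tau)
    v_end_exp = v_end_insp * np.exp(-t_exp / tau)
    return v_end_insp - v0, v_end_exp


# ---------------------------------------------------------------------------
# controllers and maneuvers
# ---------------------------------------------------------------------------

def adapt_rr_for_normocapnia(rr: float, etco2: float,
                             band: tuple[float, float] = (0.055, 0.060),
                             step: float = 1.0,
                             bounds: tuple[float, float] = (10.0, 60.0),
                             ) -> tuple[float, bool]:
    """One controller epoch: nudge RR toward the normocapnia band.

    ``etco2`` is the end-tidal CO2 fraction.  RR rises by ``step`` when CO2 is
    above the band, falls when below, and is clamped to ``bounds``.  Returns
    the new RR and a flag that is True when the band is unreachable because
    the controller is pinned at a bound.
    """
    lo, hi = band
    new_rr = rr
    if etco2 > hi:
        new_rr = rr + step
    elif etco2 < lo:
        new_rr = rr - step
    clamped = min(max(new_rr, bounds[0]), bounds[1])
    pinned = clamped != new_rr
    return clamped, pinned


def recruitment_maneuver(lung: LungModelState, max_open: float = 1.0,
                         pressure: float = 25.0, hold_s: float = 10.0,
                         repeats: int = 2) -> LungModelState:
    """Sustained-inflation maneuver normalizing volume history.

    A hold at ``pressure`` cmH2O applied ``repeats`` times for ``hold_s``
    seconds re-opens all recruitable units: the open fraction is set to its
    configured maximum.  Idempotent.
    """
    if not 0.0 < max_open <= 1.0:
        raise ValueError("max_open must lie in (0, 1]")
    del pressure, hold_s, repeats  # recorded in the protocol, not in the state
    return dataclasses.replace(lung,
                               open_fraction=max(lung.open_fraction, max_open))


def detect_auto_peep(signal: PressureFlowSignal, lung: LungModelState,
                     threshold_frac: float = 0.05) -> dict:
    """Flag incomplete exhalation (intrinsic PEEP) on one breath.

    A breath is flagged when the end-expiratory flow magnitude exceeds
    ``threshold_frac`` of the peak expiratory flow; the magnitude is the
    alveolar pressure above set PEEP at end-expiration,
    ``E_eff * V(end)``.
    """
    flow_end = signal.flow[-1]
    peak_exp = float(np.max(-signal.flow, initial=0.0))
    if peak_exp <= 0:
        return {"flag": False, "magnitude": 0.0}
    flag = abs(flow_end) > threshold_frac * peak_exp
    magnitude = lung.effective_elastance * max(signal.volume[-1], 0.0)
    return {"flag": bool(flag), "magnitude": float(magnitude)}


# ---------------------------------------------------------------------------
# the 6-h run
# ---------------------------------------------------------------------------

@dataclass
class RunResult:
    """Outcome of a simulated ventilation run."""

    hourly: pd.DataFrame
    final_state: LungModelState
    settings: VentSettings
    breath_vt: np.ndarray       # mL/kg per breath
    breath_period: np.ndarray   # s per breath
    etco2_trace: np.ndarray     # per controller epoch
    rr_trace: np.ndarray


def _calibrate_driving_pressure(lung: LungModelState, settings: VentSettings,
                                ) -> float:
    """Driving pressure delivering the target VT at the initial state."""
    t_insp, _ = settings.breath_times()
    r_eff, e_eff = _effective_re(lung, settings.rr / 60.0)
    target_l = settings.target_vt * settings.weight_kg / 1000.0
    charge = 1.0 - np.exp(-t_insp * e_eff / r_eff)
    return target_l * e_eff / charge


def run_ventilation(lung: LungModelState, settings: VentSettings,
                    gas_params: GasExchangeSimParams | None = None,
                    hours: float = 6.0, epoch_min: float = 5.0,
                    rr_bounds: tuple[float, float] = (10.0, 60.0),
                    calibrate_dp: bool = True) -> RunResult:
    """Simulate a multi-hour ventilation run breath by breath.

    The protocol follows the modeled experiment: recruitment maneuver,
    driving pressure
    calibrated at H0 to deliver the target VT and then held constant, RR
    adapted per 5-min epoch to normocapnia, hourly measurement rows (H0..H6)
    with lung state, delivered VT, effective elastance and blood gases.
    Under PVV the pattern ratios are replayed in a loop; under PCV every
    breath is identical.
    """
    gas_params = gas_params or GasExchangeSimParams()
    state = recruitment_maneuver(lung)
    settings = dataclasses.replace(settings)  # private copy (rr mutates)
    if calibrate_dp:
        settings.driving_pressure = _calibrate_driving_pressure(state, settings)

    pattern = settings.pattern
    if settings.mode == "PVV":
        ratios = np.column_stack([pattern.pressure_ratios,
                                  pattern.period_ratios])
    else:
        ratios = np.array([[1.0, 1.0]])

    total_s = hours * 3600.0
    epoch_s = epoch_min * 60.0
    weight = settings.weight_kg

    t = 0.0
    i_breath = 0
    v_carry = 0.0
    vts: list[float] = []
    periods: list[float] = []
    epoch_vts: list[float] = []
    epoch_periods: list[float] = []
    etco2_trace: list[float] = []
    rr_trace: list[float] = []
    hourly_rows: list[dict] = []
    next_epoch = epoch_s
    next_hour = 0.0

    def measure(label_hours: float) -> dict:
        # average VT over one full pattern loop so the hourly figure is not
        # aliased by where the loop happens to stand
        n_avg = max(len(ratios), 30)
        vt_recent = float(np.mean(vts[-n_avg:])) if vts else settings.target_vt
        rr_now = settings.rr
        sample, truth = generate_blood_gas(state, vt_recent, rr_now,
                                           settings.fio2, gas_params)
        return {"hour": label_hours,
                "open_fraction": state.open_fraction,
                "effective_elastance": state.effective_elastance,
                "vt_ml_kg": vt_recent,
                "rr": rr_now,
                "driving_pressure": settings.driving_pressure,
                "peep": settings.peep,
                "fio2": settings.fio2,
                "shunt": truth["shunt"],
                "pao2": sample.pao2,
                "paco2": sample.paco2,
                "pao2_fio2": sample.pao2 / sample.fio2}

    # H0 measurement with the freshly recruited lung delivering target VT
    vts_h0_done = False
    while t < total_s:
        pr, tr = ratios[i_breath % len(ratios)]
        i_breath += 1
        t_insp, t_exp = settings.breath_times(tr)
        period = t_insp + t_exp
        f_b = 1.0 / period
        r_eff, e_eff = _effective_re(state, f_b)
        vt_l, v_carry = delivered_vt_closed_form(
            settings.driving_pressure * pr, e_eff, r_eff, t_insp, t_exp,
            v0=v_carry)
        vt_ml_kg = vt_l * 1000.0 / weight
        vts.append(vt_ml_kg)
        periods.append(period)
        epoch_vts.append(vt_ml_kg)
        epoch_periods.append(period)
        state = evolve_lung_state(state, vt_ml_kg, period / 60.0)
        t += period

        if not vts_h0_done and len(vts) >= 30:
            hourly_rows.append(measure(0.0))
            vts_h0_done = True
            next_hour = 3600.0

        if t >= next_epoch:
            mean_vt = float(np.mean(epoch_vts))
            mean_rr = 60.0 / float(np.mean(epoch_periods))
            _, truth = generate_blood_gas(state, mean_vt, mean_rr,
                                          settings.fio2, gas_params)
            etco2 = truth["paco2"] / (gas_params.barometric_pressure -
                                      gas_params.water_vapor_pressure)
            new_rr, _ = adapt_rr_for_normocapnia(settings.rr, etco2,
                                                 bounds=rr_bounds)
            settings.rr = new_rr
            etco2_trace.append(etco2)
            rr_trace.append(new_rr)
            epoch_vts.clear()
            epoch_periods.clear()
            next_epoch += epoch_s

        if vts_h0_done and t >= next_hour and next_hour <= total_s:
            hourly_rows.append(measure(next_hour / 3600.0))
            next_hour += 3600.0

    hourly = pd.DataFrame(hourly_rows)
    hourly["hour_label"] = ["H%d" % round(h) for h in hourly["hour"]]
    return RunResult(hourly=hourly, final_state=state, settings=settings,
                     breath_vt=np.asarray(vts),
                     breath_period=np.asarray(periods),
                     etco2_trace=np.asarray(etco2_trace),
                     rr_trace=np.asarray(rr_trace))
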