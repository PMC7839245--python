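"""Seeded generators for every input the analysis pipeline consumes.

The study conditions emulated here are those of a COPD rabbit model under
prolonged mechanical ventilation:

* spontaneous breathing with breath-to-breath variability (tidal volume CV
  near 13%), recorded by whole-body plethysmography, with movement artifacts;
* a stiff lung (elevated tissue elastance) that slowly derecruits under
  monotonous ventilation and reopens in response to occasional large breaths;
* blood gases produced by a shunt mixing model, so the downstream shunt
  estimator can recover the generating shunt exactly;
* fluoroscopy-like frames with a controllable aerated area inside a
  lung-shaped region;
* histology-like binary airspace images with known chord lengths for
  validating mean-linear-intercept morphometry.

Every generator takes an explicit seed, is bit-reproducible, and returns its
ground truth alongside the data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .breath_pattern import PlethysmographRecording
from .gas_exchange import BloodGasSample, oxygen_content
from .saturation import (HILL_N_DEFAULT, P50_DEFAULT, o2_saturation,
                         po2_from_content)

__all__ = [
    "BreathingSimParams",
    "LungModelState",
    "GasExchangeSimParams",
    "generate_spontaneous_breathing",
    "evolve_lung_state",
    "generate_blood_gas",
    "generate_fluoro_frame",
    "generate_airspace_image",
]


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BreathingSimParams:
    """Spontaneous-breathing generator settings.

    Defaults reproduce the awake COPD-rabbit pattern used to derive the PVV
    schedule: mean tidal volume 7.1 mL/kg with 12.6% CV and mean rate
    22.9 /min with 12.9% CV, mild positive autocorrelation between
    successive breaths, and occasional movement artifacts.
    """

    mean_vt: float = 7.1          # mL/kg
    cv_vt: float = 0.126
    mean_rr: float = 22.9         # breaths/min
    cv_rr: float = 0.129
    ar1_coeff: float = 0.3
    artifact_rate: float = 0.5    # artifacts per minute
    artifact_duration: float = 2.0  # s
    sampling_rate: float = 1000.0   # Hz (plethysmograph digitization rate)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv_vt < 0 or self.cv_rr < 0:
            raise ValueError("CVs must be non-negative")
        if min(self.mean_vt, self.mean_rr, self.sampling_rate) <= 0:
            raise ValueError("mean_vt, mean_rr and sampling_rate must be positive")
        if not -1.0 < self.ar1_coeff < 1.0:
            raise ValueError("ar1_coeff must lie in (-1, 1)")
        if self.artifact_rate < 0 or self.artifact_duration < 0:
            raise ValueError("artifact settings must be non-negative")


@dataclass(frozen=True)
class LungModelState:
    """Mechanical lung with a recruited fraction of units.

    ``raw``/``iaw`` are Newtonian airway resistance and inertance; ``g_tissue``
    and ``h_tissue`` are the damping and elastance of the tissue compartment
    (constant-phase convention).  ``open_fraction`` is the recruited fraction
    of lung units; effective elastance is ``h_tissue / open_fraction``, so
    derecruitment stiffens the lung.  Closure proceeds exponentially at
    ``close_rate`` (fraction per minute) under monotonous ventilation; a
    breath exceeding ``reopen_threshold`` (mL/kg) reopens
    ``reopen_gain * (1 - open_fraction)`` units.

    Default mechanics are COPD-rabbit-like (elevated elastance); the closure
    defaults lose ~16% of open units over 6 h of monotonous 7 mL/kg breaths
    while breaths above 9 mL/kg recruit.
    """

    raw: float = 25.0             # cmH2O.s/L
    iaw: float = 0.01             # cmH2O.s^2/L
    g_tissue: float = 45.0        # cmH2O/L
    h_tissue: float = 380.0       # cmH2O/L
    open_fraction: float = 1.0
    close_rate: float = 5.0e-4    # per minute
    reopen_threshold: float = 9.0  # mL/kg
    reopen_gain: float = 0.02

    def __post_init__(self) -> None:
        if min(self.raw, self.g_tissue, self.h_tissue) <= 0:
            raise ValueError("raw, g_tissue and h_tissue must be positive")
        if self.iaw < 0:
            raise ValueError("iaw must be non-negative")
        if not 0.0 < self.open_fraction <= 1.0:
            raise ValueError("open_fraction must lie in (0, 1]")
        if self.close_rate < 0 or self.reopen_gain < 0:
            raise ValueError("close_rate and reopen_gain must be non-negative")

    @property
    def effective_elastance(self) -> float:
        """cmH2O/L: tissue elastance referred to the recruited units only."""
        return self.h_tissue / self.open_fraction


@dataclass(frozen=True)
class GasExchangeSimParams:
    """Forward blood-gas model settings.

    CO2 follows the alveolar-ventilation clearance law
    ``PaCO2 = 0.863 * VCO2 / VA`` (VCO2 in mL/min/kg STPD, VA in L/min/kg
    BTPS).  Shunt is ``baseline_shunt + shunt_per_closed_fraction * (1 -
    open_fraction)``.  Oxygen moves through the shared invertible Hill
    dissociation curve so the shunt estimator can recover the generating
    value.
    """

    hb: float = 12.0                      # g/dL
    barometric_pressure: float = 760.0    # mmHg
    water_vapor_pressure: float = 47.0    # mmHg
    respiratory_quotient: float = 0.8
    baseline_shunt: float = 0.03
    shunt_per_closed_fraction: float = 0.8
    co2_production: float = 5.1           # mL/min/kg
    dead_space: float = 2.2               # mL/kg
    venous_po2: float = 40.0              # mmHg (fixed mixed-venous side)
    p50: float = P50_DEFAULT
    hill_n: float = HILL_N_DEFAULT

    def __post_init__(self) -> None:
        positive = (self.hb, self.barometric_pressure, self.water_vapor_pressure,
                    self.co2_production, self.dead_space, self.venous_po2,
                    self.p50, self.hill_n)
        if any(v <= 0 for v in positive):
            raise ValueError("all physical parameters must be positive")
        if not 0.0 <= self.baseline_shunt < 1.0:
            raise ValueError("baseline_shunt must lie in [0, 1)")
        if not 0.5 < self.respiratory_quotient <= 1.5:
            raise ValueError("respiratory_quotient must lie in (0.5, 1.5]")
        if self.shunt_per_closed_fraction < 0:
            raise ValueError("shunt_per_closed_fraction must be non-negative")


# ---------------------------------------------------------------------------
# spontaneous breathing
# ---------------------------------------------------------------------------

def _ar1_lognormal(n: int, mean: float, cv: float, phi: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) lognormal series with exact target mean and CV."""
    if cv == 0.0:
        return np.full(n, mean)
    sigma = np.sqrt(np.log1p(cv * cv))
    mu = np.log(mean) - 0.5 * sigma * sigma
    z = np.empty(n)
    z[0] = rng.standard_normal()
    eps = rng.standard_normal(n - 1) * np.sqrt(1.0 - phi * phi) if n > 1 else []
    for i in range(1, n):
        z[i] = phi * z[i - 1] + eps[i - 1]
    return np.exp(mu + sigma * z)


def generate_spontaneous_breathing(
        params: BreathingSimParams, duration_s: float = 600.0,
) -> tuple[PlethysmographRecording, pd.DataFrame]:
    """Synthesize a plethysmograph recording of spontaneous breathing.

    Breath amplitudes (proportional to VT, in mL/kg units) and periods are
    drawn from autocorrelated lognormal processes with the requested means
    and CVs.  Each breath contributes a raised-cosine pressure bump.
    Movement artifacts (high-frequency, high-amplitude bursts) are injected
    at random positions and annotated in the recording.

    Returns the recording and a ground-truth per-breath table with columns
    ``onset_s``, ``amplitude``, ``period_s``.
    """
    mean_period = 60.0 / params.mean_rr
    if duration_s < 2.0 * mean_period:
        raise ValueError("duration must cover at least 2 breaths")
    rng = np.random.default_rng(params.seed)
    n_max = int(np.ceil(duration_s / mean_period * (1.5 + 3 * params.cv_rr))) + 4
    amps = _ar1_lognormal(n_max, params.mean_vt, params.cv_vt,
                          params.ar1_coeff, rng)
    pers = _ar1_lognormal(n_max, mean_period, params.cv_rr,
                          params.ar1_coeff, rng)

    fs = params.sampling_rate
    n_samp = int(round(duration_s * fs))
    signal = np.zeros(n_samp)
    rows = []
    t = 0.0
    for a, p in zip(amps, pers):
        if t + p > duration_s:
            break
        i0, i1 = int(round(t * fs)), int(round((t + p) * fs))
        tau = np.arange(i1 - i0) / max(i1 - i0, 1)
        signal[i0:i1] += 0.5 * a * (1.0 - np.cos(2.0 * np.pi * tau))
        rows.append((t, a, p))
        t += p
    if len(rows) < 2:
        raise ValueError("duration must cover at least 2 breaths")
    truth = pd.DataFrame(rows, columns=["onset_s", "amplitude", "period_s"])

    # movement artifacts: high-amplitude 8 Hz bursts, uniformly placed
    n_art = rng.poisson(params.artifact_rate * duration_s / 60.0)
    intervals: list[tuple[float, float]] = []
    burst_amp = 6.0 * params.mean_vt
    for _ in range(n_art):
        if params.artifact_duration <= 0:
            break
        a0 = rng.uniform(0.0, max(duration_s - params.artifact_duration, 0.0))
        a1 = a0 + params.artifact_duration
        i0, i1 = int(round(a0 * fs)), int(round(a1 * fs))
        tt = np.arange(i1 - i0) / fs
        env = np.sin(np.pi * np.linspace(0, 1, i1 - i0)) ** 2
        signal[i0:i1] += burst_amp * env * np.sin(2 * np.pi * 8.0 * tt)
        intervals.append((a0, a1))
    signal += 0.01 * params.mean_vt * rng.standard_normal(n_samp)

    rec = PlethysmographRecording(signal, fs, artifact_intervals=intervals)
    return rec, truth


# ---------------------------------------------------------------------------
# derecruitment dynamics
# ---------------------------------------------------------------------------

def evolve_lung_state(state: LungModelState, breath_vt: float,
                      dt_min: float) -> LungModelState:
    """Advance the recruitment state across one breath.

    The open fraction decays as ``exp(-close_rate * dt_min)``; if the breath
    exceeded ``reopen_threshold`` mL/kg, ``reopen_gain`` of the closed units
    reopen.  The result is clipped to (0, 1].
    """
    if breath_vt < 0:
        raise ValueError("breath_vt must be non-negative")
    if dt_min < 0:
        raise ValueError("dt_min must be non-negative")
    open_frac = state.open_fraction * np.exp(-state.close_rate * dt_min)
    if breath_vt > state.reopen_threshold:
        open_frac += state.reopen_gain * (1.0 - open_frac)
    open_frac = min(open_frac, 1.0)
    return dataclasses.replace(state, open_fraction=open_frac)


# ---------------------------------------------------------------------------
# blood gases
# ---------------------------------------------------------------------------

def generate_blood_gas(lung: LungModelState, vt_ml_kg: float, rr: float,
                       fio2: float, params: GasExchangeSimParams,
                       ) -> tuple[BloodGasSample, dict]:
    """Forward blood-gas model for the current lung state and ventilation.

    PaCO2 follows the alveolar clearance law; shunt mixes end-capillary and
    venous oxygen content; arterial PO2 is recovered by inverting the shared
    content-vs-tension curve, so the downstream shunt estimator reproduces
    the shunt used here.

    Returns the arterial sample and a ground-truth dict with the generating
    shunt and intermediate contents.
    """
    va = (vt_ml_kg - params.dead_space) * rr / 1000.0  # L/min/kg
    if va <= 0:
        raise ValueError("achieved alveolar ventilation must be positive "
                         f"(vt={vt_ml_kg} mL/kg, dead space={params.dead_space})")
    paco2 = 0.863 * params.co2_production / va

    shunt = params.baseline_shunt + \
        params.shunt_per_closed_fraction * (1.0 - lung.open_fraction)
    if shunt >= 1.0:
        raise ValueError("forward model produced a total (>=1) shunt")

    pao2_alv = fio2 * (params.barometric_pressure - params.water_vapor_pressure) \
        - paco2 / params.respiratory_quotient
    if pao2_alv <= 0:
        raise ValueError("alveolar PO2 non-positive under these settings")

    sat = lambda p: float(o2_saturation(p, params.p50, params.hill_n))
    cc = oxygen_content(pao2_alv, sat(pao2_alv), params.hb)
    cv = oxygen_content(params.venous_po2, sat(params.venous_po2), params.hb)
    ca = (1.0 - shunt) * cc + shunt * cv
    if ca < 0 or cv < 0 or cc < 0:
        raise ValueError("non-physical negative oxygen content")
    pao2 = po2_from_content(ca, params.hb, p50=params.p50, n=params.hill_n)

    sample = BloodGasSample(pao2=pao2, paco2=paco2, sao2=sat(pao2),
                            hb=params.hb, fio2=fio2,
                            pvo2=params.venous_po2,
                            svo2=sat(params.venous_po2), site="arterial")
    truth = {"shunt": shunt, "cc_o2": cc, "ca_o2": ca, "cv_o2": cv,
             "alveolar_po2": pao2_alv, "paco2": paco2}
    return sample, truth


# ---------------------------------------------------------------------------
# fluoroscopy-like frames
# ---------------------------------------------------------------------------

def _lung_region_mask(shape: tuple[int, int]) -> np.ndarray:
    """Two-ellipse, vaguely thoracic region of interest."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = h * 0.52, w * 0.5
    ry, rx = h * 0.36, w * 0.17
    left = (((yy - cy) / ry) ** 2 + ((xx - (cx - w * 0.20)) / rx) ** 2) <= 1.0
    right = (((yy - cy) / ry) ** 2 + ((xx - (cx + w * 0.20)) / rx) ** 2) <= 1.0
    return left | right


def generate_fluoro_frame(aerated_fraction: float,
                          size: tuple[int, int] = (256, 256),
                          seed: int = 0,
                          noise_sigma: float = 6.0) -> tuple[np.ndarray, dict]:
    """Fluoroscopy-like 8-bit frame with a known aerated pixel count.

    Inside a lung-shaped region, exactly ``round(aerated_fraction * area)``
    pixels are rendered radiolucent (dark, aerated); the rest are tissue-dense.
    Aerated pixels are selected from a smooth random field biased toward the
    non-dependent (upper) region, so aeration loss looks spatially coherent.
    Speckle noise is added without bridging the two intensity modes.

    Returns the image and a ground-truth dict with ``aerated_pixels``,
    ``region_pixels`` and the region mask.
    """
    if not 0.0 <= aerated_fraction <= 1.0:
        raise ValueError("aerated_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    region = _lung_region_mask(size)
    n_region = int(region.sum())
    k = int(round(aerated_fraction * n_region))

    # spatial preference field: smooth noise + gravity gradient
    fld = ndimage.gaussian_filter(rng.standard_normal(size), sigma=8.0)
    fld = fld + 2.0 * (np.mgrid[0:size[0], 0:size[1]][0] / size[0])
    order = np.argsort(fld[region], kind="stable")
    aerated_flat = np.zeros(n_region, dtype=bool)
    aerated_flat[order[:k]] = True
    aerated = np.zeros(size, dtype=bool)
    aerated[region] = aerated_flat

    img = np.full(size, 228.0)
    img[region] = 172.0
    img[aerated] = 58.0
    img += noise_sigma * rng.standard_normal(size)
    img = np.clip(img, 0, 255).round().astype(np.uint8)

    truth = {"aerated_pixels": k, "region_pixels": n_region,
             "lung_mask": region, "aerated_mask": aerated}
    return img, truth


# ---------------------------------------------------------------------------
# histology-like airspace phantoms
# ---------------------------------------------------------------------------

def generate_airspace_image(chord_length_um: float, pixel_size_um: float,
                            pattern: str = "stripes", seed: int = 0,
                            shape: tuple[int, int] = (512, 512),
                            ) -> tuple[np.ndarray, np.ndarray, dict]:
    """Binary airspace phantom with a known mean linear intercept.

    ``stripes``: alternating vertical air/tissue bands; the air-band width is
    ``chord_length_um`` (rounded to whole pixels), so horizontal test lines
    see chords of exactly that length.  ``circles``: non-overlapping air
    discs of diameter ``(4/pi) * chord_length_um`` — the mean chord of a disc
    across parallel lines is (pi/4) of its diameter, so the expected MLI is
    again ``chord_length_um``.

    Returns ``(air_mask, exclusion_mask, truth)``; the exclusion mask is
    empty (no vessels/airways are simulated) and ``truth`` carries the
    expected MLI implied by the rendered geometry.
    """
    if chord_length_um < 2.0 * pixel_size_um:
        raise ValueError("chord length below twice the pixel size is not resolvable")
    air = np.zeros(shape, dtype=bool)
    rng = np.random.default_rng(seed)

    if pattern == "stripes":
        w_air = int(round(chord_length_um / pixel_size_um))
        w_tis = max(2, w_air // 2)
        period = w_air + w_tis
        cols = np.arange(shape[1])
        air[:, (cols % period) < w_air] = True
        expected = w_air * pixel_size_um
        extra = {"air_band_px": w_air, "tissue_band_px": w_tis}
    elif pattern == "circles":
        diam_um = 4.0 / np.pi * chord_length_um
        r_px = max(1, int(round(diam_um / pixel_size_um / 2.0)))
        pitch = int(np.ceil(2.6 * r_px))
        yy, xx = np.mgrid[-r_px:r_px + 1, -r_px:r_px + 1]
        disc = (yy * yy + xx * xx) <= r_px * r_px
        jit = max(0, (pitch - 2 * r_px) // 2 - 1)
        margin = r_px + jit + 1
        for cy in range(margin, shape[0] - margin, pitch):
            for cx in range(margin, shape[1] - margin, pitch):
                dy, dx = (rng.integers(-jit, jit + 1), rng.integers(-jit, jit + 1)) \
                    if jit > 0 else (0, 0)
                air[cy + dy - r_px:cy + dy + r_px + 1,
                    cx + dx - r_px:cx + dx + r_px + 1] |= disc
        # mean chord of a disc of radius r across parallel lines = (pi/2) r
        expected = (np.pi / 2.0) * r_px * pixel_size_um
        extra = {"disc_radius_px": r_px, "disc_diameter_um": 2 * r_px * pixel_size_um}
    else:
        raise ValueError(f"unknown pattern {pattern!r}")

    exclusion = np.zeros(shape, dtype=bool)
    truth = {"expected_mli_um": expected, "pixel_size_um": pixel_size_um, **extra}
    return air, exclusion, truth
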