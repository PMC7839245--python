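"""Derivation of the variable-ventilation driving pattern from spontaneous breathing.

The physiologically variable ventilation (PVV) mode replays the breath-by-breath
variability of spontaneous breathing recorded by whole-body plethysmography.
This module turns such a recording into the driving schedule: breath detection
on the band-passed pressure signal, exclusion of movement-artifact segments,
ratio-preserving normalization into a :class:`VentilationPattern` (unit-mean
pressure and period ratios), rescaling of that pattern to arbitrary mean tidal
volume and respiratory rate, looped playback, and the summary statistics
(mean / CV / min / max of tidal volume and rate) used to characterize a pattern.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "PlethysmographRecording",
    "BreathRecord",
    "VentilationPattern",
    "BreathSchedule",
    "detect_breaths",
    "find_artifact_intervals",
    "remove_artifact_segments",
    "build_pvv_pattern",
    "rescale_pattern",
    "loop_schedule",
    "pattern_statistics",
]


class BreathDetectionError(RuntimeError):
    """No breaths could be segmented from a recording."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class PlethysmographRecording:
    """A sampled pressure-like trace from whole-body plethysmography.

    ``samples`` are in arbitrary pressure units proportional to tidal volume
    (the box calibration is absorbed into the unit).  ``artifact_intervals``
    are ``(start_s, end_s)`` windows flagged as movement artifacts.
    ``segment_edges`` lists times (s) at which the trace is discontinuous
    because an artifact segment was excised; breath periods are never computed
    across such an edge.
    """

    samples: np.ndarray
    sampling_rate: float
    artifact_intervals: list[tuple[float, float]] = field(default_factory=list)
    segment_edges: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        dur = self.duration
        ivals = sorted((float(a), float(b)) for a, b in self.artifact_intervals)
        for a, b in ivals:
            if not (0.0 <= a < b <= dur + 1.0 / self.sampling_rate):
                raise ValueError(f"artifact interval ({a}, {b}) outside record")
        # merge overlaps so downstream bookkeeping sees disjoint windows
        merged: list[tuple[float, float]] = []
        for a, b in ivals:
            if merged and a <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], b))
            else:
                merged.append((a, b))
        self.artifact_intervals = merged

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_rate

    @property
    def time(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sampling_rate


@dataclass(frozen=True)
class BreathRecord:
    """One detected breath: peak-to-trough amplitude, cycle period, timing."""

    index: int
    amplitude: float
    period: float
    inspiratory_time: float
    onset: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if self.period <= 0:
            raise ValueError("period must be positive")
        if not 0 <= self.inspiratory_time < self.period:
            raise ValueError("inspiratory_time must lie within the period")


@dataclass
class VentilationPattern:
    """Normalized driving schedule: unit-mean pressure and period ratios."""

    pressure_ratios: np.ndarray
    period_ratios: np.ndarray
    source_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pressure_ratios = np.asarray(self.pressure_ratios, dtype=float)
        self.period_ratios = np.asarray(self.period_ratios, dtype=float)
        if self.pressure_ratios.shape != self.period_ratios.shape:
            raise ValueError("ratio arrays must have equal length")
        if self.n_breaths < 1:
            raise ValueError("pattern needs at least one breath")
        if np.any(self.pressure_ratios <= 0) or np.any(self.period_ratios <= 0):
            raise ValueError("all ratios must be positive")
        for name, r in (("pressure", self.pressure_ratios),
                        ("period", self.period_ratios)):
            if abs(r.mean() - 1.0) > 1e-9:
                raise ValueError(f"mean {name} ratio deviates from 1 by more "
                                 f"than 1e-9 ({r.mean():.3e})")

    @property
    def n_breaths(self) -> int:
        return len(self.pressure_ratios)


@dataclass
class BreathSchedule:
    """A concrete per-breath delivery plan in physical units."""

    vt: np.ndarray          # mL/kg per breath
    period: np.ndarray      # s per breath

    def __post_init__(self) -> None:
        self.vt = np.asarray(self.vt, dtype=float)
        self.period = np.asarray(self.period, dtype=float)
        if self.vt.shape != self.period.shape:
            raise ValueError("vt and period must have equal length")

    @property
    def rr(self) -> np.ndarray:
        """Instantaneous respiratory rate, breaths/min."""
        return 60.0 / self.period

    @property
    def n_breaths(self) -> int:
        return len(self.vt)


# ---------------------------------------------------------------------------
# breath detection
# ---------------------------------------------------------------------------

def _bandpass(x: np.ndarray, fs: float, band: tuple[float, float]) -> np.ndarray:
    lo, hi = band
    nyq = fs / 2.0
    hi = min(hi, 0.95 * nyq)
    sos = sps.butter(2, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
    # generous padding keeps the low-frequency edge transient away from the
    # first and last breath cycles
    padlen = min(len(x) - 1, int(3.0 * fs / lo))
    return sps.sosfiltfilt(sos, x, padlen=padlen)


def _overlaps(t0: float, t1: float, intervals: Sequence[tuple[float, float]]) -> bool:
    return any(t0 < b and t1 > a for a, b in intervals)


def _detect_in_segment(x: np.ndarray, fs: float, t_offset: float,
                       band: tuple[float, float],
                       min_amplitude_frac: float) -> list[tuple[float, float, float, float]]:
    """Return (onset, amplitude, period, t_insp) tuples for one contiguous segment."""
    if len(x) < int(2.0 * fs / band[1]):
        return []
    xf = _bandpass(x, fs, band)

    # cycle boundaries: upward zero crossings of the band-passed signal
    neg = xf < 0
    up = np.flatnonzero(neg[:-1] & ~neg[1:]) + 1
    if len(up) < 1:
        return []
    # sub-sample refinement of each crossing by linear interpolation
    frac = xf[up - 1] / (xf[up - 1] - xf[up])
    times = (up - 1) + frac
    bounds = list(up)
    btimes = list(times)
    spans = np.diff(up)
    med_span = np.median(spans) if len(spans) else len(x)
    # a leading/trailing span long enough to hold a full cycle is kept
    if up[0] >= 0.6 * med_span:
        bounds.insert(0, 0)
        btimes.insert(0, 0.0)
    if len(x) - up[-1] >= 0.6 * med_span:
        bounds.append(len(x))
        btimes.append(float(len(x) - 1))

    cycles = []
    for (i0, i1), (s0, s1) in zip(zip(bounds[:-1], bounds[1:]),
                                  zip(btimes[:-1], btimes[1:])):
        seg = xf[i0:i1]
        if len(seg) < 3:
            continue
        amp_f = float(seg.max() - seg.min())
        # amplitude reported from the raw trace: the band-passed copy is only
        # used for segmentation (filter transients would bias edge cycles)
        raw_seg = x[i0:i1]
        amp = float(raw_seg.max() - raw_seg.min())
        ipk = int(np.argmax(seg))
        cycles.append((s0, s1, amp_f, amp, ipk))
    if not cycles:
        return []

    med_amp = float(np.median([c[2] for c in cycles]))
    out = []
    for s0, s1, amp_f, amp, ipk in cycles:
        if amp_f < min_amplitude_frac * med_amp:
            continue  # noise crossing, not a breath
        onset = t_offset + s0 / fs
        period = (s1 - s0) / fs
        t_insp = ipk / fs
        out.append((onset, amp, period, t_insp))
    return out


def detect_breaths(recording: PlethysmographRecording,
                   band: tuple[float, float] = (0.1, 3.0),
                   min_amplitude_frac: float = 0.25) -> list[BreathRecord]:
    """Segment a plethysmograph trace into breaths.

    The signal is band-passed (default 0.1–3 Hz), cycles are delimited by
    upward zero crossings, and cycles whose peak-to-trough excursion falls
    below ``min_amplitude_frac`` of the median excursion are rejected as noise.
    Breaths overlapping an annotated artifact interval or an excision edge are
    excluded.

    Raises
    ------
    BreathDetectionError
        If no breath survives segmentation and exclusion.
    """
    fs = recording.sampling_rate
    x = recording.samples
    if len(x) < int(2 * fs / band[1]):
        raise BreathDetectionError("recording shorter than two plausible breaths")

    # split at excision edges so no cycle spans a discontinuity
    edges = sorted(set([0.0] + list(recording.segment_edges) + [recording.duration]))
    raw: list[tuple[float, float, float, float]] = []
    for t0, t1 in zip(edges[:-1], edges[1:]):
        i0, i1 = int(round(t0 * fs)), int(round(t1 * fs))
        raw.extend(_detect_in_segment(x[i0:i1], fs, t0, band, min_amplitude_frac))

    breaths: list[BreathRecord] = []
    for onset, amp, period, t_insp in raw:
        if _overlaps(onset, onset + period, recording.artifact_intervals):
            continue
        breaths.append(BreathRecord(index=len(breaths), amplitude=amp,
                                    period=period, inspiratory_time=t_insp,
                                    onset=onset))
    if not breaths:
        raise BreathDetectionError(
            f"no breaths detected ({len(raw)} candidate cycles, "
            f"{len(recording.artifact_intervals)} artifact intervals)")
    return breaths


# ---------------------------------------------------------------------------
# artifact handling
# ---------------------------------------------------------------------------

def find_artifact_intervals(recording: PlethysmographRecording,
                            window_s: float = 0.25,
                            outlier_factor: float = 3.0,
                            pad_s: float = 0.3) -> list[tuple[float, float]]:
    """Flag movement artifacts as amplitude outliers.

    A moving RMS (window ``window_s``) of the zero-meaned signal is compared
    with its median; samples above ``outlier_factor`` times the median RMS are
    flagged and the flagged runs padded by ``pad_s`` on each side.
    """
    fs = recording.sampling_rate
    x = recording.samples - np.mean(recording.samples)
    n = max(3, int(window_s * fs))
    kernel = np.ones(n) / n
    rms = np.sqrt(np.convolve(x * x, kernel, mode="same"))
    thresh = outlier_factor * np.median(rms)
    hot = rms > thresh
    if not hot.any():
        return []
    idx = np.flatnonzero(hot)
    gaps = np.flatnonzero(np.diff(idx) > 1)
    starts = np.r_[idx[0], idx[gaps + 1]]
    ends = np.r_[idx[gaps], idx[-1]]
    out = []
    for s, e in zip(starts, ends):
        a = max(0.0, s / fs - pad_s)
        b = min(recording.duration, (e + 1) / fs + pad_s)
        if out and a <= out[-1][1]:
            out[-1] = (out[-1][0], b)
        else:
            out.append((a, b))
    return out


def remove_artifact_segments(recording: PlethysmographRecording,
                             detect: bool = False,
                             **detector_kwargs) -> PlethysmographRecording:
    """Excise artifact segments, keeping a contiguity map.

    Uses annotated ``artifact_intervals`` by default; with ``detect=True``
    the amplitude-outlier rule of :func:`find_artifact_intervals` is applied
    first and merged with any annotation.  The returned recording has the
    flagged samples removed, no remaining artifact intervals, and
    ``segment_edges`` marking each excision point (in the new time base) so
    that breath periods are never computed across a cut.
    """
    intervals = list(recording.artifact_intervals)
    if detect:
        intervals += find_artifact_intervals(recording, **detector_kwargs)
    if not intervals:
        return PlethysmographRecording(recording.samples.copy(),
                                       recording.sampling_rate,
                                       segment_edges=list(recording.segment_edges))
    # merge
    intervals.sort()
    merged = [intervals[0]]
    for a, b in intervals[1:]:
        if a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))

    fs = recording.sampling_rate
    n = len(recording.samples)
    keep_chunks = []
    edges = []
    pos = 0
    kept = 0
    for a, b in merged:
        ia, ib = int(round(a * fs)), min(n, int(round(b * fs)))
        if ia > pos:
            keep_chunks.append(recording.samples[pos:ia])
            kept += ia - pos
        if ia >= pos:
            edges.append(kept / fs)
        pos = max(pos, ib)
    if pos < n:
        keep_chunks.append(recording.samples[pos:n])
    if not keep_chunks:
        return PlethysmographRecording(np.empty(0), fs)
    samples = np.concatenate(keep_chunks)
    edges = [e for e in edges if 0.0 < e < len(samples) / fs]
    return PlethysmographRecording(samples, fs, segment_edges=sorted(set(edges)))


# ---------------------------------------------------------------------------
# pattern algebra
# ---------------------------------------------------------------------------

def build_pvv_pattern(breaths: Sequence[BreathRecord], n_breaths: int = 382,
                      source_meta: dict | None = None) -> VentilationPattern:
    """Normalize detected breaths into the looping PVV driving pattern.

    The first ``n_breaths`` breaths (temporal order preserved) are converted
    to ratios against their own means; both ratio series are renormalized so
    their means are exactly 1.
    """
    if len(breaths) < n_breaths:
        raise ValueError(f"need {n_breaths} breaths, have only {len(breaths)} "
                         f"(short by {n_breaths - len(breaths)})")
    amps = np.array([b.amplitude for b in breaths[:n_breaths]], dtype=float)
    pers = np.array([b.period for b in breaths[:n_breaths]], dtype=float)
    pr = amps / amps.mean()
    pr /= pr.mean()
    tr = pers / pers.mean()
    tr /= tr.mean()
    meta = dict(source_meta or {})
    meta.setdefault("n_breaths", int(n_breaths))
    return VentilationPattern(pr, tr, source_meta=meta)


def pattern_from_series(amplitudes: np.ndarray, periods: np.ndarray,
                        source_meta: dict | None = None) -> VentilationPattern:
    """Build a pattern directly from amplitude and period series."""
    amplitudes = np.asarray(amplitudes, dtype=float)
    periods = np.asarray(periods, dtype=float)
    breaths = [BreathRecord(i, a, p, p / 4.0)
               for i, (a, p) in enumerate(zip(amplitudes, periods))]
    return build_pvv_pattern(breaths, n_breaths=len(breaths),
                             source_meta=source_meta)


def rescale_pattern(pattern: VentilationPattern, target_mean_rr: float,
                    target_mean_vt: float) -> BreathSchedule:
    """Rescale the unit-mean pattern to physical targets.

    Because the ratios have unit mean, the schedule's mean VT and mean period
    equal the targets and every dimensionless shape statistic (CV, min/mean,
    max/mean, successive ratios) is preserved exactly.
    """
    if target_mean_rr <= 0 or target_mean_vt <= 0:
        raise ValueError("targets must be positive")
    vt = target_mean_vt * pattern.pressure_ratios
    period = (60.0 / target_mean_rr) * pattern.period_ratios
    return BreathSchedule(vt=vt, period=period)


def loop_schedule(schedule: BreathSchedule, n_loops: int) -> BreathSchedule:
    """Replay a schedule in a loop, as done for the 382-breath pattern file."""
    if n_loops < 1:
        raise ValueError("n_loops must be >= 1")
    return BreathSchedule(np.tile(schedule.vt, n_loops),
                          np.tile(schedule.period, n_loops))


def pattern_statistics(vt: np.ndarray, period: np.ndarray) -> pd.DataFrame:
    """Mean, CV (%), min and max of tidal volume and instantaneous rate.

    CV is the sample standard deviation (ddof=1) over the mean, in percent;
    instantaneous rate for breath i is 60/period_i.
    """
    vt = np.asarray(vt, dtype=float)
    period = np.asarray(period, dtype=float)
    if len(vt) < 2 or len(period) < 2:
        raise ValueError("need at least 2 breaths (CV undefined otherwise)")
    rr = 60.0 / period

    def stats(x):
        return {"mean": x.mean(),
                "cv_pct": 100.0 * x.std(ddof=1) / x.mean(),
                "min": x.min(), "max": x.max()}

    return pd.DataFrame({"vt": stats(vt), "rr": stats(rr)})
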