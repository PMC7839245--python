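"""File formats: delimiter-separated tables with JSON sidecars.

Recordings are written as two-column time/value TSV plus a sidecar carrying
sampling rate, units and artifact intervals.  Pattern files hold three columns
(breath_index, pressure_ratio, period_ratio) with full float precision and a
checksum in the sidecar, so a write/read round-trip is bit-exact.  Impedance
spectra are four-column tables; fitted mechanics and ground truth go to JSON.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .breath_pattern import PlethysmographRecording, VentilationPattern
from .fot_mechanics import ImpedanceSpectrum, MechanicsParams

__all__ = [
    "write_recording", "read_recording",
    "write_pattern", "read_pattern",
    "write_impedance", "read_impedance",
    "write_mechanics", "load_run_config",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_recording(path, recording: PlethysmographRecording,
                    units: str = "a.u.") -> None:
    path = Path(path)
    df = pd.DataFrame({"time_s": recording.time, "value": recording.samples})
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    meta = {"sampling_rate_hz": recording.sampling_rate, "units": units,
            "artifact_intervals_s": [list(iv) for iv in recording.artifact_intervals],
            "segment_edges_s": list(recording.segment_edges)}
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_recording(path) -> PlethysmographRecording:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta = json.loads(_sidecar(path).read_text())
    return PlethysmographRecording(
        df["value"].to_numpy(), meta["sampling_rate_hz"],
        artifact_intervals=[tuple(iv) for iv in meta["artifact_intervals_s"]],
        segment_edges=list(meta.get("segment_edges_s", [])))


def write_pattern(path, pattern: VentilationPattern) -> None:
    path = Path(path)
    lines = ["breath_index\tpressure_ratio\tperiod_ratio"]
    for i, (pr, tr) in enumerate(zip(pattern.pressure_ratios,
                                     pattern.period_ratios)):
        lines.append(f"{i}\t{float(pr)!r}\t{float(tr)!r}")  # repr: bit-exact
    body = "\n".join(lines) + "\n"
    path.write_text(body)
    meta = {"n_breaths": pattern.n_breaths,
            "source_meta": pattern.source_meta,
            "sha256": hashlib.sha256(body.encode()).hexdigest()}
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_pattern(path, verify_checksum: bool = True) -> VentilationPattern:
    path = Path(path)
    body = path.read_text()
    meta = json.loads(_sidecar(path).read_text())
    if verify_checksum and \
            hashlib.sha256(body.encode()).hexdigest() != meta["sha256"]:
        raise ValueError(f"pattern file {path} fails its checksum")
    rows = [ln.split("\t") for ln in body.strip().splitlines()[1:]]
    pr = np.array([float(r[1]) for r in rows])
    tr = np.array([float(r[2]) for r in rows])
    return VentilationPattern(pr, tr, source_meta=meta.get("source_meta", {}))


def write_impedance(path, spectrum: ImpedanceSpectrum,
                    meta: dict | None = None) -> None:
    path = Path(path)
    df = pd.DataFrame({"frequency_hz": spectrum.frequencies,
                       "z_real": spectrum.z_real, "z_imag": spectrum.z_imag,
                       "coherence": spectrum.coherence})
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")
    sidecar = {"units": "cmH2O.s/L", **(meta or {})}
    _sidecar(path).write_text(json.dumps(sidecar, indent=1))


def read_impedance(path) -> ImpedanceSpectrum:
    df = pd.read_csv(Path(path), sep="\t")
    return ImpedanceSpectrum(df["frequency_hz"].to_numpy(),
                             df["z_real"].to_numpy(), df["z_imag"].to_numpy(),
                             df["coherence"].to_numpy())


def write_mechanics(path, params: MechanicsParams) -> None:
    Path(path).write_text(json.dumps(
        {"raw": params.raw, "iaw": params.iaw, "g": params.g, "h": params.h,
         "alpha": params.alpha, "fit_residual": params.fit_residual,
         "boundary_flag": params.boundary_flag}, indent=1))


def load_run_config(path) -> dict:
    """Run configuration (YAML or JSON) for the simulation drivers."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)
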