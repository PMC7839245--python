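#!/usr/bin/env python
"""Forced-oscillation measurement of the synthetic lung's mechanics.

Simulates the full measurement chain at two lung states (freshly recruited
and derecruited to 80% open): the 2 cmH2O peak-to-peak 15-component forcing
is applied for 10 s, flow is synthesized through the true constant-phase
impedance in series with a breathing-circuit tube, 5% instrument noise is
added, three epochs are averaged, the circuit impedance is subtracted, and
the airway + tissue model is fitted by multi-start least squares.  Writes
true-versus-recovered parameters under results/fot/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from varvent.fot_mechanics import (ForcingDesign, ImpedanceSpectrum,
                                   average_epochs, cp_impedance,
                                   design_forcing_signal, estimate_impedance,
                                   fit_constant_phase,
                                   subtract_circuit_impedance)
from varvent.io import write_impedance
from varvent.synthetic_data import LungModelState

OUT = Path(__file__).resolve().parent.parent / "results" / "fot"
OUT.mkdir(parents=True, exist_ok=True)

FS = 1000.0
NOISE = 0.05
CIRCUIT_R, CIRCUIT_I = 4.0, 0.003   # rigid tube: small resistance + inertance

design = ForcingDesign()
_, forcing, _ = design_forcing_signal(design, FS, seed=3)
f_grid = np.fft.rfftfreq(len(forcing), 1.0 / FS)
rng = np.random.default_rng(42)

rows = []
for label, open_fraction in (("recruited", 1.0), ("derecruited", 0.8)):
    lung = LungModelState(open_fraction=open_fraction)
    h_eff = lung.h_tissue / open_fraction
    g_eff = lung.g_tissue / open_fraction

    def z_total(f):
        z_lung = cp_impedance(lung.raw, lung.iaw, g_eff, h_eff,
                              np.maximum(f, 1e-9))
        return z_lung + CIRCUIT_R + 1j * 2 * np.pi * f * CIRCUIT_I

    flow = np.fft.irfft(np.fft.rfft(forcing) / z_total(f_grid),
                        n=len(forcing))
    epochs = []
    for _ in range(3):
        p_meas = forcing + NOISE * forcing.std() * rng.standard_normal(len(forcing))
        f_meas = flow + NOISE * flow.std() * rng.standard_normal(len(flow))
        epochs.append(estimate_impedance(p_meas, f_meas, FS, design))
    z_meas = average_epochs(epochs)
    z_circ = ImpedanceSpectrum(
        design.frequencies,
        np.full(15, CIRCUIT_R),
        2 * np.pi * design.frequencies * CIRCUIT_I)
    z_rs = subtract_circuit_impedance(z_meas, z_circ)
    write_impedance(OUT / f"zrs_{label}.tsv", z_rs,
                    meta={"epochs": 3, "state": label})

    fit = fit_constant_phase(z_rs, n_starts=20, seed=9)
    for name, true in (("raw", lung.raw), ("iaw", lung.iaw),
                       ("g", g_eff), ("h", h_eff)):
        rows.append({"state": label, "parameter": name, "true": true,
                     "fitted": getattr(fit, name),
                     "rel_err_pct": 100 * abs(getattr(fit, name) - true) / true})
    rows.append({"state": label, "parameter": "alpha",
                 "true": (2 / np.pi) * np.arctan(h_eff / g_eff),
                 "fitted": fit.alpha, "rel_err_pct": np.nan})

table = pd.DataFrame(rows)
table.to_csv(OUT / "mechanics_recovery.tsv", sep="\t", index=False,
             float_format="%.4f")
print(table.round(4).to_string(index=False))
print("\nDerecruitment to 80% open raises tissue damping and elastance by "
      "the same 1/open factor (constant hysteresivity); the fit recovers "
      "both states from noisy three-epoch measurements.")
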