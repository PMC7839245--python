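#!/usr/bin/env python
"""Shunt-fraction round trip and oxygenation indices.

Feeds the forward blood-gas model a grid of generating shunt fractions,
then recovers each with the three-content Berggren estimator
(Qs/Qt = (Cc - Ca)/(Cc - Cv)) from the produced arterial sample alone;
tabulates PaO2, PaO2/FiO2 and the recovered shunt under results/.
"""

from pathlib import Path

import pandas as pd

from varvent.gas_exchange import oxygenation_index, shunt_from_sample
from varvent.synthetic_data import (GasExchangeSimParams, LungModelState,
                                    generate_blood_gas)

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(parents=True, exist_ok=True)

rows = []
for shunt in (0.0, 0.05, 0.10, 0.17, 0.30):
    params = GasExchangeSimParams(baseline_shunt=shunt)
    sample, truth = generate_blood_gas(LungModelState(), vt_ml_kg=7.0,
                                       rr=24.0, fio2=0.4, params=params)
    rows.append({
        "shunt_true": shunt,
        "shunt_recovered": shunt_from_sample(sample, params),
        "pao2_mmhg": sample.pao2,
        "paco2_mmhg": sample.paco2,
        "pao2_fio2_mmhg": oxygenation_index(sample.pao2, sample.fio2),
    })

table = pd.DataFrame(rows)
table.to_csv(OUT / "gas_exchange_round_trip.tsv", sep="\t", index=False,
             float_format="%.4f")
print(table.round(3).to_string(index=False))
worst = (table.shunt_recovered - table.shunt_true).abs().max()
print(f"\nWorst absolute round-trip error: {worst:.2e} — the estimator "
      "inverts the forward model through the shared dissociation curve, so "
      "venous admixture maps one-to-one onto the oxygenation index.")
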