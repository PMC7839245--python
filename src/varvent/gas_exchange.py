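"""Oxygenation index, oxygen contents and intrapulmonary shunt fraction.

The shunt fraction is the classical three-content Berggren ratio

    Qs/Qt = (CcO2 - CaO2) / (CcO2 - CvO2)

with end-capillary content obtained from the alveolar gas equation and the
shared oxygen-dissociation curve, arterial and central-venous contents from
the measured tensions and saturations.  The oxygenation index is PaO2/FiO2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .saturation import HILL_N_DEFAULT, P50_DEFAULT, o2_saturation

__all__ = [
    "BloodGasSample",
    "OxygenContents",
    "oxygenation_index",
    "oxygen_content",
    "end_capillary_content",
    "shunt_fraction",
    "shunt_from_sample",
]

#: mL O2 bound per gram of hemoglobin and plasma solubility (mL/dL/mmHg)
HB_O2_CAPACITY = 1.34
O2_SOLUBILITY = 0.003


@dataclass(frozen=True)
class BloodGasSample:
    """A point-of-care blood gas measurement (one site, one timepoint)."""

    pao2: float            # mmHg
    paco2: float           # mmHg
    sao2: float            # fraction
    hb: float              # g/dL
    fio2: float            # fraction
    pvo2: float = float("nan")   # mmHg, central venous
    svo2: float = float("nan")   # fraction, central venous
    site: str = "arterial"

    def __post_init__(self) -> None:
        if self.pao2 <= 0 or self.paco2 <= 0:
            raise ValueError("gas tensions must be positive")
        if not 0.0 <= self.sao2 <= 1.0:
            raise ValueError("saturation must lie in [0, 1]")
        if not 0.21 < self.fio2 <= 1.0:
            raise ValueError("fio2 must lie in (0.21, 1.0]")


@dataclass(frozen=True)
class OxygenContents:
    """End-capillary, arterial and central-venous oxygen contents (mL O2/dL)."""

    cc_o2: float
    ca_o2: float
    cv_o2: float

    def __post_init__(self) -> None:
        if min(self.cc_o2, self.ca_o2, self.cv_o2) < 0:
            raise ValueError("oxygen contents must be non-negative")
        if not (self.cc_o2 >= self.ca_o2 >= self.cv_o2):
            warnings.warn("contents violate the physiologic ordering "
                          "cc >= ca >= cv; shunt may fall outside [0, 1]",
                          stacklevel=2)


def oxygenation_index(pao2: float, fio2: float) -> float:
    """PaO2/FiO2 in mmHg."""
    if fio2 <= 0:
        raise ValueError("fio2 must be positive")
    return pao2 / fio2


def oxygen_content(po2: float, so2: float, hb: float, *,
                   hb_capacity: float = HB_O2_CAPACITY,
                   solubility: float = O2_SOLUBILITY) -> float:
    """Whole-blood oxygen content, mL O2/dL: bound plus dissolved."""
    if po2 < 0 or so2 < 0 or hb < 0:
        raise ValueError("inputs must be non-negative")
    return hb_capacity * hb * so2 + solubility * po2


def end_capillary_content(fio2: float, paco2: float, hb: float, params) -> float:
    """End-capillary oxygen content via the alveolar gas equation.

    Alveolar PO2 = FiO2 * (Pb - PH2O) - PaCO2 / RQ; end-capillary blood is
    assumed equilibrated with alveolar gas, its saturation read from the
    shared dissociation curve.  ``params`` supplies the ambient constants
    (``barometric_pressure``, ``water_vapor_pressure``,
    ``respiratory_quotient``, ``p50``, ``hill_n``).
    """
    if not 0.0 < fio2 <= 1.0:
        raise ValueError("fio2 must lie in (0, 1]")
    pao2_alv = fio2 * (params.barometric_pressure - params.water_vapor_pressure) \
        - paco2 / params.respiratory_quotient
    if pao2_alv <= 0:
        raise ValueError("alveolar PO2 non-positive; check FiO2/PaCO2")
    so2 = float(o2_saturation(pao2_alv,
                              getattr(params, "p50", P50_DEFAULT),
                              getattr(params, "hill_n", HILL_N_DEFAULT)))
    return oxygen_content(pao2_alv, so2, hb)


def shunt_fraction(contents: OxygenContents) -> float:
    """Berggren shunt fraction (Cc - Ca) / (Cc - Cv), as a fraction.

    Returned unclipped: inputs violating cc >= ca >= cv produce an
    out-of-range value together with the ordering warning raised when the
    contents object was built, never a silently clipped one.
    """
    denom = contents.cc_o2 - contents.cv_o2
    if denom == 0:
        raise ValueError("shunt undefined: cc_o2 equals cv_o2")
    qs_qt = (contents.cc_o2 - contents.ca_o2) / denom
    if not 0.0 <= qs_qt <= 1.0:
        warnings.warn(f"shunt fraction {qs_qt:.3f} outside [0, 1]",
                      stacklevel=2)
    return qs_qt


def shunt_from_sample(sample: BloodGasSample, params) -> float:
    """Shunt fraction from one arterial sample with venous tensions attached.

    End-capillary content comes from the alveolar-gas route (default; the
    alternative of assuming fully saturated end-capillary blood is a one-line
    substitution of ``oxygen_content(sample.pao2, 1.0, sample.hb)``).
    """
    cc = end_capillary_content(sample.fio2, sample.paco2, sample.hb, params)
    ca = oxygen_content(sample.pao2, sample.sao2, sample.hb)
    cv = oxygen_content(sample.pvo2, sample.svo2, sample.hb)
    return shunt_fraction(OxygenContents(cc_o2=cc, ca_o2=ca, cv_o2=cv))
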