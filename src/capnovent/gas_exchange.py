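"""Oxygen-content, alveolar-gas and shunt-fraction computations.

Contents are in mL O2 per dL blood (Hb in g/dL), with the Hufner constant
1.34 mL/g and plasma solubility 0.0031 mL/dL/mmHg.  The capillary content
assumes full saturation; the shunt fraction is the oxygen-content balance
Qs/Qt = (Cc - Ca) / (Cc - Cv).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import DomainError

__all__ = [
    "BloodGasPanel",
    "OxygenContents",
    "HUFNER",
    "O2_SOLUBILITY",
    "alveolar_po2",
    "oxygen_contents",
    "shunt_fraction",
    "oxygenation_index",
    "augment_frame",
]

HUFNER = 1.34  # mL O2 per g Hb
O2_SOLUBILITY = 0.0031  # mL O2 per dL per mmHg


@dataclass(frozen=True)
class BloodGasPanel:
    pao2: float  # mmHg
    paco2: float  # mmHg
    sao2: float  # fraction
    hb_art: float  # g/dL
    pvo2: float  # mmHg
    svo2: float  # fraction
    hb_ven: float  # g/dL
    fio2: float  # fraction
    p_atmos: float = 760.0  # mmHg
    p_h2o: float = 47.0  # mmHg
    rq: float = 0.8

    def __post_init__(self):
        for name in ("sao2", "svo2", "fio2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("pao2", "paco2", "pvo2", "p_atmos", "p_h2o"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.hb_art <= 0 or self.hb_ven <= 0:
            raise ValueError("hemoglobin must be positive")
        if self.p_h2o >= self.p_atmos:
            raise ValueError("p_h2o must be below p_atmos")
        if self.rq <= 0:
            raise ValueError("rq must be positive")


@dataclass(frozen=True)
class OxygenContents:
    cc: float  # mL O2/dL
    ca: float
    cv: float
    pao2_alv: float  # mmHg

    def __post_init__(self):
        if self.cc < 0 or self.ca < 0 or self.cv < 0:
            raise ValueError("oxygen contents must be non-negative")


def alveolar_po2(panel: BloodGasPanel) -> float:
    """Alveolar PO2: FiO2*(Patmos - PH2O) - Paco2/RQ."""
    pao2_alv = panel.fio2 * (panel.p_atmos - panel.p_h2o) - panel.paco2 / panel.rq
    if pao2_alv <= 0:
        raise DomainError(
            f"alveolar PO2 {pao2_alv:.1f} mmHg <= 0: unphysiologic configuration"
        )
    return pao2_alv


def oxygen_contents(panel: BloodGasPanel) -> OxygenContents:
    pao2_alv = alveolar_po2(panel)
    ca = HUFNER * panel.hb_art * panel.sao2 + panel.pao2 * O2_SOLUBILITY
    cv = HUFNER * panel.hb_ven * panel.svo2 + panel.pvo2 * O2_SOLUBILITY
    cc = HUFNER * panel.hb_art + pao2_alv * O2_SOLUBILITY
    return OxygenContents(cc=cc, ca=ca, cv=cv, pao2_alv=pao2_alv)


def shunt_fraction(contents: OxygenContents) -> float:
    """Oxygen-content shunt balance (Cc - Ca)/(Cc - Cv)."""
    if contents.cc <= contents.cv:
        raise DomainError("capillary content must exceed venous content")
    return (contents.cc - contents.ca) / (contents.cc - contents.cv)


def oxygenation_index(pao2: float, fio2: float) -> float:
    """Pao2/FiO2 ratio in mmHg."""
    if fio2 <= 0:
        raise ValueError("fio2 must be positive")
    return pao2 / fio2


_PANEL_COLUMNS = (
    "pao2", "paco2", "sao2", "hb_art", "pvo2", "svo2", "hb_ven", "fio2",
)


def augment_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Append computed gas-exchange columns to a table of panels (one per row)."""
    missing = [c for c in _PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing panel columns: {missing}")
    out = df.copy()
    rows = []
    for rec in df.to_dict("records"):
        kwargs = {c: rec[c] for c in _PANEL_COLUMNS}
        for opt in ("p_atmos", "p_h2o", "rq"):
            if opt in rec and pd.notna(rec[opt]):
                kwargs[opt] = rec[opt]
        panel = BloodGasPanel(**kwargs)
        contents = oxygen_contents(panel)
        rows.append(
            {
                "pao2_alv": contents.pao2_alv,
                "cc_o2": contents.cc,
                "ca_o2": contents.ca,
                "cv_o2": contents.cv,
                "qs_qt": shunt_fraction(contents),
                "pao2_fio2": oxygenation_index(panel.pao2, panel.fio2),
            }
        )
    computed = pd.DataFrame(rows, index=df.index)
    for col in computed.columns:
        out[col] = computed[col]
    return out
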