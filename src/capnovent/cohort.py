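"""Synthetic crossover cohort generator.

Eleven-subject, two-mode (PCV, VV) by three-stage (START, CP, post-CP)
crossover with subject random intercepts.  Cell means and SDs default to the
published stage summaries where those are printed in text; stage levels that
appear only in figures (Raw, G, H and absolute Qs/Qt) use plausible
baselines carrying the printed relative changes and are configuration-only
assumptions.  Shunt fractions are derived through the oxygen-content
equations from generated blood-gas panels, never drawn independently.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigError
from .gas_exchange import BloodGasPanel, oxygen_contents, shunt_fraction
from .oscillometry import (
    ForcingSpec,
    MechanicalState,
    cpm_impedance,
    make_forcing_signal,
    tube_impedance,
)
from .ventilation import driving_pressure

__all__ = [
    "OUTCOMES",
    "MODES",
    "STAGES",
    "StageEffectConfig",
    "SubjectStageRecord",
    "default_config",
    "null_config",
    "generate_cohort",
    "cohort_to_frame",
    "generate_oscillometry_raw",
]

MODES = ("pcv", "vv")
STAGES = ("start", "cp", "post_cp")

OUTCOMES = (
    "pao2_fio2",  # mmHg
    "paco2",  # mmHg
    "qs_qt",  # fraction
    "raw",  # cmH2O.s/L
    "g",  # cmH2O/L
    "h",  # cmH2O/L
    "map",  # mmHg
    "hr",  # /min
    "co",  # L/min
    "p_driving",  # cmH2O
    "vt_ml",  # mL
    "rr",  # /min
)

# (mean, SD) per cell, ordered (start, cp, post_cp) within each mode.
# Abstract/Results-derived gas-exchange cells; hemodynamic and ventilation
# cells straight from the published table; mechanics and absolute shunt
# levels are assumptions consistent with the printed relative changes.
_DEFAULT_CELLS: dict[str, dict[tuple[str, str], tuple[float, float]]] = {
    "pao2_fio2": {
        ("pcv", "start"): (440.8, 35.0),
        ("pcv", "cp"): (405.5, 34.1),
        ("pcv", "post_cp"): (423.2, 38.0),
        ("vv", "start"): (425.9, 40.0),
        ("vv", "cp"): (370.5, 44.9),
        ("vv", "post_cp"): (438.7, 35.0),
    },
    "paco2": {
        ("pcv", "start"): (37.8, 3.2),
        ("pcv", "cp"): (48.4, 5.1),
        ("pcv", "post_cp"): (44.6, 4.3),
        ("vv", "start"): (35.4, 3.2),
        ("vv", "cp"): (52.8, 6.0),
        ("vv", "post_cp"): (41.0, 2.3),
    },
    "qs_qt": {
        ("pcv", "start"): (0.080, 0.018),
        ("pcv", "cp"): (0.106, 0.024),
        ("pcv", "post_cp"): (0.101, 0.022),
        ("vv", "start"): (0.080, 0.018),
        ("vv", "cp"): (0.129, 0.030),
        ("vv", "post_cp"): (0.084, 0.019),
    },
    "raw": {
        ("pcv", "start"): (27.0, 4.0),
        ("pcv", "cp"): (33.0, 5.0),
        ("pcv", "post_cp"): (27.5, 4.0),
        ("vv", "start"): (27.0, 4.0),
        ("vv", "cp"): (33.0, 5.0),
        ("vv", "post_cp"): (27.5, 4.0),
    },
    "g": {
        ("pcv", "start"): (350.0, 55.0),
        ("pcv", "cp"): (490.0, 80.0),
        ("pcv", "post_cp"): (355.0, 55.0),
        ("vv", "start"): (350.0, 55.0),
        ("vv", "cp"): (490.0, 80.0),
        ("vv", "post_cp"): (355.0, 55.0),
    },
    "h": {
        ("pcv", "start"): (1900.0, 280.0),
        ("pcv", "cp"): (2660.0, 420.0),
        ("pcv", "post_cp"): (1920.0, 290.0),
        ("vv", "start"): (1900.0, 280.0),
        ("vv", "cp"): (2660.0, 420.0),
        ("vv", "post_cp"): (1920.0, 290.0),
    },
    "map": {
        ("pcv", "start"): (67.0, 16.0),
        ("pcv", "cp"): (76.0, 14.0),
        ("pcv", "post_cp"): (75.0, 13.0),
        ("vv", "start"): (68.0, 15.0),
        ("vv", "cp"): (78.0, 14.0),
        ("vv", "post_cp"): (73.0, 15.0),
    },
    "hr": {
        ("pcv", "start"): (219.0, 10.0),
        ("pcv", "cp"): (215.0, 20.0),
        ("pcv", "post_cp"): (225.0, 11.0),
        ("vv", "start"): (219.0, 21.0),
        ("vv", "cp"): (215.0, 31.0),
        ("vv", "post_cp"): (225.0, 20.0),
    },
    "co": {
        ("pcv", "start"): (0.51, 0.18),
        ("pcv", "cp"): (0.59, 0.18),
        ("pcv", "post_cp"): (0.58, 0.16),
        ("vv", "start"): (0.47, 0.12),
        ("vv", "cp"): (0.54, 0.14),
        ("vv", "post_cp"): (0.53, 0.18),
    },
    "p_driving": {
        ("pcv", "start"): (5.4, 0.8),
        ("pcv", "cp"): (8.9, 1.1),
        ("pcv", "post_cp"): (5.2, 0.8),
        ("vv", "start"): (5.7, 0.7),
        ("vv", "cp"): (8.5, 1.5),
        ("vv", "post_cp"): (5.3, 0.8),
    },
    "vt_ml": {
        ("pcv", "start"): (24.2, 1.7),
        ("pcv", "cp"): (24.1, 1.6),
        ("pcv", "post_cp"): (23.8, 1.7),
        ("vv", "start"): (24.1, 1.6),
        ("vv", "cp"): (24.1, 1.5),
        ("vv", "post_cp"): (24.2, 1.7),
    },
    "rr": {
        ("pcv", "start"): (22.2, 1.6),
        ("pcv", "cp"): (22.4, 1.4),
        ("pcv", "post_cp"): (22.4, 1.4),
        ("vv", "start"): (22.2, 1.6),
        ("vv", "cp"): (22.1, 1.6),
        ("vv", "post_cp"): (22.2, 1.6),
    },
}

# Outcomes whose defaults come straight from printed text/table values.
PRINTED_OUTCOMES = (
    "paco2", "pao2_fio2", "map", "hr", "co", "p_driving", "vt_ml", "rr",
)

_LOWER_BOUNDS = {name: 1e-6 for name in OUTCOMES}


@dataclass
class StageEffectConfig:
    """Target moments of every (mode, stage) cell plus coupling structure."""

    cells: dict[str, dict[tuple[str, str], tuple[float, float]]]
    between_subject_frac: float = 0.6  # share of cell SD from the random intercept
    coupling_slope: float = -0.3  # H change -> Pao2/FiO2 change at CP
    carryover: float = 0.0  # crossover analysis assumes none
    peep: float = 5.0
    fio2: float = 0.4

    def __post_init__(self):
        if not 0.0 <= self.between_subject_frac < 1.0:
            raise ConfigError("between_subject_frac must be in [0, 1)")
        if self.carryover != 0.0:
            raise ConfigError("mode carryover is fixed at zero by design")
        for outcome in OUTCOMES:
            if outcome not in self.cells:
                raise ConfigError(f"missing outcome {outcome!r} in cell config")
            for mode in MODES:
                for stage in STAGES:
                    if (mode, stage) not in self.cells[outcome]:
                        raise ConfigError(f"missing cell {(mode, stage)} for {outcome!r}")
                    mean, sd = self.cells[outcome][(mode, stage)]
                    if sd < 0 or not np.isfinite(mean):
                        raise ConfigError(f"bad moments for {outcome!r} {(mode, stage)}")

    def cell(self, outcome: str, mode: str, stage: str) -> tuple[float, float]:
        return self.cells[outcome][(mode, stage)]

    def to_dict(self) -> dict:
        return {
            "cells": {
                outcome: {f"{m}|{s}": list(v) for (m, s), v in table.items()}
                for outcome, table in self.cells.items()
            },
            "between_subject_frac": self.between_subject_frac,
            "coupling_slope": self.coupling_slope,
            "carryover": self.carryover,
            "peep": self.peep,
            "fio2": self.fio2,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StageEffectConfig":
        cells = {
            outcome: {
                tuple(key.split("|")): tuple(v) for key, v in table.items()
            }
            for outcome, table in d["cells"].items()
        }
        return cls(
            cells=cells,
            between_subject_frac=d.get("between_subject_frac", 0.6),
            coupling_slope=d.get("coupling_slope", -0.3),
            carryover=d.get("carryover", 0.0),
            peep=d.get("peep", 5.0),
            fio2=d.get("fio2", 0.4),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "StageEffectConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def default_config(**kw) -> StageEffectConfig:
    cells = {o: dict(t) for o, t in _DEFAULT_CELLS.items()}
    return StageEffectConfig(cells=cells, **kw)


def null_config(**kw) -> StageEffectConfig:
    """All six cells of every outcome share the (PCV, START) moments."""
    cells = {}
    for outcome, table in _DEFAULT_CELLS.items():
        base = table[("pcv", "start")]
        cells[outcome] = {(m, s): base for m in MODES for s in STAGES}
    return StageEffectConfig(cells=cells, **kw)


@dataclass(frozen=True)
class SubjectStageRecord:
    subject: int
    arm: str  # 'pcv_first' | 'vv_first'
    mode: str
    stage: str
    outcomes: dict[str, float]
    mech: MechanicalState
    panel: BloodGasPanel
    pip: float
    peep: float


def generate_cohort(
    config: StageEffectConfig, n_subjects: int = 11, seed: int = 0
) -> list[SubjectStageRecord]:
    """Draw one full crossover cohort (6 records per subject)."""
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    rng = np.random.default_rng(seed)

    for outcome in OUTCOMES:
        for key, (mean, sd) in config.cells[outcome].items():
            if mean > 0 and sd > mean / 2.0:
                warnings.warn(
                    f"cell SD > mean/2 for {outcome!r} {key}: truncation bias may "
                    "exceed 5%",
                    UserWarning,
                    stacklevel=2,
                )

    # Balanced seeded arm assignment (6/5 split at n=11).
    order = rng.permutation(n_subjects)
    arms = np.empty(n_subjects, dtype=object)
    half = (n_subjects + 1) // 2
    arms[order[:half]] = "pcv_first"
    arms[order[half:]] = "vv_first"

    rho = config.between_subject_frac
    resid_scale = np.sqrt(1.0 - rho**2)

    values: dict[str, np.ndarray] = {}
    for outcome in OUTCOMES:
        u = rng.normal(0.0, 1.0, n_subjects)  # subject intercept, outcome-specific
        cell = np.empty((n_subjects, len(MODES), len(STAGES)))
        for j, mode in enumerate(MODES):
            for k, stage in enumerate(STAGES):
                mean, sd = config.cell(outcome, mode, stage)
                e = rng.normal(0.0, 1.0, n_subjects)
                x = mean + sd * (rho * u + resid_scale * e)
                lower = _LOWER_BOUNDS[outcome]
                bad = x <= lower
                tries = 0
                while np.any(bad):
                    x = np.where(
                        bad,
                        mean + sd * (rho * u + resid_scale * rng.normal(0.0, 1.0, n_subjects)),
                        x,
                    )
                    bad = x <= lower
                    tries += 1
                    if tries > 1000:
                        raise ConfigError(
                            f"cannot draw {outcome!r} {(mode, stage)} above {lower}"
                        )
                cell[:, j, k] = x
        values[outcome] = cell

    # Mechanics -> oxygenation coupling at CP: a centered multiplicative term
    # keeps the cell mean while tying Pao2/FiO2 to the subject's H rise.
    if config.coupling_slope != 0.0:
        k_cp = STAGES.index("cp")
        k_start = STAGES.index("start")
        for j in range(len(MODES)):
            ratio = values["h"][:, j, k_cp] / values["h"][:, j, k_start]
            centered = (ratio - ratio.mean()) / max(ratio.mean(), 1e-12)
            values["pao2_fio2"][:, j, k_cp] *= 1.0 + config.coupling_slope * centered

    # Ancillary blood-gas quantities (not study outcomes).
    sao2 = np.clip(rng.normal(0.99, 0.004, (n_subjects, 2, 3)), 0.95, 0.999)
    hb = np.clip(rng.normal(12.0, 0.8, (n_subjects, 2, 3)), 8.0, 16.0)
    pvo2 = np.clip(rng.normal(40.0, 3.0, (n_subjects, 2, 3)), 25.0, 60.0)
    iaw = np.clip(rng.normal(0.10, 0.015, (n_subjects, 2, 3)), 0.02, 0.3)

    records: list[SubjectStageRecord] = []
    for i in range(n_subjects):
        for j, mode in enumerate(MODES):
            for k, stage in enumerate(STAGES):
                pf = values["pao2_fio2"][i, j, k]
                paco2 = values["paco2"][i, j, k]
                qs_target = min(values["qs_qt"][i, j, k], 0.95)
                pao2 = pf * config.fio2

                panel = _panel_for_shunt(
                    pao2=pao2,
                    paco2=paco2,
                    sao2=sao2[i, j, k],
                    hb=hb[i, j, k],
                    pvo2=pvo2[i, j, k],
                    fio2=config.fio2,
                    qs_target=qs_target,
                )
                qs_qt = shunt_fraction(oxygen_contents(panel))

                mech = MechanicalState(
                    raw=values["raw"][i, j, k],
                    iaw=iaw[i, j, k],
                    g=values["g"][i, j, k],
                    h=values["h"][i, j, k],
                )
                p_drv = values["p_driving"][i, j, k]
                pip = config.peep + p_drv
                outcomes = {o: float(values[o][i, j, k]) for o in OUTCOMES}
                outcomes["qs_qt"] = float(qs_qt)
                outcomes["pao2_fio2"] = float(pf)
                outcomes["p_driving"] = float(driving_pressure(pip, config.peep))
                outcomes["eta"] = mech.eta
                records.append(
                    SubjectStageRecord(
                        subject=i + 1,
                        arm=str(arms[i]),
                        mode=mode,
                        stage=stage,
                        outcomes=outcomes,
                        mech=mech,
                        panel=panel,
                        pip=float(pip),
                        peep=config.peep,
                    )
                )
    return records


def _panel_for_shunt(pao2, paco2, sao2, hb, pvo2, fio2, qs_target) -> BloodGasPanel:
    """Choose venous saturation so the content balance hits the target shunt."""
    trial = BloodGasPanel(
        pao2=pao2, paco2=paco2, sao2=sao2, hb_art=hb,
        pvo2=pvo2, svo2=0.7, hb_ven=hb, fio2=fio2,
    )
    contents = oxygen_contents(trial)
    qs_target = float(np.clip(qs_target, 1e-4, 0.95))
    # Cv that realizes the target; Sv'O2 clamped to a physiologic window, so
    # the recorded Qs/Qt is always recomputed from the final panel.
    cv = contents.cc - (contents.cc - contents.ca) / qs_target
    from .gas_exchange import HUFNER, O2_SOLUBILITY

    svo2 = (cv - pvo2 * O2_SOLUBILITY) / (HUFNER * hb)
    svo2 = float(np.clip(svo2, 0.05, min(sao2, 0.98)))
    return BloodGasPanel(
        pao2=pao2, paco2=paco2, sao2=sao2, hb_art=hb,
        pvo2=pvo2, svo2=svo2, hb_ven=hb, fio2=fio2,
    )


_STAGE_ORDER = {s: i for i, s in enumerate(STAGES)}


def cohort_to_frame(records: list[SubjectStageRecord]) -> pd.DataFrame:
    """Tidy table: one record per row, outcome and panel columns flattened."""
    rows = []
    for r in records:
        row = {
            "subject": r.subject,
            "arm": r.arm,
            "mode": r.mode,
            "stage": r.stage,
            "pip": r.pip,
            "peep": r.peep,
        }
        row.update(r.outcomes)
        row.update(
            {
                "iaw": r.mech.iaw,
                "pao2": r.panel.pao2,
                "sao2": r.panel.sao2,
                "hb_art": r.panel.hb_art,
                "pvo2": r.panel.pvo2,
                "svo2": r.panel.svo2,
                "hb_ven": r.panel.hb_ven,
                "fio2": r.panel.fio2,
            }
        )
        rows.append(row)
    df = pd.DataFrame(rows)
    df["stage_order"] = df["stage"].map(_STAGE_ORDER)
    return df.sort_values(["subject", "mode", "stage_order"]).drop(
        columns="stage_order"
    ).reset_index(drop=True)


def generate_oscillometry_raw(
    record: SubjectStageRecord,
    spec: ForcingSpec | None = None,
    noise_sd: float = 0.0,
    n_reps: int = 1,
    seed: int = 0,
    tube=None,
):
    """Raw apneic pressure/flow recordings whose true impedance is the
    record's mechanics in series with the tube."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if spec is None:
        spec = ForcingSpec()
    freqs = spec.frequency_array()
    if tube is None:
        tube = tube_impedance(freqs)
    z_total = cpm_impedance(record.mech, freqs).values + tube.values

    n = spec.n_samples
    bins = np.round(freqs * n / spec.sample_rate).astype(int)
    rng = np.random.default_rng(seed)
    out = []
    for rep in range(n_reps):
        pressure = make_forcing_signal(spec, seed=int(rng.integers(0, 2**31 - 1)))
        p_hat = np.fft.rfft(pressure)
        f_hat = np.zeros_like(p_hat)
        f_hat[bins] = p_hat[bins] / z_total
        flow = np.fft.irfft(f_hat, n)
        if noise_sd > 0:
            pressure = pressure + rng.normal(0.0, noise_sd * pressure.std(), n)
            flow = flow + rng.normal(0.0, noise_sd * flow.std(), n)
        out.append((pressure, flow))
    return out
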