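"""Breath-plan generation and single-compartment breath delivery.

Pressure-controlled breaths are ideal square waves between PEEP and PIP with
a fixed inspiratory:expiratory ratio, driving a linear single-compartment
lung with resistance R = Raw + G/w_b**alpha (w_b = breathing angular
frequency) and elastance E = H.  Variable ventilation draws truncated
Gaussian multipliers on PIP-PEEP and on breath rate, then rescales every
disjoint averaging window so the window means hit the conventional targets
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .errors import ConfigError, NumericalError
from .oscillometry import MechanicalState

__all__ = [
    "VentilatorSettings",
    "BreathPlan",
    "SimulatedBreathing",
    "DEFAULT_MECHANICS",
    "effective_resistance",
    "make_pcv_plan",
    "make_vv_plan",
    "calibrate_pip_for_vt",
    "simulate_breaths",
    "driving_pressure",
]

#: Default lung used when a plan is built without explicit mechanics.
DEFAULT_MECHANICS = MechanicalState(raw=25.0, iaw=0.1, g=300.0, h=1500.0)

# Multiplier truncation in pre-truncation SD units; the draw scale is
# inflated by the truncated-normal SD shrinkage so the realized CV matches
# the nominal one.
_TRUNC_SD = 2.0
_TRUNC_SHRINK = float(
    np.sqrt(truncnorm.stats(-_TRUNC_SD, _TRUNC_SD, moments="v"))
)


@dataclass(frozen=True)
class VentilatorSettings:
    mode: str
    target_vt_per_kg: float = 7.0  # mL/kg
    body_mass: float = 3.9  # kg
    rr_target: float = 22.0  # breaths/min
    peep: float = 5.0  # cmH2O
    ie_ratio: float = 0.5  # inspiratory:expiratory, 1:2
    fio2: float = 0.4
    vv_cv_pip: float = 0.0
    vv_cv_rr: float = 0.0
    averaging_window: int = 30

    def __post_init__(self):
        if self.mode not in ("pcv", "vv"):
            raise ValueError(f"mode must be 'pcv' or 'vv', got {self.mode!r}")
        if not 0.0 < self.fio2 <= 1.0:
            raise ValueError("fio2 must be in (0, 1]")
        if self.peep < 0:
            raise ValueError("peep must be >= 0")
        if not 20.0 <= self.rr_target <= 25.0:
            raise ValueError("rr_target outside the protocol range 20-25/min")
        if self.target_vt_per_kg < 0 or self.body_mass <= 0:
            raise ValueError("non-physical tidal-volume target")
        if self.ie_ratio <= 0:
            raise ValueError("ie_ratio must be positive")
        if self.mode == "pcv" and (self.vv_cv_pip != 0 or self.vv_cv_rr != 0):
            raise ValueError("PCV requires zero breath-to-breath variability")
        if self.vv_cv_pip < 0 or self.vv_cv_rr < 0:
            raise ValueError("coefficients of variation must be >= 0")
        if self.averaging_window < 1:
            raise ValueError("averaging_window must be >= 1")

    @classmethod
    def pcv(cls, **kw) -> "VentilatorSettings":
        return cls(mode="pcv", **kw)

    @classmethod
    def vv(cls, vv_cv_pip: float = 0.2, vv_cv_rr: float = 0.2, **kw) -> "VentilatorSettings":
        return cls(mode="vv", vv_cv_pip=vv_cv_pip, vv_cv_rr=vv_cv_rr, **kw)

    @property
    def target_vt_ml(self) -> float:
        return self.target_vt_per_kg * self.body_mass


@dataclass(frozen=True)
class BreathPlan:
    """Per-breath PIP (cmH2O) and cycle duration (s)."""

    pips: np.ndarray
    durations: np.ndarray
    peep: float
    base_pip: float
    target_vt_ml: float
    seed: int | None = None

    def __post_init__(self):
        pips = np.asarray(self.pips, dtype=float)
        durations = np.asarray(self.durations, dtype=float)
        if pips.shape != durations.shape or pips.ndim != 1 or pips.size == 0:
            raise ValueError("pips and durations must be equal-length 1-D arrays")
        if np.any(pips <= self.peep):
            raise ValueError("every PIP must exceed PEEP")
        if np.any(durations <= 0):
            raise ValueError("every breath duration must be positive")
        object.__setattr__(self, "pips", pips)
        object.__setattr__(self, "durations", durations)

    @property
    def n_breaths(self) -> int:
        return self.pips.size

    def model_vt_ml(self) -> np.ndarray:
        """Per-breath tidal volume on the plan's linear model (VT ~ PIP-PEEP)."""
        return self.target_vt_ml * (self.pips - self.peep) / (self.base_pip - self.peep)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "breath": np.arange(1, self.n_breaths + 1),
                "pip_cmh2o": self.pips,
                "duration_s": self.durations,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def sidecar(self) -> dict:
        return {
            "peep": self.peep,
            "base_pip": self.base_pip,
            "target_vt_ml": self.target_vt_ml,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class SimulatedBreathing:
    """Time-domain realization of a breath plan on a linear lung."""

    time: np.ndarray  # s
    pressure: np.ndarray  # airway-opening pressure, cmH2O
    flow: np.ndarray  # L/s
    volume: np.ndarray  # L above end-expiratory volume
    vt_ml: np.ndarray  # delivered tidal volume per breath
    breath_bounds: np.ndarray  # sample index starting each breath, plus end
    dt: float
    # Flow is discontinuous where the square wave switches; these record the
    # sample index opening each smooth segment and the right-limit flow there,
    # so quadrature can respect the jumps.
    segment_starts: np.ndarray | None = None
    segment_flow0: np.ndarray | None = None

    def trapezoid_volume(self) -> np.ndarray:
        """Time-integral of flow by segment-aware trapezoid, as a cumulative
        volume trace comparable to ``volume - volume[0]``."""
        if self.segment_starts is None:
            raise ValueError("segment metadata missing")
        f = self.flow.copy()
        # substitute right limits at segment-opening samples for integration
        increments = 0.5 * self.dt * (f[1:] + f[:-1])
        for idx, f0 in zip(self.segment_starts, self.segment_flow0):
            if idx < f.size - 1:
                increments[idx] = 0.5 * self.dt * (f0 + f[idx + 1])
        return np.concatenate([[0.0], np.cumsum(increments)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time,
                "pao_cmh2o": self.pressure,
                "flow_l_s": self.flow,
                "volume_l": self.volume,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def effective_resistance(mech: MechanicalState, rr_per_min: float) -> float:
    """First-order resistance at the breathing frequency: Raw + G/w_b**alpha."""
    w_b = 2.0 * np.pi * rr_per_min / 60.0
    return mech.raw + mech.g / w_b ** mech.alpha


def simulate_breaths(
    plan: BreathPlan,
    mech: MechanicalState,
    peep: float | None = None,
    ie_ratio: float = 0.5,
    dt: float = 5e-4,
    v0: float = 0.0,
) -> SimulatedBreathing:
    """Deliver a breath plan on the single-compartment R-E lung.

    Exact exponential update of R*V' + E*V = Pao - PEEP per constant-pressure
    segment; per-breath VT is the maximum inspired volume minus the
    end-expiratory volume of that breath.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if dt > 1e-3 + 1e-12:
        raise ValueError("dt must be <= 1 ms")
    if peep is None:
        peep = plan.peep
    rr_equiv = 60.0 / float(np.mean(plan.durations))
    r = effective_resistance(mech, rr_equiv)
    e = mech.h
    tau = r / e

    times, paos, flows, vols, vt_ml = [], [], [], [], []
    bounds = [0]
    seg_starts, seg_flow0 = [], []
    v = float(v0)
    t_start = 0.0
    sample_count = 1  # leading t=0 sample
    for pip, dur in zip(plan.pips, plan.durations):
        n_tot = max(int(round(dur / dt)), 2)
        n_insp = min(max(int(round(n_tot * ie_ratio / (1.0 + ie_ratio))), 1), n_tot - 1)
        v_peak = v
        for target, n_seg, drive in (
            ((pip - peep) / e, n_insp, pip),
            (0.0, n_tot - n_insp, peep),
        ):
            seg_starts.append(sample_count - 1)
            seg_flow0.append((target - v) / tau)
            k = np.arange(1, n_seg + 1)
            decay = np.exp(-k * dt / tau)
            v_seg = target + (v - target) * decay
            f_seg = (target - v_seg) / tau
            times.append(t_start + k * dt)
            paos.append(np.full(n_seg, drive))
            flows.append(f_seg)
            vols.append(v_seg)
            v_peak = max(v_peak, float(v_seg.max()))
            v = float(v_seg[-1])
            t_start += n_seg * dt
            sample_count += n_seg
        vt_ml.append((v_peak - v) * 1000.0)
        bounds.append(bounds[-1] + n_tot)

    time = np.concatenate([[0.0], np.concatenate(times)])
    pao = np.concatenate([[plan.pips[0]], np.concatenate(paos)])
    flow0 = ((plan.pips[0] - peep) / e - v0) / tau
    flow = np.concatenate([[flow0], np.concatenate(flows)])
    volume = np.concatenate([[v0], np.concatenate(vols)])
    return SimulatedBreathing(
        time=time,
        pressure=pao,
        flow=flow,
        volume=np.maximum(volume, 0.0),
        vt_ml=np.asarray(vt_ml),
        breath_bounds=np.asarray(bounds),
        dt=dt,
        segment_starts=np.asarray(seg_starts),
        segment_flow0=np.asarray(seg_flow0),
    )


def _steady_state_vt_ml(
    delta_p: float, mech: MechanicalState, settings: VentilatorSettings, dt: float
) -> float:
    pip = settings.peep + delta_p
    plan = BreathPlan(
        pips=np.full(4, pip),
        durations=np.full(4, 60.0 / settings.rr_target),
        peep=settings.peep,
        base_pip=pip,
        target_vt_ml=settings.target_vt_ml,
    )
    sim = simulate_breaths(plan, mech, ie_ratio=settings.ie_ratio, dt=dt)
    return float(sim.vt_ml[-1])


def calibrate_pip_for_vt(
    mech: MechanicalState,
    settings: VentilatorSettings,
    dt: float = 5e-4,
    rel_tol: float = 1e-3,
    max_iter: int = 100,
) -> float:
    """PIP (cmH2O) whose steady-state breath delivers the target VT.

    Monotone bisection on PIP-PEEP against the simulated delivered VT.
    """
    target = settings.target_vt_ml
    if target == 0.0:
        return settings.peep
    if target < 0:
        raise ValueError("target VT must be non-negative")
    lo, hi = 0.0, 2.0 * (target / 1000.0) * mech.h
    for _ in range(max_iter):
        if _steady_state_vt_ml(hi, mech, settings, dt) >= target:
            break
        hi *= 2.0
    else:
        raise NumericalError(
            "failed to bracket the target VT",
            {"target_vt_ml": target, "hi": hi},
        )
    for i in range(max_iter):
        mid = 0.5 * (lo + hi)
        vt = _steady_state_vt_ml(mid, mech, settings, dt)
        if abs(vt - target) <= rel_tol * target:
            return settings.peep + mid
        if vt < target:
            lo = mid
        else:
            hi = mid
    raise NumericalError(
        "bisection failed to converge on PIP",
        {"target_vt_ml": target, "lo": lo, "hi": hi, "iterations": max_iter},
    )


def make_pcv_plan(
    settings: VentilatorSettings,
    n_breaths: int,
    mech: MechanicalState = DEFAULT_MECHANICS,
    seed: int | None = None,
) -> BreathPlan:
    """Constant-PIP, constant-rate plan hitting the VT target."""
    if n_breaths < 1:
        raise ValueError("n_breaths must be >= 1")
    pip = calibrate_pip_for_vt(mech, settings)
    return BreathPlan(
        pips=np.full(n_breaths, pip),
        durations=np.full(n_breaths, 60.0 / settings.rr_target),
        peep=settings.peep,
        base_pip=pip,
        target_vt_ml=settings.target_vt_ml,
        seed=seed,
    )


def _window_slices(n: int, window: int):
    for start in range(0, n, window):
        yield slice(start, min(start + window, n))


def make_vv_plan(
    settings: VentilatorSettings,
    n_breaths: int,
    seed: int,
    mech: MechanicalState = DEFAULT_MECHANICS,
) -> BreathPlan:
    """Variable plan whose disjoint averaging windows match the PCV targets.

    Truncated-Gaussian multipliers (nominal CV, +/-2 SD) are applied to
    PIP-PEEP and to breath rate, then each disjoint window is affinely
    rescaled so its mean rate and mean model-predicted VT are exact.
    """
    if n_breaths < 1:
        raise ValueError("n_breaths must be >= 1")
    cv_p, cv_r = settings.vv_cv_pip, settings.vv_cv_rr
    for name, cv in (("vv_cv_pip", cv_p), ("vv_cv_rr", cv_r)):
        scale = cv / _TRUNC_SHRINK
        if 1.0 - _TRUNC_SD * scale <= 0.0:
            raise ConfigError(
                f"{name}={cv} pushes the truncation floor to or below zero "
                "(PIP would not exceed PEEP)"
            )
    if cv_p == 0.0 and cv_r == 0.0:
        return make_pcv_plan(
            replace(settings, mode="pcv"), n_breaths, mech=mech, seed=seed
        )

    rng = np.random.default_rng(seed)

    def multipliers(cv):
        if cv == 0.0:
            return np.ones(n_breaths)
        scale = cv / _TRUNC_SHRINK
        return truncnorm.rvs(
            -_TRUNC_SD, _TRUNC_SD, loc=1.0, scale=scale, size=n_breaths, random_state=rng
        )

    mp = multipliers(cv_p)
    mr = multipliers(cv_r)
    for sl in _window_slices(n_breaths, settings.averaging_window):
        mp[sl] /= mp[sl].mean()
        mr[sl] /= mr[sl].mean()

    base_pip = calibrate_pip_for_vt(mech, settings)
    pips = settings.peep + (base_pip - settings.peep) * mp
    rates = settings.rr_target * mr
    if np.any(pips <= settings.peep):
        raise ConfigError("window rescaling drove a PIP to or below PEEP")
    return BreathPlan(
        pips=pips,
        durations=60.0 / rates,
        peep=settings.peep,
        base_pip=base_pip,
        target_vt_ml=settings.target_vt_ml,
        seed=seed,
    )


def driving_pressure(pip: float, peep: float) -> float:
    """PIP minus PEEP."""
    if pip < peep:
        raise ValueError("pip must be >= peep")
    return pip - peep
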