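"""End-to-end in-silico study: cohort -> oscillometry fits -> gas exchange -> stats."""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from .cohort import StageEffectConfig, default_config, generate_cohort, cohort_to_frame
from .errors import CapnoventError
from .oscillometry import ForcingSpec, fit_recordings, tube_impedance
from .stats import pairwise_cells, relative_changes, rm_anova
from .ventilation import VentilatorSettings

__all__ = ["StudyConfig", "StudyResults", "run_study"]

log = logging.getLogger("capnovent")

#: Outcomes analyzed by the statistical stage (eta is derived but analyzed).
ANALYSIS_OUTCOMES = cohort_mod.OUTCOMES + ("eta",)


@dataclass
class StudyConfig:
    n_subjects: int = 11
    seed: int = 1
    stage_config: StageEffectConfig = field(default_factory=default_config)
    forcing: ForcingSpec = field(default_factory=ForcingSpec)
    settings_pcv: VentilatorSettings = field(
        default_factory=lambda: VentilatorSettings.pcv()
    )
    settings_vv: VentilatorSettings = field(
        default_factory=lambda: VentilatorSettings.vv()
    )
    osc_noise_sd: float = 0.03
    osc_n_reps: int = 3
    fit_oscillometry: bool = True
    outdir: str | None = None

    def to_dict(self) -> dict:
        d = {
            "n_subjects": self.n_subjects,
            "seed": self.seed,
            "stage_config": self.stage_config.to_dict(),
            "forcing": {
                "f_min": self.forcing.f_min,
                "f_max": self.forcing.f_max,
                "n_components": self.forcing.n_components,
                "duration": self.forcing.duration,
                "sample_rate": self.forcing.sample_rate,
                "frequencies": list(self.forcing.frequencies)
                if self.forcing.frequencies is not None
                else None,
                "amplitudes": list(self.forcing.amplitudes)
                if self.forcing.amplitudes is not None
                else None,
            },
            "settings_pcv": asdict(self.settings_pcv),
            "settings_vv": asdict(self.settings_vv),
            "osc_noise_sd": self.osc_noise_sd,
            "osc_n_reps": self.osc_n_reps,
            "fit_oscillometry": self.fit_oscillometry,
            "outdir": self.outdir,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        forcing_kw = dict(d.get("forcing", {}))
        if forcing_kw.get("frequencies") is not None:
            forcing_kw["frequencies"] = tuple(forcing_kw["frequencies"])
        if forcing_kw.get("amplitudes") is not None:
            forcing_kw["amplitudes"] = tuple(forcing_kw["amplitudes"])
        return cls(
            n_subjects=d.get("n_subjects", 11),
            seed=d.get("seed", 1),
            stage_config=StageEffectConfig.from_dict(d["stage_config"])
            if "stage_config" in d
            else default_config(),
            forcing=ForcingSpec(**forcing_kw),
            settings_pcv=VentilatorSettings(**d["settings_pcv"])
            if "settings_pcv" in d
            else VentilatorSettings.pcv(),
            settings_vv=VentilatorSettings(**d["settings_vv"])
            if "settings_vv" in d
            else VentilatorSettings.vv(),
            osc_noise_sd=d.get("osc_noise_sd", 0.03),
            osc_n_reps=d.get("osc_n_reps", 3),
            fit_oscillometry=d.get("fit_oscillometry", True),
            outdir=d.get("outdir"),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class StudyResults:
    cohort: pd.DataFrame
    fits: list[dict]
    analysis: dict
    warnings: list[str]

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.cohort.to_csv(outdir / "cohort.csv", index=False)
        with open(outdir / "fits.json", "w") as fh:
            json.dump(self.fits, fh, indent=1, sort_keys=True)
        with open(outdir / "results.json", "w") as fh:
            json.dump(
                {"analysis": self.analysis, "warnings": self.warnings},
                fh,
                indent=1,
                sort_keys=True,
            )
        (outdir / "report.md").write_text(self.report_markdown())

    def report_markdown(self) -> str:
        lines = ["# In-silico crossover study report", ""]
        if self.warnings:
            lines += ["## Warnings", ""] + [f"- {w}" for w in self.warnings] + [""]
        outcomes = list(self.analysis["anova"])
        lines += ["## Cell means (mean ± SD)", ""]
        header = "| outcome | " + " | ".join(
            f"{m.upper()} {s}" for m in cohort_mod.MODES for s in cohort_mod.STAGES
        ) + " |"
        lines += [header, "|" + "---|" * 7]
        for outcome in outcomes:
            cells = []
            for m in cohort_mod.MODES:
                for s in cohort_mod.STAGES:
                    sub = self.cohort[
                        (self.cohort["mode"] == m) & (self.cohort["stage"] == s)
                    ][outcome]
                    cells.append(f"{sub.mean():.3g} ± {sub.std(ddof=1):.2g}")
            lines.append(f"| {outcome} | " + " | ".join(cells) + " |")
        lines += ["", "## Two-way repeated-measures ANOVA", ""]
        lines += [
            "| outcome | F(mode) | p(mode) | F(stage) | p(stage, GG) | F(inter) | p(inter, GG) |",
            "|" + "---|" * 7,
        ]
        for outcome in outcomes:
            an = self.analysis["anova"][outcome]
            lines.append(
                f"| {outcome} | {an['mode']['F']:.3g} | {an['mode']['p']:.3g} "
                f"| {an['stage']['F']:.3g} | {an['stage']['p_gg']:.3g} "
                f"| {an['interaction']['F']:.3g} | {an['interaction']['p_gg']:.3g} |"
            )
        lines += ["", "## Relative changes from START (mean % [95% CI])", ""]
        lines += [
            "| outcome | mode | contrast | mean % | 95% CI |",
            "|" + "---|" * 5,
        ]
        for outcome in outcomes:
            for rc in self.analysis["relative_changes"][outcome]:
                lines.append(
                    f"| {outcome} | {rc['mode']} | {rc['contrast']} "
                    f"| {rc['mean_pct']:.1f} | [{rc['ci95'][0]:.1f}, {rc['ci95'][1]:.1f}] |"
                )
        return "\n".join(lines) + "\n"


def _stage_guard(stage_name: str, record_id: str | None = None):
    class _Guard:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, CapnoventError):
                return False
            if exc is not None:
                where = f" (record {record_id})" if record_id else ""
                raise CapnoventError(f"stage {stage_name!r} failed{where}: {exc}") from exc
            return False

    return _Guard()


def run_study(config: StudyConfig) -> StudyResults:
    """Execute the full simulated crossover study.

    Deterministic for a fixed config: the master seed spawns independent
    per-stage seed sequences, so e.g. oscillometry noise never perturbs the
    cohort draws.
    """
    t0 = time.perf_counter()
    run_warnings: list[str] = []
    if config.n_subjects < 6:
        msg = f"n_subjects={config.n_subjects}: analysis is under-powered"
        warnings.warn(msg, UserWarning, stacklevel=2)
        run_warnings.append(msg)

    ss = np.random.SeedSequence(config.seed)
    cohort_seed, osc_root = ss.spawn(2)

    with _stage_guard("simulate"):
        records = generate_cohort(
            config.stage_config,
            n_subjects=config.n_subjects,
            seed=cohort_seed.generate_state(1)[0],
        )
    df = cohort_to_frame(records)
    log.info("simulate: %d records in %.2fs", len(df), time.perf_counter() - t0)

    fits: list[dict] = []
    if config.fit_oscillometry:
        t1 = time.perf_counter()
        freqs = config.forcing.frequency_array()
        tube = tube_impedance(freqs)
        osc_seeds = osc_root.spawn(len(records))
        fitted = {name: [] for name in ("raw", "g", "h", "eta", "iaw")}
        for name in ("raw", "g", "h", "eta", "iaw"):
            df[f"{name}_true"] = df[name]
        for rec, child in zip(records, osc_seeds):
            rec_id = f"{rec.subject}:{rec.mode}:{rec.stage}"
            with _stage_guard("oscillometry", rec_id):
                pairs = cohort_mod.generate_oscillometry_raw(
                    rec,
                    spec=config.forcing,
                    noise_sd=config.osc_noise_sd,
                    n_reps=config.osc_n_reps,
                    seed=child.generate_state(1)[0],
                    tube=tube,
                )
                fit = fit_recordings(pairs, config.forcing, ztube=tube)
            fits.append(
                {"record": rec_id, **fit.to_dict()}
            )
            fitted["raw"].append(fit.state.raw)
            fitted["g"].append(fit.state.g)
            fitted["h"].append(fit.state.h)
            fitted["eta"].append(fit.state.eta)
            fitted["iaw"].append(fit.state.iaw)
        for name in ("raw", "g", "h", "eta", "iaw"):
            df[name] = fitted[name]
        log.info("oscillometry: %d fits in %.2fs", len(fits), time.perf_counter() - t1)

    with _stage_guard("analyze"):
        analysis = {
            "anova": {o: rm_anova(df, o).to_dict() for o in ANALYSIS_OUTCOMES},
            "pairwise": {
                o: [p.to_dict() for p in pairwise_cells(df, o)]
                for o in ANALYSIS_OUTCOMES
            },
            "relative_changes": {
                o: [r.to_dict() for r in relative_changes(df, o)]
                for o in ANALYSIS_OUTCOMES
            },
        }
    log.info("study complete in %.2fs", time.perf_counter() - t0)

    results = StudyResults(cohort=df, fits=fits, analysis=analysis, warnings=run_warnings)
    if config.outdir is not None:
        results.write(config.outdir)
    return results
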