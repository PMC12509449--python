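"""Crossover repeated-measures analysis.

Two-way fully-within-subject ANOVA (mode x stage) with Mauchly's sphericity
test and Greenhouse-Geisser / Huynh-Feldt corrections, Holm-Sidak step-down
adjustment for the post hoc family, per-subject relative stage changes with
t-based confidence intervals, and Pearson correlation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "FactorResult",
    "AnovaResult",
    "PairwiseResult",
    "RelativeChange",
    "rm_anova",
    "holm_sidak",
    "pairwise_cells",
    "relative_changes",
    "pearson_r",
]


@dataclass(frozen=True)
class FactorResult:
    name: str
    f: float
    df_num: float
    df_den: float
    p: float
    mauchly_w: float
    mauchly_p: float
    eps_gg: float
    eps_hf: float
    p_gg: float
    p_hf: float

    def to_dict(self) -> dict:
        return {
            "F": self.f,
            "df": [self.df_num, self.df_den],
            "p": self.p,
            "mauchly_w": self.mauchly_w,
            "mauchly_p": self.mauchly_p,
            "eps_gg": self.eps_gg,
            "eps_hf": self.eps_hf,
            "p_gg": self.p_gg,
            "p_hf": self.p_hf,
        }


@dataclass(frozen=True)
class AnovaResult:
    outcome: str
    mode: FactorResult
    stage: FactorResult
    interaction: FactorResult
    shapiro_p: float
    brown_forsythe_p: float

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "mode": self.mode.to_dict(),
            "stage": self.stage.to_dict(),
            "interaction": self.interaction.to_dict(),
            "shapiro_p": self.shapiro_p,
            "brown_forsythe_p": self.brown_forsythe_p,
        }


@dataclass(frozen=True)
class PairwiseResult:
    contrast: str
    mean_diff: float
    p_raw: float
    p_adjusted: float
    significant: bool

    def to_dict(self) -> dict:
        return {
            "contrast": self.contrast,
            "mean_diff": self.mean_diff,
            "p_raw": self.p_raw,
            "p_adjusted": self.p_adjusted,
            "significant": self.significant,
        }


@dataclass(frozen=True)
class RelativeChange:
    outcome: str
    mode: str
    contrast: str  # 'cp_vs_start' | 'post_cp_vs_start'
    mean_pct: float
    ci_low: float
    ci_high: float
    n: int

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "mode": self.mode,
            "contrast": self.contrast,
            "mean_pct": self.mean_pct,
            "ci95": [self.ci_low, self.ci_high],
            "n": self.n,
        }


def _pivot(cohort: pd.DataFrame, outcome: str, modes, stages) -> np.ndarray:
    """Subjects x modes x stages array; raises on missing or duplicate cells."""
    subjects = sorted(cohort["subject"].unique())
    y = np.full((len(subjects), len(modes), len(stages)), np.nan)
    for (subj, mode, stage), grp in cohort.groupby(["subject", "mode", "stage"]):
        if len(grp) != 1:
            raise ValueError(f"duplicate cell for subject {subj}, {mode}, {stage}")
        i = subjects.index(subj)
        y[i, modes.index(mode), stages.index(stage)] = grp[outcome].iloc[0]
    if np.any(np.isnan(y)):
        raise ValueError("incomplete within-subject table: missing cells")
    return y


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """k x (k-1) orthonormal contrast matrix (normalized Helmert)."""
    h = np.zeros((k, k - 1))
    for j in range(1, k):
        h[:j, j - 1] = 1.0
        h[j, j - 1] = -j
        h[:, j - 1] /= np.linalg.norm(h[:, j - 1])
    return h


def _sphericity(z: np.ndarray, n: int):
    """Mauchly W/p and GG/HF epsilons from transformed variables z (n x p)."""
    p = z.shape[1]
    if p < 2:
        return 1.0, 1.0, 1.0, 1.0
    s = np.cov(z, rowvar=False, ddof=1)
    s = np.atleast_2d(s)
    tr = np.trace(s)
    if tr <= 0 or not np.all(np.isfinite(s)):
        return 1.0, 1.0, 1.0, 1.0
    eig = np.linalg.eigvalsh(s)
    eig = np.clip(eig, 0.0, np.inf)
    det = float(np.prod(eig))
    w = det / (tr / p) ** p if det > 0 else 0.0
    w = min(w, 1.0)
    if w <= 0:
        mauchly_p = 0.0
    else:
        d = 1.0 - (2.0 * p * p + p + 2.0) / (6.0 * p * (n - 1))
        chi2 = -(n - 1) * d * math.log(w)
        df = p * (p + 1) / 2.0 - 1.0
        mauchly_p = float(sps.chi2.sf(chi2, df))
    eps_gg = float(tr**2 / (p * np.sum(eig**2)))
    eps_gg = min(max(eps_gg, 1.0 / p), 1.0)
    num = n * p * eps_gg - 2.0
    den = p * (n - 1.0 - p * eps_gg)
    eps_hf = min(num / den, 1.0) if den > 0 else 1.0
    eps_hf = max(eps_hf, eps_gg)
    return w, mauchly_p, eps_gg, eps_hf


def _factor_result(name, ss_eff, df_eff, ss_err, df_err, w, mauchly_p, eps_gg, eps_hf):
    if ss_eff <= 1e-300 and ss_err <= 1e-300:
        f = 0.0
        p = p_gg = p_hf = 1.0
    else:
        ms_eff = ss_eff / df_eff
        ms_err = ss_err / df_err
        if ms_err <= 0:
            f = 0.0 if ms_eff <= 0 else math.inf
            p = p_gg = p_hf = 1.0 if f == 0.0 else 0.0
        else:
            f = ms_eff / ms_err
            p = float(sps.f.sf(f, df_eff, df_err))
            p_gg = float(sps.f.sf(f, df_eff * eps_gg, df_err * eps_gg))
            p_hf = float(sps.f.sf(f, df_eff * eps_hf, df_err * eps_hf))
    return FactorResult(
        name=name, f=float(f), df_num=df_eff, df_den=df_err, p=p,
        mauchly_w=float(w), mauchly_p=float(mauchly_p),
        eps_gg=float(eps_gg), eps_hf=float(eps_hf), p_gg=p_gg, p_hf=p_hf,
    )


def rm_anova(
    cohort: pd.DataFrame,
    outcome: str,
    modes: tuple[str, ...] = ("pcv", "vv"),
    stages: tuple[str, ...] = ("start", "cp", "post_cp"),
) -> AnovaResult:
    """Two-way fully repeated-measures ANOVA on one outcome.

    Classical sums-of-squares decomposition with factor-by-subject error
    terms; sphericity diagnostics computed on the stage factor and the
    interaction (the two-level mode factor is spherical by construction).
    """
    y = _pivot(cohort, outcome, list(modes), list(stages))
    n, a, b = y.shape

    grand = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_sa = y.mean(axis=2)
    m_sb = y.mean(axis=1)
    m_ab = y.mean(axis=0)

    ss_a = n * b * np.sum((m_a - grand) ** 2)
    ss_b = n * a * np.sum((m_b - grand) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_s = a * b * np.sum((m_s - grand) ** 2)
    ss_as = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2)
    ss_bs = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2)
    ss_tot = np.sum((y - grand) ** 2)
    ss_abs = max(ss_tot - ss_a - ss_b - ss_ab - ss_s - ss_as - ss_bs, 0.0)

    df_a, df_b = a - 1, b - 1
    df_ab = df_a * df_b
    df_as, df_bs, df_abs = df_a * (n - 1), df_b * (n - 1), df_ab * (n - 1)

    c_a = _orthonormal_contrasts(a)
    c_b = _orthonormal_contrasts(b)
    z_a = y.mean(axis=2) @ c_a
    z_b = y.mean(axis=1) @ c_b
    z_ab = y.reshape(n, a * b) @ np.kron(c_a, c_b)

    res_a = _factor_result("mode", ss_a, df_a, ss_as, df_as, *_sphericity(z_a, n))
    res_b = _factor_result("stage", ss_b, df_b, ss_bs, df_bs, *_sphericity(z_b, n))
    res_ab = _factor_result(
        "interaction", ss_ab, df_ab, ss_abs, df_abs, *_sphericity(z_ab, n)
    )

    # Diagnostics only; they never gate the ANOVA.
    resid = (y - m_ab[None, :, :] - m_s[:, None, None] + grand).ravel()
    if np.ptp(resid) > 0:
        shapiro_p = float(sps.shapiro(resid).pvalue)
    else:
        shapiro_p = 1.0
    cells = [y[:, j, k] for j in range(a) for k in range(b)]
    if all(np.ptp(c) == 0 for c in cells):
        bf_p = 1.0
    else:
        bf_p = float(sps.levene(*cells, center="median").pvalue)

    return AnovaResult(
        outcome=outcome, mode=res_a, stage=res_b, interaction=res_ab,
        shapiro_p=shapiro_p, brown_forsythe_p=bf_p,
    )


def holm_sidak(pvalues) -> np.ndarray:
    """Holm-Sidak step-down adjustment, returned in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.maximum.accumulate(adj_sorted)
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def pairwise_cells(
    cohort: pd.DataFrame,
    outcome: str,
    modes: tuple[str, ...] = ("pcv", "vv"),
    stages: tuple[str, ...] = ("start", "cp", "post_cp"),
    alpha: float = 0.05,
) -> list[PairwiseResult]:
    """Paired-t contrasts between all (mode, stage) cells, Holm-Sidak family."""
    y = _pivot(cohort, outcome, list(modes), list(stages))
    cells = {
        f"{m}:{s}": y[:, j, k]
        for j, m in enumerate(modes)
        for k, s in enumerate(stages)
    }
    labels = list(cells)
    raw, diffs, names = [], [], []
    for la, lb in itertools.combinations(labels, 2):
        d = cells[la] - cells[lb]
        if np.ptp(d) == 0:
            p = 1.0 if np.allclose(d, 0) else 0.0
        else:
            p = float(sps.ttest_rel(cells[la], cells[lb]).pvalue)
        raw.append(p)
        diffs.append(float(d.mean()))
        names.append(f"{la} - {lb}")
    adj = holm_sidak(raw)
    return [
        PairwiseResult(
            contrast=nm, mean_diff=df_, p_raw=pr, p_adjusted=float(pa),
            significant=bool(pa < alpha),
        )
        for nm, df_, pr, pa in zip(names, diffs, raw, adj)
    ]


def relative_changes(
    cohort: pd.DataFrame,
    outcome: str,
    modes: tuple[str, ...] = ("pcv", "vv"),
    baseline: str = "start",
    targets: tuple[str, ...] = ("cp", "post_cp"),
) -> list[RelativeChange]:
    """Per-subject percent change from baseline, mean and t-based 95% CI."""
    stages = (baseline,) + tuple(targets)
    y = _pivot(cohort, outcome, list(modes), list(stages))
    n = y.shape[0]
    if n < 2:
        raise ValueError("relative changes need n >= 2 subjects for a CI")
    out = []
    for j, mode in enumerate(modes):
        base = y[:, j, 0]
        if np.any(base == 0):
            raise ValueError(f"zero baseline value for {outcome!r} under {mode}")
        for k, stage in enumerate(targets, start=1):
            pct = 100.0 * (y[:, j, k] - base) / base
            mean = float(pct.mean())
            sd = float(pct.std(ddof=1))
            half = float(sps.t.ppf(0.975, n - 1)) * sd / math.sqrt(n)
            out.append(
                RelativeChange(
                    outcome=outcome, mode=mode, contrast=f"{stage}_vs_{baseline}",
                    mean_pct=mean, ci_low=mean - half, ci_high=mean + half, n=n,
                )
            )
    return out


def pearson_r(x, y) -> tuple[float, float]:
    """Sample Pearson correlation and two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
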