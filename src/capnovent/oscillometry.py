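"""Multifrequency forced-oscillation workflow.

Synthesis of the pseudorandom forcing signal, spectral estimation of
respiratory input impedance (Zrs = Pao / V'), tube-impedance correction,
ensemble averaging, and fitting of the four-parameter constant-phase model

    Z(w) = Raw + j*w*Iaw + (G - j*H) / w**alpha,   alpha = (2/pi)*atan(H/G)

with w in rad/s (G and H therefore refer to 1 rad/s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import AliasingError, NumericalError, SingularFrequencyError

__all__ = [
    "ForcingSpec",
    "ImpedanceSpectrum",
    "MechanicalState",
    "FitResult",
    "default_frequency_grid",
    "make_forcing_signal",
    "time_grid",
    "estimate_impedance",
    "subtract_tube_impedance",
    "ensemble_average",
    "cpm_impedance",
    "tube_impedance",
    "fit_constant_phase",
    "fit_recordings",
]

#: FFT bin width of the standard 8-s apneic recording window.
BIN_HZ = 0.125

# Bin multiples of 0.125 Hz: 4 (0.5 Hz) and 166 (20.75 Hz) anchor the band,
# the 21 interior values are primes, so no pairwise ratio is an integer.
_DEFAULT_BIN_MULTIPLES: tuple[int, ...] = (
    4, 5, 7, 11, 13, 17, 19, 23, 29, 37, 43, 53,
    61, 71, 79, 89, 101, 113, 127, 139, 151, 163, 166,
)


def default_frequency_grid() -> np.ndarray:
    """The default 23-component frequency grid in Hz (0.5 ... 20.75)."""
    return np.asarray(_DEFAULT_BIN_MULTIPLES, dtype=float) * BIN_HZ


@dataclass(frozen=True)
class ForcingSpec:
    """Specification of the pseudorandom multifrequency forcing signal."""

    f_min: float = 0.5
    f_max: float = 20.75
    n_components: int = 23
    duration: float = 8.0
    sample_rate: float = 256.0
    frequencies: tuple[float, ...] | None = None
    amplitudes: tuple[float, ...] | None = None

    def __post_init__(self):
        freqs = self.frequency_array()
        if len(freqs) != self.n_components:
            raise ValueError(
                f"{len(freqs)} frequencies given but n_components={self.n_components}"
            )
        if freqs.min() < self.f_min - 1e-12 or freqs.max() > self.f_max + 1e-12:
            raise ValueError("component frequencies outside [f_min, f_max]")
        if np.any(np.diff(freqs) <= 0):
            raise ValueError("component frequencies must be strictly ascending")
        ratio = freqs[:, None] / freqs[None, :]
        off_diag = ~np.eye(len(freqs), dtype=bool)
        if np.any(np.abs(ratio[off_diag] - np.round(ratio[off_diag])) < 1e-9):
            raise ValueError("component frequencies must be pairwise non-integer multiples")
        if self.sample_rate < 10.0 * self.f_max:
            raise AliasingError(
                f"sample_rate {self.sample_rate} Hz < 10 * f_max = {10 * self.f_max} Hz"
            )
        if self.amplitudes is not None and len(self.amplitudes) != self.n_components:
            raise ValueError("amplitudes length must equal n_components")

    def frequency_array(self) -> np.ndarray:
        if self.frequencies is None:
            return default_frequency_grid()
        return np.asarray(self.frequencies, dtype=float)

    def amplitude_array(self) -> np.ndarray:
        if self.amplitudes is None:
            return np.full(self.n_components, 0.5)
        return np.asarray(self.amplitudes, dtype=float)

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sample_rate))


@dataclass(frozen=True)
class ImpedanceSpectrum:
    """Complex impedance values (cmH2O.s/L) on an ascending frequency grid."""

    frequencies: np.ndarray
    values: np.ndarray
    ensemble_count: int = 1

    def __post_init__(self):
        f = np.asarray(self.frequencies, dtype=float)
        z = np.asarray(self.values, dtype=complex)
        if f.shape != z.shape:
            raise ValueError("frequencies and values must have the same shape")
        if f.size == 0:
            raise ValueError("empty spectrum")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly ascending")
        if not (np.all(np.isfinite(f)) and np.all(np.isfinite(z))):
            raise ValueError("spectrum contains non-finite values")
        if self.ensemble_count < 1:
            raise ValueError("ensemble_count must be >= 1")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "values", z)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frequency_hz": self.frequencies,
                "z_real": self.values.real,
                "z_imag": self.values.imag,
                "ensemble_count": self.ensemble_count,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ImpedanceSpectrum":
        df = pd.read_csv(path)
        return cls(
            frequencies=df["frequency_hz"].to_numpy(float),
            values=df["z_real"].to_numpy(float) + 1j * df["z_imag"].to_numpy(float),
            ensemble_count=int(df["ensemble_count"].iloc[0]) if "ensemble_count" in df else 1,
        )


@dataclass(frozen=True)
class MechanicalState:
    """Constant-phase parameters of one subject-stage.

    raw : airway resistance, cmH2O.s/L
    iaw : airway inertance, cmH2O.s^2/L
    g   : tissue damping, cmH2O/L (at 1 rad/s)
    h   : tissue elastance, cmH2O/L (at 1 rad/s)
    """

    raw: float
    iaw: float
    g: float
    h: float

    def __post_init__(self):
        if not (self.raw > 0 and self.g > 0 and self.h > 0):
            raise ValueError("raw, g and h must be positive")
        if self.iaw < 0:
            raise ValueError("iaw must be non-negative")

    @property
    def eta(self) -> float:
        """Tissue hysteresivity G/H."""
        return self.g / self.h

    @property
    def alpha(self) -> float:
        """Constant-phase exponent (2/pi)*atan(H/G), in (0, 1)."""
        return (2.0 / math.pi) * math.atan(self.h / self.g)


@dataclass(frozen=True)
class FitResult:
    state: MechanicalState
    cost: float
    se: dict[str, float]
    converged: bool
    iterations: int

    def to_dict(self) -> dict:
        return {
            "raw": self.state.raw,
            "iaw": self.state.iaw,
            "g": self.state.g,
            "h": self.state.h,
            "eta": self.state.eta,
            "alpha": self.state.alpha,
            "cost": self.cost,
            "se": dict(self.se),
            "converged": self.converged,
            "iterations": self.iterations,
        }


def time_grid(spec: ForcingSpec) -> np.ndarray:
    return np.arange(spec.n_samples) / spec.sample_rate


def make_forcing_signal(spec: ForcingSpec, seed: int) -> np.ndarray:
    """Pressure time series: sum of sinusoids with seeded pseudorandom phases."""
    rng = np.random.default_rng(seed)
    phases = rng.uniform(0.0, 2.0 * np.pi, spec.n_components)
    t = time_grid(spec)
    freqs = spec.frequency_array()
    amps = spec.amplitude_array()
    return (amps[:, None] * np.sin(2.0 * np.pi * freqs[:, None] * t[None, :] + phases[:, None])).sum(axis=0)


def _component_bins(spec: ForcingSpec, n: int) -> np.ndarray:
    df = spec.sample_rate / n
    k = spec.frequency_array() / df
    k_round = np.round(k)
    if np.any(np.abs(k - k_round) > 1e-6):
        raise ValueError(
            "series length does not place the component frequencies on FFT bins"
        )
    return k_round.astype(int)


def estimate_impedance(
    pressure: np.ndarray, flow: np.ndarray, spec: ForcingSpec
) -> ImpedanceSpectrum:
    """Zrs at the component frequencies from one apneic recording.

    Uses the cross-spectrum of pressure with flow over the flow auto-spectrum
    on the rectangular (bin-aligned) window, which reduces to P(f)/V'(f).
    """
    pressure = np.asarray(pressure, dtype=float)
    flow = np.asarray(flow, dtype=float)
    if pressure.shape != flow.shape or pressure.ndim != 1:
        raise ValueError("pressure and flow must be 1-D arrays of equal length")
    n = pressure.size
    if n / spec.sample_rate < 1.0 / spec.f_min - 1e-9:
        raise ValueError("series shorter than one period of the lowest component")
    bins = _component_bins(spec, n)
    p_hat = np.fft.rfft(pressure)
    f_hat = np.fft.rfft(flow)
    freqs = spec.frequency_array()
    auto = np.abs(f_hat[bins]) ** 2
    floor = 1e-18 * n * n
    for f, a in zip(freqs, auto):
        if a <= floor:
            raise SingularFrequencyError(float(f))
    cross = p_hat[bins] * np.conj(f_hat[bins])
    return ImpedanceSpectrum(freqs, cross / auto, ensemble_count=1)


def subtract_tube_impedance(
    zrs: ImpedanceSpectrum, ztube: ImpedanceSpectrum
) -> ImpedanceSpectrum:
    if zrs.frequencies.shape != ztube.frequencies.shape or not np.allclose(
        zrs.frequencies, ztube.frequencies, rtol=0, atol=1e-9
    ):
        raise ValueError("frequency grids differ")
    return ImpedanceSpectrum(
        zrs.frequencies, zrs.values - ztube.values, ensemble_count=zrs.ensemble_count
    )


def ensemble_average(spectra: list[ImpedanceSpectrum]) -> ImpedanceSpectrum:
    if len(spectra) == 0:
        raise ValueError("need at least one spectrum to average")
    f0 = spectra[0].frequencies
    for s in spectra[1:]:
        if s.frequencies.shape != f0.shape or not np.allclose(s.frequencies, f0, rtol=0, atol=1e-9):
            raise ValueError("frequency grids differ")
    mean = np.mean([s.values for s in spectra], axis=0)
    return ImpedanceSpectrum(f0, mean, ensemble_count=len(spectra))


def cpm_impedance(mech: MechanicalState, frequencies) -> ImpedanceSpectrum:
    """Constant-phase model spectrum on the given frequency grid (Hz)."""
    f = np.asarray(frequencies, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequencies must be positive")
    omega = 2.0 * np.pi * f
    z = mech.raw + 1j * omega * mech.iaw + (mech.g - 1j * mech.h) / omega ** mech.alpha
    return ImpedanceSpectrum(f, z)


def tube_impedance(
    frequencies, resistance: float = 2.0, inertance: float = 0.01
) -> ImpedanceSpectrum:
    """Series R-I model of the tracheal tube and connecting tubing."""
    f = np.asarray(frequencies, dtype=float)
    return ImpedanceSpectrum(f, resistance + 1j * 2.0 * np.pi * f * inertance)


def _cpm_values(raw, iaw, g, h, omega):
    # Extreme optimizer probes can overflow h/g or omega**alpha; the limits
    # (arctan(inf)=pi/2, x/inf=0) are correct, so the warnings are benign.
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        alpha = (2.0 / np.pi) * np.arctan(h / g)
        return raw + 1j * omega * iaw + (g - 1j * h) / omega ** alpha


def _initial_guess(z: ImpedanceSpectrum) -> np.ndarray:
    # Raw from the high-frequency real part; G, H from the lowest component
    # assuming alpha ~ 0.9; Iaw from the residual high-frequency reactance.
    omega = 2.0 * np.pi * z.frequencies
    w_lo, w_hi = omega[0], omega[-1]
    raw0 = max(0.8 * z.values.real[-1], 1e-2)
    h0 = max(-z.values.imag[0] * w_lo ** 0.9, 1e-1)
    g0 = max((z.values.real[0] - raw0) * w_lo ** 0.9, 1e-1)
    iaw0 = max((z.values.imag[-1] + h0 / w_hi ** 0.9) / w_hi, 1e-4)
    return np.array([raw0, iaw0, g0, h0])


def fit_constant_phase(
    z: ImpedanceSpectrum,
    weights: np.ndarray | None = None,
    n_starts: int = 5,
) -> FitResult:
    """Least-squares constant-phase fit.

    Minimizes sum_f w_f * |Z(f) - Zmodel(f)|^2 over (Raw, Iaw, G, H) in
    log-parameters (positivity by construction), from ``n_starts``
    deterministic starts geometrically spanning 0.1x ... 10x a heuristic
    initial guess.
    """
    if z.frequencies.size < 4:
        raise ValueError("need at least 4 frequencies for 4 free parameters")
    omega = 2.0 * np.pi * z.frequencies
    if weights is None:
        w = np.ones_like(omega)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != omega.shape or np.any(w < 0):
            raise ValueError("weights must be non-negative, one per frequency")
    sw = np.sqrt(w)
    target = z.values

    def residuals(logp):
        with np.errstate(over="ignore"):
            params = np.exp(logp)
        zm = _cpm_values(*params, omega)
        d = zm - target
        return np.concatenate([sw * d.real, sw * d.imag])

    guess = _initial_guess(z)
    scales = np.power(10.0, np.linspace(-1.0, 1.0, max(int(n_starts), 1)))
    best = None
    failures = []
    for s in scales:
        x0 = np.log(guess * s)
        try:
            res = least_squares(residuals, x0, method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception as exc:  # pragma: no cover - scipy internal failure
            failures.append({"scale": s, "error": str(exc)})
            continue
        if res.status <= 0:
            failures.append({"scale": s, "status": res.status, "message": res.message})
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise NumericalError("no optimizer start converged", {"starts": failures})

    params = np.exp(best.x)
    sum_sq = 2.0 * best.cost
    m = 2 * omega.size
    dof = max(m - 4, 1)
    jtj = best.jac.T @ best.jac
    try:
        cov_log = np.linalg.inv(jtj) * (sum_sq / dof)
    except np.linalg.LinAlgError:
        cov_log = np.linalg.pinv(jtj) * (sum_sq / dof)
    se_log = np.sqrt(np.clip(np.diag(cov_log), 0.0, np.inf))
    se = dict(zip(("raw", "iaw", "g", "h"), params * se_log))
    grad_norm = np.linalg.norm(best.jac.T @ best.fun, np.inf)
    converged = bool(grad_norm <= 1e-6 * max(1.0, sum_sq))
    state = MechanicalState(*params)
    return FitResult(state=state, cost=float(sum_sq), se=se, converged=converged, iterations=int(best.nfev))


def fit_recordings(
    recordings: list[tuple[np.ndarray, np.ndarray]],
    spec: ForcingSpec,
    ztube: ImpedanceSpectrum | None = None,
    weighting: str = "zinv",
) -> FitResult:
    """Full estimation pipeline for one condition.

    estimate per recording -> subtract tube -> ensemble average -> fit.
    Measurement noise scales with signal amplitude, so the pipeline default
    weights each frequency by 1/|Z|^2 (relative deviations); pass
    ``weighting="uniform"`` for absolute deviations.
    """
    if len(recordings) == 0:
        raise ValueError("need at least one recording")
    if weighting not in ("zinv", "uniform"):
        raise ValueError("weighting must be 'zinv' or 'uniform'")
    if ztube is None:
        ztube = tube_impedance(spec.frequency_array())
    spectra = [
        subtract_tube_impedance(estimate_impedance(p, v, spec), ztube)
        for p, v in recordings
    ]
    avg = ensemble_average(spectra)
    w = 1.0 / np.abs(avg.values) ** 2 if weighting == "zinv" else None
    return fit_constant_phase(avg, weights=w)
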