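import numpy as np
import pytest

import capnovent as cv


@pytest.fixture(scope="session")
def spec() -> cv.ForcingSpec:
    return cv.ForcingSpec()


@pytest.fixture(scope="session")
def canonical_mech() -> cv.MechanicalState:
    return cv.MechanicalState(raw=25.0, iaw=0.1, g=300.0, h=1500.0)


@pytest.fixture(scope="session")
def synth_flow():
    """Synthesize flow through a known impedance in the frequency domain."""

    def _synth(pressure: np.ndarray, z_values: np.ndarray, spec: cv.ForcingSpec):
        n = pressure.size
        bins = np.round(spec.frequency_array() * n / spec.sample_rate).astype(int)
        p_hat = np.fft.rfft(pressure)
        f_hat = np.zeros_like(p_hat)
        f_hat[bins] = p_hat[bins] / z_values
        return np.fft.irfft(f_hat, n)

    return _synth


@pytest.fixture(scope="session")
def default_cohort():
    from capnovent.cohort import cohort_to_frame, default_config, generate_cohort

    return cohort_to_frame(generate_cohort(default_config(), n_subjects=11, seed=1))
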