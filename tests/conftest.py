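import numpy as np
import pytest

import satflux as sf


@pytest.fixture
def single_lorentzian_config():
    """One noiseless Lorentzian Pi line: height 2, FWHM 20 Hz at +4.9 ppm."""
    return sf.SimulationConfig(
        peaks=(sf.PeakSpec("Pi", 4.9, 2.0, 20.0),), n_points=4000
    )


@pytest.fixture
def muscle_config():
    """Noiseless five-peak resting-muscle spectrum."""
    return sf.SimulationConfig(peaks=tuple(sf.default_muscle_peaks()))


@pytest.fixture
def control_exchange_config():
    """Pi pool with the control-group observables kf=0.304, T1obs=1.59 s."""
    base = {p.label: p for p in sf.default_muscle_peaks()}
    ex = sf.ExchangeSpec.from_observed(m0=base["Pi"].amplitude, t1obs=1.59, kf=0.304)
    return sf.SimulationConfig(exchange={"Pi": ex})


def numerical_fwhm(ppm_axis, intensities, freq_mhz):
    """Interpolated full width at half maximum, in Hz, of the tallest peak."""
    i = int(np.argmax(intensities))
    half = intensities[i] / 2.0
    left = np.flatnonzero(intensities[:i] < half)
    right = i + np.flatnonzero(intensities[i:] < half)
    if left.size == 0 or right.size == 0:
        raise ValueError("peak does not fall to half maximum inside the axis")
    l0 = left[-1]
    r0 = right[0]

    def cross(j, k):
        x0, x1 = ppm_axis[j], ppm_axis[k]
        y0, y1 = intensities[j], intensities[k]
        return x0 + (half - y0) * (x1 - x0) / (y1 - y0)

    return (cross(r0 - 1, r0) - cross(l0, l0 + 1)) * freq_mhz
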