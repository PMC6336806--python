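import numpy as np
import pytest

from vasomet.reconstruct import UniformSeries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def morlet_quadrature(values, fs_hz, scale, t_center, f0=1.0):
    """Independent trapezoid-quadrature evaluation of the wavelet integral.

    Direct numerical integration of s^{-1/2} * int psi((u-t)/s) g(u) du with
    the analytic Morlet psi(u) = pi^{-1/4} exp(i 2 pi f0 u) exp(-u^2/2);
    used as the oracle for the FFT implementation.
    """
    u = np.arange(values.size) / fs_hz
    x = (u - t_center) / scale
    psi = np.pi ** -0.25 * np.exp(1j * 2 * np.pi * f0 * x) * np.exp(-0.5 * x * x)
    return np.trapezoid(psi * values, dx=1.0 / fs_hz) / np.sqrt(scale)


@pytest.fixture
def sinusoid_series():
    def make(freq_hz, fs_hz=1.0, duration_s=1200.0, amplitude=1.0, windows=None):
        t = np.arange(int(duration_s * fs_hz)) / fs_hz
        return UniformSeries(
            fs_hz=fs_hz,
            t0_seconds=0.0,
            values=amplitude * np.sin(2 * np.pi * freq_hz * t),
            windows=windows or {},
        )

    return make
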