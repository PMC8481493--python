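import numpy as np
import pytest

from phytoeis import CircuitParameters, FrequencyGrid, evaluate_impedance


@pytest.fixture
def reference_params() -> CircuitParameters:
    """A suspension circuit with comfortably separated dispersions.

    Corners: w12 ~ 9.8, w23 ~ 392, w34 ~ 3.3e5, w45 ~ 5e5, w56 ~ 1.46e9,
    w67 ~ 5e10 rad/s; k = 2, p = 0.02.
    """
    return CircuitParameters(
        R_s=10.0, R_ct=2.0e4, C_dl=5.0e-6, R_1=500.0, C_1=2.0e-12, R=1000.0, C=2.0e-9
    )


@pytest.fixture
def wide_grid() -> FrequencyGrid:
    """4 Hz - 20 GHz band at 12 points per decade."""
    return FrequencyGrid.log_spaced(4.0, 2.0e10, 12)


@pytest.fixture
def reference_spectrum(reference_params, wide_grid):
    return evaluate_impedance(reference_params, wide_grid)


@pytest.fixture
def extreme_separation_params() -> CircuitParameters:
    """All six corners at least 3 decades apart (k = 1e-3, p = 5e-7)."""
    return CircuitParameters(
        R_s=5.0e-5, R_ct=2.0e5, C_dl=1.0e-2, R_1=100.0, C_1=1.0e-12, R=0.1, C=1.0e-8
    )


def dense_log_omega(w_lo: float, w_hi: float, per_decade: int = 200) -> np.ndarray:
    n = int(np.log10(w_hi / w_lo) * per_decade) + 1
    return np.logspace(np.log10(w_lo), np.log10(w_hi), n)
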