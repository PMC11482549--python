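"""Shared fixtures: ground truth, grids, and cached staged-fit results.

The staged Powell fits are the expensive pieces (tens of seconds); they are
computed once per session and shared by the recovery, TEER and end-to-end
tests.
"""

import pytest

import barrierkit as bk
from barrierkit.eis_fit import staged_calibration


@pytest.fixture(scope="session")
def truth():
    return bk.default_ground_truth()


@pytest.fixture(scope="session")
def grid():
    return bk.default_grid()


@pytest.fixture(scope="session")
def noiseless_staged(truth, grid):
    spectra, t = bk.generate_staged_dataset(
        truth, grid, bk.SpectrumNoiseModel(0.0, 0.0, 0))
    return spectra, t


@pytest.fixture(scope="session")
def noiseless_staged_results(noiseless_staged):
    spectra, _ = noiseless_staged
    return staged_calibration(spectra)


@pytest.fixture(scope="session")
def noisy_staged_seed0(truth, grid):
    spectra, t = bk.generate_staged_dataset(
        truth, grid, bk.SpectrumNoiseModel(0.01, 1.0, 0))
    return spectra, t


@pytest.fixture(scope="session")
def noisy_staged_seed0_results(noisy_staged_seed0):
    spectra, _ = noisy_staged_seed0
    return staged_calibration(spectra)


def relative_error(fitted: float, true: float) -> float:
    return abs(fitted - true) / abs(true)
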