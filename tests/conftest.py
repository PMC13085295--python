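import numpy as np
import pytest

from mixcal.design import load_design_fixture, split_calibration_validation
from mixcal.preprocess import select_window
from mixcal.synthetic import NoiseSpec, generate_pure_spectra, simulate_mixture_spectra


@pytest.fixture(scope="session")
def design():
    return load_design_fixture()


@pytest.fixture(scope="session")
def pure():
    return generate_pure_spectra()


@pytest.fixture(scope="session")
def pure_window(pure):
    return pure.restrict(224.0, 330.0)


@pytest.fixture(scope="session")
def clean_spectra(design, pure):
    return simulate_mixture_spectra(design, pure, None)


@pytest.fixture(scope="session")
def noisy_spectra(design, pure):
    return simulate_mixture_spectra(design, pure, NoiseSpec(sd_frac=0.005, seed=0))


def _split_xy(design, spectra):
    windowed = select_window(spectra)
    roles = design.role_array
    cal, val = split_calibration_validation(design)
    return {
        "X_cal": windowed.absorbance[roles == "calibration"],
        "X_val": windowed.absorbance[roles == "validation"],
        "Y_cal": cal.concentrations,
        "Y_val": val.concentrations,
        "windowed": windowed,
    }


@pytest.fixture(scope="session")
def clean_xy(design, clean_spectra):
    return _split_xy(design, clean_spectra)


@pytest.fixture(scope="session")
def noisy_xy(design, noisy_spectra):
    return _split_xy(design, noisy_spectra)
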