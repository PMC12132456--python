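import numpy as np
import pytest

from cosidex import default_scheme
from cosidex.image_pipeline import CellSpectraMatrix, extract_cell_spectra
from cosidex.reference_library import ReferenceLibrary, ReferenceSpectrum, build_library
from cosidex.spectral_core import Spectrum
from cosidex.synthetic_data import default_fp_panel, model_spectrum, simulate_experiment


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def panel3():
    return default_fp_panel(3)


@pytest.fixture(scope="session")
def model_library(panel3, scheme):
    """Library built directly from the 3-FP panel's model spectra."""
    return ReferenceLibrary(
        references=[
            ReferenceSpectrum(fp_name=fp.name, spectrum=model_spectrum(fp, scheme))
            for fp in panel3
        ]
    )


def extract_experiment(exp):
    """Per-scene CellSpectraMatrix with truth labels attached."""
    return {
        name: extract_cell_spectra(scene.stack, scene.mask, truth_labels=scene.truth)
        for name, scene in zip(exp.scene_names, exp.scenes)
    }


@pytest.fixture(scope="session")
def noisefree_library3(scheme):
    """3-FP reference library built through the full image pipeline at zero noise."""
    exp = simulate_experiment("monoculture", n_fps=3, n_cells=30, noise_sd=0.0, seed=101)
    return build_library(extract_experiment(exp))
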