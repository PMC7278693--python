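import numpy as np
import pytest

from milkcal.simulate import default_scenario, generate_concentrations, generate_spectra


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20200506)


@pytest.fixture(scope="session")
def small_dataset():
    """A 60-sample synthetic fluorescence dataset (fast modality) with its
    reference table — shared by pipeline-level tests."""
    cfg = default_scenario(n_samples=60, seed=11)
    ref = generate_concentrations(cfg)
    ds = generate_spectra(ref, cfg, "sync_fluor")
    return cfg, ref, ds


@pytest.fixture(scope="session")
def nir_dataset():
    cfg = default_scenario(n_samples=120, seed=13)
    ref = generate_concentrations(cfg)
    ds = generate_spectra(ref, cfg, "nir")
    return cfg, ref, ds
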