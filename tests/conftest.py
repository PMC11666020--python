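import warnings

import numpy as np
import pandas as pd
import pytest

import phenogp as pg


@pytest.fixture(autouse=True)
def _quiet():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture(scope="session")
def small_panel():
    """Shared small synthetic panel: genotypes, design, GRM."""
    geno = pg.simulate_genotypes(60, 400, seed=11)
    design = pg.simulate_trial_design(60, n_blocks=4, seed=11)
    return geno, design


@pytest.fixture(scope="session")
def df_dataset(small_panel):
    """Phenotypes for the high-heritability flowering-time trait."""
    geno, design = small_panel
    spec = pg.default_trait_specs()["DF"]
    records, truth = pg.simulate_phenotypes(geno, design, spec, seed=11)
    return geno, design, records, truth


@pytest.fixture(scope="session")
def small_spectra(small_panel):
    geno, design = small_panel
    spec = pg.SpectraSpec(
        n_wavelengths=80,
        wavelength_grid=np.linspace(1000, 2500, 80, endpoint=False),
        target_h2_profile=np.full(80, 0.7),
    )
    spectra, truth = pg.simulate_spectra(geno, design, spec, seed=11)
    return spectra, truth


@pytest.fixture()
def toy_stacked_index():
    genos = [f"G{i}" for i in range(3)]
    return pd.DataFrame(
        {"genotype": genos * 2, "env": ["E1"] * 3 + ["E2"] * 3}
    )
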