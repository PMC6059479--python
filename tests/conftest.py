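import numpy as np
import pandas as pd
import pytest

import chipdecode as cd


@pytest.fixture(scope="session")
def kanmx():
    return cd.KANMX_UP


@pytest.fixture(scope="session")
def ade2():
    return cd.ADE2_5P


@pytest.fixture(scope="session")
def small_screen():
    """A 200-strain, 4-replicate screen with known binders, counts and sheet."""
    config = cd.SimulationConfig(n_strains=200, n_replicates=4, depth=50_000,
                                 dispersion=0.02, frac_binders=0.2,
                                 effect_mean=1.5, effect_sd=0.3, seed=42)
    truth = cd.simulate_library(config, cd.KANMX_UP)
    sheet = cd.design_sample_sheet(config)
    counts = cd.simulate_counts(truth, config, sheet=sheet)
    return config, truth, sheet, counts


def make_read(design, index, barcode, prefix="", suffix=""):
    """Assemble a read laid out per the design (index+anchor+barcode)."""
    return prefix + index + design.constant_region + barcode + suffix


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)
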