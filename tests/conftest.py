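import warnings

import numpy as np
import pandas as pd
import pytest

from histphen.simulate import GeneratorConfig, simulate


@pytest.fixture(autouse=True)
def _quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture(scope="session")
def small_dataset():
    """60 accessions x 6 years, ~4 observed years each, with known truth."""
    cfg = GeneratorConfig(
        n_accessions=60,
        years=tuple(range(2000, 2006)),
        years_observed_per_block=4,
        missingness="mcar",
        seed=42,
    )
    ds, truth = simulate(cfg)
    return ds, truth, cfg


@pytest.fixture(scope="session")
def full_grid_dataset():
    """120 accessions x 8 fully observed years with known truth."""
    cfg = GeneratorConfig(
        n_accessions=120,
        years=tuple(range(1995, 2003)),
        missingness="full",
        seed=7,
    )
    ds, truth = simulate(cfg)
    return ds, truth, cfg


def write_csv(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text)
    return path
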