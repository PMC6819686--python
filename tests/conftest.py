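import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import sgeblup as sg

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")


@pytest.fixture
def trio_pedigree():
    """Two founders and one offspring: the textbook 3x3 example."""
    return sg.make_pedigree([1, 2, 3], [0, 0, 1], [0, 0, 2])


@pytest.fixture
def random_pedigree():
    """A 200-animal random pedigree with some unknown parents and inbreeding."""
    rng = np.random.default_rng(42)
    n = 200
    sire, dam = [0, 0], [0, 0]
    for i in range(3, n + 1):
        sire.append(int(rng.integers(1, i)) if rng.random() < 0.9 else 0)
        dam.append(int(rng.integers(1, i)) if rng.random() < 0.9 else 0)
    return sg.make_pedigree(list(range(1, n + 1)), sire, dam)


@pytest.fixture(scope="session")
def small_dataset():
    """A small but non-trivial simulated dataset shared across tests."""
    cfg = sg.SimulationConfig(
        n_founders=60, n_generations=2, litter_size_range=(3, 6),
        group_size_range=(4, 6), n_batches=3, n_markers=120,
        genotyped_fraction=0.4, seed=20240901,
    )
    return sg.simulate_social_phenotypes(cfg)


@pytest.fixture(scope="session")
def small_design(small_dataset):
    spec = sg.SocialModelSpec()
    return sg.build_design(small_dataset.phenotypes, small_dataset.pedigree, spec), spec


def tiny_two_pen_phenotypes():
    """Six animals in two pens of three; used by dense-oracle MME tests."""
    return pd.DataFrame({
        "animal": [4, 5, 6, 7, 8, 9],
        "adg": [810.0, 777.0, 795.0, 768.0, 802.0, 786.0],
        "batch": ["b1"] * 3 + ["b2"] * 3,
        "sex": ["M"] * 6,
        "pen": [1, 1, 1, 2, 2, 2],
        "litter": [1, 1, 2, 2, 3, 3],
        "age_days": [150.0, 152.0, 148.0, 156.0, 149.0, 151.0],
        "period": [1, 1, 1, 2, 2, 2],
    })


@pytest.fixture
def tiny_model():
    """Pedigree + phenotypes + design for a 9-animal, 2-pen toy problem."""
    ped = sg.make_pedigree(
        [1, 2, 3, 4, 5, 6, 7, 8, 9],
        [0, 0, 0, 1, 1, 3, 3, 1, 3],
        [0, 0, 0, 2, 2, 2, 2, 2, 2],
    )
    ph = tiny_two_pen_phenotypes()
    spec = sg.SocialModelSpec(dilution_enabled=False, fixed_group_size=False,
                              age_covariate=False)
    design = sg.build_design(ph, ped, spec)
    return ped, ph, design, spec
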