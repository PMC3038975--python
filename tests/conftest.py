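import numpy as np
import pandas as pd
import pytest

from ebgs import datasets
from ebgs.io_data import PhenotypeTable, adjust_plot_means
from ebgs.synthetic_data import (
    SimConfig,
    TrueArchitecture,
    simulate_ril_genotypes,
    simulate_trait,
)

from tests.util import toy_marker_map


@pytest.fixture(scope="session")
def soybean_map():
    return datasets.soybean_marker_map()


@pytest.fixture(scope="session")
def tiny_map():
    return toy_marker_map(5)


@pytest.fixture(scope="session")
def small_sim(tiny_map):
    """30 lines x 2 plots on a 5-marker map with one planted main effect."""
    cfg = SimConfig(marker_map=tiny_map, n_lines=30, n_plots=2, seed=11)
    truth = TrueArchitecture(
        beta=5.0,
        main_effects={"M2": 1.0},
        epistatic_effects={},
        plot_effect_sd=0.5,
        resid_sd=1.0,
    )
    geno = simulate_ril_genotypes(cfg)
    pheno = adjust_plot_means(simulate_trait(geno, truth, cfg))
    return geno, pheno, truth


@pytest.fixture(scope="session")
def default_sim():
    """The default simulated world: 126 lines x 3 plots on the 80-marker map."""
    cfg = SimConfig(seed=5)
    ds_geno = simulate_ril_genotypes(cfg)
    from ebgs.synthetic_data import random_architecture

    truth = random_architecture(datasets.soybean_marker_map(), seed=5)
    pheno = adjust_plot_means(simulate_trait(ds_geno, truth, cfg))
    return ds_geno, pheno, truth


@pytest.fixture
def pheno_table():
    def make(lines, plots, values):
        return PhenotypeTable(
            pd.DataFrame(
                {"line_id": lines, "plot_id": plots, "raw_value": values}
            )
        )

    return make
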