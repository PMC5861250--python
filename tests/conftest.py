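import numpy as np
import pytest

import treenbh
from treenbh.experiment import GrowthModelParams

SMALL_PLOTS = {1: 6, 2: 5, 4: 4, 8: 3, 16: 2, 24: 1}


@pytest.fixture(scope="session")
def small_site():
    """A ~21-plot site A simulation shared across tests (seeded)."""
    census, plots, design, truth = treenbh.simulate_site(
        SMALL_PLOTS, site_id="A", seed=11, large_focal_fraction=0.0
    )
    return census, plots, design, truth


@pytest.fixture(scope="session")
def small_dataset(small_site):
    census, plots, _, _ = small_site
    return treenbh.build_focal_dataset(census, plots)


@pytest.fixture(scope="session")
def medium_selection():
    """A selection run on a medium simulation: shared by surface/sign tests."""
    census, plots, design, truth = treenbh.simulate_site(
        {1: 10, 2: 8, 4: 6, 8: 4, 16: 3, 24: 2},
        site_id="A",
        seed=23,
        large_focal_fraction=0.0,
        focal_block=6,
    )
    ds = treenbh.build_focal_dataset(census, plots, index_censuses="all")
    sel = treenbh.select_neighbourhood_model(ds)
    return sel, ds, truth


def noiseless_params(**overrides) -> GrowthModelParams:
    base = dict(
        alpha=2.0,
        beta_logv=0.8,
        beta_nci=-0.2,
        beta_cnd=0.0,
        beta_nsr=0.1,
        beta_logv_nci=0.0,
        beta_logv_nsr=0.0,
        beta_nci_nsr=0.0,
        beta_logv_nci_nsr=0.0,
        sd_species=0.0,
        sd_composition=0.0,
        sd_density=0.0,
        sd_plot=0.0,
        sd_resid=0.0,
    )
    base.update(overrides)
    return GrowthModelParams(**base)
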