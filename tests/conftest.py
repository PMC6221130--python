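import numpy as np
import pytest

import assortmr as am


@pytest.fixture(scope="session")
def small_cross_cfg() -> am.ScenarioConfig:
    """A fast cross-trait assortment scenario for structural checks."""
    return am.ScenarioConfig(
        n_trios=4000, n_snps_x=20, n_snps_y=10, h2_x=0.5, h2_y=0.5,
        p_assort=1.0, n_instrument_snps=10,
        assortment=am.AssortmentSpec("cross_trait", "X", "Y"), seed=42)


@pytest.fixture(scope="session")
def small_trios(small_cross_cfg) -> am.TrioDataset:
    return am.simulate_trios(small_cross_cfg, seed=42)


@pytest.fixture(scope="session")
def random_mating_trios() -> am.TrioDataset:
    cfg = am.ScenarioConfig(n_trios=6000, n_snps_x=20, n_snps_y=10,
                            h2_x=0.5, h2_y=0.1, beta_xy=0.1,
                            n_instrument_snps=20, seed=7)
    return am.simulate_trios(cfg, seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
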