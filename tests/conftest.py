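import numpy as np
import pytest

import irtkit as ik


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def five_item_meta():
    """The five-item illustrative metadata table (mixed models)."""
    return ik.build_item_meta(
        a=[1, 1.2, 0.5, 1.7, 0.7],
        b=[0.2, 2.3, -0.4, -2.5, 0.9],
        g=[np.nan, np.nan, 0.2, 0.1, 0.2],
        item_ids=["ITEM1", "ITEM2", "ITEM3", "ITEM4", "ITEM5"],
        cats=2,
        model=["1PLM", "2PLM", "3PLM", "3PLM", "DRM"],
    )


@pytest.fixture
def random_3pl_meta(rng):
    """12 random 3PLM items with moderate parameters."""
    return ik.build_item_meta(
        a=rng.uniform(0.6, 2.0, 12),
        b=rng.normal(0.0, 1.0, 12),
        g=rng.uniform(0.05, 0.3, 12),
        model="3PLM",
    )


@pytest.fixture(scope="session")
def simdat30():
    """Session-cached 2000 x 30 complete 3PLM response fixture."""
    return ik.fixture_simdat30(seed=1)


@pytest.fixture(scope="session")
def simdat30_3pl_fit(simdat30):
    """Session-cached 3PLM calibration of the 30-item fixture (g ~ beta(5,16))."""
    control = ik.EMControl(D=1.702)
    gprior = ik.PriorSpec("beta", (5.0, 16.0), "g")
    return ik.estimate_mmle_em(simdat30.data, "3PLM", 2, control, [gprior])


@pytest.fixture(scope="session")
def simdat60():
    """Session-cached 50-operational + 10-pretest fixture with missingness."""
    return ik.fixture_simdat60(seed=1)
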