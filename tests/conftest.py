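import numpy as np
import pandas as pd
import pytest

import icetariff as it


@pytest.fixture(scope="session")
def o_sample():
    """Synthetic ICECAP-O sample at the study's sample size (n=516)."""
    cfg = it.default_config("ICECAP-O", n=516, seed=20260101)
    return it.generate_dataset(cfg)


@pytest.fixture(scope="session")
def a_sample():
    """Synthetic ICECAP-A sample at the study's sample size (n=1373)."""
    cfg = it.default_config("ICECAP-A", n=1373, seed=20260102)
    return it.generate_dataset(cfg)


@pytest.fixture(scope="session")
def o_design(o_sample):
    return it.build_design(o_sample, it.ICECAP_O, include_ses=True)


@pytest.fixture(scope="session")
def exact_design(o_sample):
    """Design whose response is exactly linear in the columns (no noise)."""
    design = it.build_design(o_sample, it.ICECAP_O, include_ses=False)
    rng = np.random.default_rng(42)
    beta = rng.uniform(-0.2, 0.0, size=design.X.shape[1])
    beta[0] = 0.9
    design.y = pd.Series(design.X.to_numpy() @ beta, name="swb")
    return design, beta
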