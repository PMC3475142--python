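import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=50)
settings.load_profile("suite")

SEED = 20260930


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)


@pytest.fixture(scope="session")
def marker():
    from linkpower import MarkerModel

    return MarkerModel()


@pytest.fixture(scope="session")
def h0_asp_replicates():
    """20k H0 replicates of 500 ASPs: NPL and KC-LOD per replicate.

    Session-shared by the null-calibration checks.
    """
    import linkpower as lp

    return lp.run_replicates(
        lp.SampleSpec.homogeneous("ASP", 500),
        "H0",
        None,
        ["npl", "kclod"],
        20_000,
        seed=SEED,
    )
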