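import numpy as np
import pandas as pd
import pytest

from mri2synaptic import NetworkConfig, PhantomParams, make_phantom
from mri2synaptic.phantom import default_effects


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture(scope="session")
def small_params():
    return PhantomParams(shape=(40, 40, 40), voxel_size=(2.0, 2.0, 2.0), seed=11)


@pytest.fixture(scope="session")
def effects():
    return default_effects()


@pytest.fixture(scope="session")
def hc_case(small_params, effects):
    return make_phantom(small_params, effects["HC"], dose=15.0, case_id="sub-001")


@pytest.fixture(scope="session")
def ad_case(small_params, effects):
    return make_phantom(small_params, effects["AD"], dose=15.0, case_id="sub-001")


@pytest.fixture(scope="session")
def tiny_net_cfg():
    """A small mirrored ladder for fast forward/backward checks."""
    return NetworkConfig(encoder_filters=(2, 4), decoder_filters=(4, 2), init_seed=3)


def synthetic_manifest(n, ratio, n_low, seed):
    """Manifest-only cohort table (no volumes) for fold-design tests."""
    rng = np.random.default_rng(seed)
    diags = [d for d, c in sorted(ratio.items()) for _ in range(c)]
    rng.shuffle(diags)
    ids = [f"sub-{i + 1:03d}" for i in range(n)]
    low = set(rng.choice(ids, size=n_low, replace=False)) if n_low else set()
    return pd.DataFrame(
        {
            "id": ids,
            "diagnosis": diags,
            "dose_mCi": [3.0 if i in low else 15.0 for i in ids],
            "low_dose": [i in low for i in ids],
        }
    )
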