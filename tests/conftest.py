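import numpy as np
import pytest

from fedglioma.network import PRESETS, init_params
from fedglioma.preprocess import SliceDataset, preprocess_cohort
from fedglioma.synthetic import SiteSpec, generate_site, split_patients


@pytest.fixture(scope="session")
def small_site_scans():
    """One deterministic 3/3-patient site at 32^3 resolution."""
    spec = SiteSpec(site_id="fix", n_class0=3, n_class1=3, seed=77)
    return generate_site(spec)


@pytest.fixture(scope="session")
def small_slice_dataset(small_site_scans) -> SliceDataset:
    return preprocess_cohort(small_site_scans, out_size=32)


@pytest.fixture(scope="session")
def two_client_data():
    """Two tiny clients with train/test splits, 32x32 slices."""
    clients, tests = {}, {}
    for i, sid in enumerate(("a", "b")):
        scans = generate_site(SiteSpec(site_id=sid, n_class0=3, n_class1=3,
                                       seed=50 + i))
        tr, te = split_patients(scans, 2 / 3, seed=5)
        clients[sid] = preprocess_cohort(tr, out_size=32)
        tests[sid] = preprocess_cohort(te, out_size=32)
    return clients, tests


@pytest.fixture(scope="session")
def micro_config():
    return PRESETS["micro"]


@pytest.fixture(scope="session")
def micro_params(micro_config):
    """Micro network with parameters nudged off the zero-bias kinks so
    finite-difference checks are well posed."""
    params = init_params(micro_config, seed=3)
    rng = np.random.default_rng(42)
    for k in params:
        params[k] = params[k] + 0.05 * rng.standard_normal(params[k].shape)
    return params
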