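import warnings

import numpy as np
import pytest

from rsldecode import (
    FeatureNormMatrix,
    build_cosine_rsm,
    make_fold_plan,
    make_synthetic_ephys,
    svd_embed,
)
from rsldecode.simulate import make_synthetic_norms


@pytest.fixture(autouse=True)
def _quiet_convergence_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="FISTA did not converge")
        warnings.filterwarnings("ignore", message=".*constant feature column.*")
        yield


@pytest.fixture(scope="session")
def norms() -> FeatureNormMatrix:
    """100-item synthetic feature norms (50 animate / 50 inanimate)."""
    return make_synthetic_norms(seed=0)


@pytest.fixture(scope="session")
def rsm(norms):
    return build_cosine_rsm(norms)


@pytest.fixture(scope="session")
def embedding(norms, rsm):
    """Rank-3 target embedding of the synthetic norms."""
    return svd_embed(rsm, 3, domains=norms.domains)


@pytest.fixture(scope="session")
def fold_plan(embedding):
    return make_fold_plan(embedding.item_ids, embedding.domains, k_outer=10, seed=0)


@pytest.fixture(scope="session")
def ephys(embedding):
    """Planted-signal voltage fixture at the default study condition."""
    return make_synthetic_ephys(embedding, snr=4.0, seed=1)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
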