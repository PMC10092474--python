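from pathlib import Path

import numpy as np
import pytest
from scipy.special import ndtr

from icdscreen.instruments import load_instrument, reference_resource

REPO_ROOT = Path(__file__).resolve().parents[1]


@pytest.fixture(scope="session")
def idq_spec():
    return load_instrument("idq")


@pytest.fixture(scope="session")
def iaq_spec():
    return load_instrument("iaq")


@pytest.fixture(scope="session")
def reference():
    return reference_resource()


@pytest.fixture(scope="session")
def idq_params(reference):
    blk = reference["idq"]["params_2pl"]
    return np.asarray(blk["a"]), np.asarray(blk["b"])


@pytest.fixture(scope="session")
def iaq_params(reference):
    blk = reference["iaq"]["params_2pl"]
    return np.asarray(blk["a"]), np.asarray(blk["b"])


@pytest.fixture(scope="session")
def fixture_cohort_path():
    return REPO_ROOT / "data" / "cohort_n500_synthetic.csv"


def simulate_binary(a, b, n, seed):
    """Direct 2PL Bernoulli sampler used as simulation input in IRT tests."""
    rng = np.random.default_rng(seed)
    theta = rng.standard_normal(n)
    p = ndtr(np.asarray(a)[None, :] * (theta[:, None] - np.asarray(b)[None, :]))
    return (rng.random(p.shape) < p).astype(int)
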