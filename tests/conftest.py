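import numpy as np
import pytest

import rverdict as rv
from rverdict.evaluation import PCA_OPERATING_POINT


@pytest.fixture(scope="session")
def scheme():
    return rv.innovate_scheme()


@pytest.fixture(scope="session")
def pca_point():
    return PCA_OPERATING_POINT


@pytest.fixture(scope="session")
def trained_dnn(scheme):
    """Session-wide rVERDICT network, trained once at the study SNR.

    Scaled for suite runtime (smaller training set than the package
    default); the acceptance script trains at full scale.
    """
    ts = rv.sample_training_set(rv.DEFAULT_RANGES, scheme, 40_000, snr=35.0, seed=101)
    hyper = rv.DnnHyperparams(epochs=60)
    return rv.train(ts, hyper, seed=101)


@pytest.fixture(scope="session")
def noiseless_dnn(scheme):
    """Estimator trained on noiseless signals (pure model inversion)."""
    ts = rv.sample_training_set(rv.DEFAULT_RANGES, scheme, 40_000, snr=np.inf, seed=303)
    return rv.train(ts, rv.DnnHyperparams(hidden=(128, 128, 128), epochs=150), seed=303)


@pytest.fixture(scope="session")
def trained_verdict_dnn(scheme):
    """Session-wide classic-VERDICT network (3 outputs)."""
    sig, tgt = rv.sample_verdict_training_set(
        rv.DEFAULT_RANGES, scheme, 40_000, snr=35.0, seed=202
    )
    r = rv.DEFAULT_RANGES
    lo = np.array([r.f0_ic[0], r.f0_ees[0], r.r[0]])
    hi = np.array([r.f0_ic[1], r.f0_ees[1], r.r[1]])
    return rv.train_verdict(sig, tgt, scheme, (lo, hi), rv.DnnHyperparams(epochs=60), seed=202)
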