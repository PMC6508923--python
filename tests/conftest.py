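import warnings

import numpy as np
import pytest

from thighseg.phantom import PhantomSpec, make_phantom

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free default phantom (96x96x50 @ 1.5 mm)."""
    return make_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def noisy_phantom():
    """5%-noise phantom, seed 1."""
    return make_phantom(PhantomSpec(noise_sigma=0.05, seed=1))


def dice(pred: np.ndarray, truth: np.ndarray) -> float:
    pred = np.asarray(pred) > 0
    truth = np.asarray(truth) > 0
    tp = np.count_nonzero(pred & truth)
    denom = pred.sum() + truth.sum()
    return 2.0 * tp / denom if denom else 1.0
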