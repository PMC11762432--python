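import numpy as np
import pytest

from hierattn import (
    EligibilityConfig,
    SyntheticConfig,
    build_default_schema,
    generate_cohort,
    tensorize_cohort,
)


@pytest.fixture(scope="session")
def schema():
    return build_default_schema()


@pytest.fixture(scope="session")
def small_cohort(schema):
    """A small but fully-featured synthetic cohort shared across tests."""
    cfg = SyntheticConfig(n_patients=400, seed=5)
    events, statics, truth = generate_cohort(cfg, schema)
    return events, statics, truth, cfg


@pytest.fixture(scope="session")
def small_tensor(schema, small_cohort):
    events, statics, _, _ = small_cohort
    tensor, labels, report = tensorize_cohort(
        events, statics, schema, EligibilityConfig())
    return tensor, labels, report


def random_masked_batch(rng, n, t, v, n_static=2, missing=0.3, dtype=np.float32):
    """Random doubly-masked batch with right-aligned histories."""
    x = rng.standard_normal((n, t, v)).astype(dtype)
    mt = np.zeros((n, t), dtype=dtype)
    for i in range(n):
        h = rng.integers(1, t + 1)
        mt[i, t - h:] = 1.0
    mv = (rng.random((n, t, v)) > missing).astype(dtype) * mt[:, :, None]
    x *= mv
    s = rng.standard_normal((n, n_static)).astype(dtype)
    return x, mv, mt, s
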