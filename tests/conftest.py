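import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")

from tfminet import (
    GrnSpec,
    TFNetworkModel,
    generate_grn,
    synthetic_annotation,
    truth_tf_list,
)

#: benchmark architecture used for recovery checks: 10 hubs x 5 targets,
#: three two-step cascades, 50 background genes, 200 samples, noise 0.3
BENCH_SPEC = GrnSpec(
    n_tf_hubs=10,
    targets_per_hub=5,
    n_paralog_groups=0,
    paralog_group_size=0,
    n_cascades=3,
    n_background=50,
    n_samples=200,
    link="mixed",
    noise_sd=0.3,
    seed=11,
)


@pytest.fixture(scope="session")
def bench_grn():
    return generate_grn(BENCH_SPEC)


@pytest.fixture(scope="session")
def bench_fit(bench_grn):
    matrix, truth = bench_grn
    model = TFNetworkModel(
        matrix, truth_tf_list(truth), synthetic_annotation(truth), mode="full"
    )
    return model.fit(dpi_epsilons=(0.0, 0.1, 0.2), n_permutations=2000, seed=5), truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
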