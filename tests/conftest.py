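import numpy as np
import pytest

import rdklearn as rk


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A scaled-down simulated cohort shared across runner/analysis tests.

    Two V and two AV observers, 4 training days of 80 trials, 80 post-test
    trials per location; one group has a nonzero abort rate so abort
    bookkeeping is exercised.
    """
    cfg = rk.ProtocolConfig(
        trials_per_training_session=80,
        training_days=4,
        posttest_trials_per_location=80,
        master_seed=2024,
        groups=[
            rk.GroupConfig(label="V", size=2, abort_prob=0.05),
            rk.GroupConfig(
                label="AV",
                size=2,
                av_cue=True,
                transfer_h=0.0,
                learn_rate_h_mean=12.0,
                learn_rate_v_mean=6.0,
            ),
        ],
    )
    trials, summary = rk.run_cohort(cfg)
    return cfg, trials, summary
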