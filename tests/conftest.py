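import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import tlcausal as tl


@pytest.fixture
def discrete_toy():
    """Confounded cohort with two binary covariates (4 strata), all strata
    containing both arms. Used for saturated-fit / g-computation checks."""
    rng = np.random.default_rng(5)
    n = 300
    w1 = rng.binomial(1, 0.5, n)
    w2 = rng.binomial(1, 0.4, n)
    a = rng.binomial(1, expit(-0.5 + w1 + 0.5 * w2))
    y = rng.binomial(1, expit(-1 + 0.8 * a + 0.6 * w1 - 0.4 * w2))
    return tl.Cohort(y=y, a=a, w=pd.DataFrame({"w1": w1, "w2": w2}))


@pytest.fixture
def hand_toy():
    """12-subject cohort over 3 strata whose stratified risk difference is
    1/3 by hand arithmetic (see test_tmle for the worked numbers)."""
    rows = [
        # stratum (0,0): ybar1=1/2, ybar0=1/2, diff 0
        (0, 0, 0, 0), (1, 0, 0, 0), (0, 1, 0, 0), (1, 1, 0, 0),
        # stratum (0,1): ybar1=2/3, ybar0=0, diff 2/3
        (0, 0, 0, 1), (1, 1, 0, 1), (1, 1, 0, 1), (0, 1, 0, 1),
        # stratum (1,0): ybar1=1, ybar0=2/3, diff 1/3
        (1, 0, 1, 0), (1, 0, 1, 0), (0, 0, 1, 0), (1, 1, 1, 0),
    ]
    y, a, w1, w2 = (np.array(col) for col in zip(*rows))
    return tl.Cohort(y=y, a=a, w=pd.DataFrame({"w1": w1, "w2": w2}))


@pytest.fixture
def small_run_config():
    """Fast configuration: single-learner libraries, few folds."""
    return tl.RunConfig(
        outcome_library=("logistic",), ps_library=("logistic",), v_folds=5, seed=7
    )


@pytest.fixture
def cohort_csv(tmp_path):
    """Write a cohort DataFrame to CSV and return the path."""

    def _write(df: pd.DataFrame, name: str = "cohort.csv"):
        path = tmp_path / name
        df.to_csv(path, index=False)
        return path

    return _write
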