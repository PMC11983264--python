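import numpy as np
import pandas as pd
import pytest

from survbenefit import TrialData, make_scenario


def trial_from_arrays(time, event, arm, cov=None, ids=None):
    n = len(time)
    if cov is None:
        cov = pd.DataFrame({"x": np.linspace(0.0, 1.0, n)})
    return TrialData(
        ids=np.array([str(i) for i in range(n)]) if ids is None else np.asarray(ids, dtype=str),
        time=np.asarray(time, dtype=float),
        event=np.asarray(event, dtype=int),
        arm=np.asarray(arm, dtype=int),
        covariates=cov,
    )


@pytest.fixture(scope="session")
def default_trial():
    """One frozen draw from the calibrated generator, shared across tests."""
    return make_scenario("paper_default", seed=20240)


@pytest.fixture
def tiny_trial():
    return trial_from_arrays(
        time=[2.0, 0.5, 1.0, 3.0, 1.5, 2.5],
        event=[1, 0, 1, 1, 0, 1],
        arm=[1, 0, 1, 0, 1, 0],
    )
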