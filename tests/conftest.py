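import numpy as np
import pandas as pd
import pytest

from numconf.cohort import COHORT_PARAM_PRESETS
from numconf.ddm import DDMParams, drift_for_distance, simulate_batch
from numconf.design import CORE_DIGIT_PAIRS, build_design, log_distance


@pytest.fixture(scope="session")
def exp1_design():
    return build_design("exp1")


@pytest.fixture(scope="session")
def exp1_distances():
    return [log_distance(a, b) for a, b in CORE_DIGIT_PAIRS]


@pytest.fixture(scope="session")
def positive_params():
    m = COHORT_PARAM_PRESETS["exp1"]["positive"]["mean"]
    return DDMParams(**m, un=2.5)


@pytest.fixture(scope="session")
def simulated_trials(positive_params, exp1_distances):
    """A 720-trial dataset simulated at the reference positive-numeral
    parameters; shared by likelihood and property tests."""
    rng = np.random.default_rng(42)
    frames = []
    for d in exp1_distances:
        v = drift_for_distance(positive_params, d)
        b = simulate_batch(v, positive_params, 72, rng)
        ok = b["choice"] != 0
        frames.append(
            pd.DataFrame(
                {
                    "rt": b["rt"][ok],
                    "correct": b["choice"][ok] == 1,
                    "log_distance": d,
                    "dv_mean": b["dv_mean"][ok],
                    "n_steps": b["n_steps"][ok],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
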