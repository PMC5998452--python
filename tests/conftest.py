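import numpy as np
import pytest

import stageflow as sf

# truth generator for recovery/coverage simulations: every arrow carries
# enough expected events over two 13-week intervals to be identifiable
RECOVERY_RATES = {
    "q12": 0.035, "q13": 0.03, "q14": 0.02,
    "q21": 0.035, "q23": 0.035, "q24": 0.02,
    "q31": 0.03, "q32": 0.03, "q34": 0.035,
}
RECOVERY_INIT = (0.34, 0.33, 0.33, 0.0)


@pytest.fixture(scope="session")
def recovery_Q():
    return sf.IntensityMatrix.from_rates(RECOVERY_RATES)


@pytest.fixture(scope="session")
def reference_fixtures():
    return sf.make_reference_fixtures()


@pytest.fixture(scope="session")
def study_curves():
    """Weekly model prevalence per arm from the study-like generators,
    started at the observed week-0 stage distributions."""
    qs = sf.study_like_intensities()
    inits = {"HE": (67, 24, 0, 0), "BA": (31, 12, 0, 0), "MI": (69, 14, 4, 0)}
    return {
        g: sf.model_prevalence(qs[g], np.asarray(inits[g], float) / sum(inits[g]))
        for g in qs
    }


def random_intensity(rng, scale=0.2):
    """Random valid generator with all nine arrows."""
    rates = {}
    for l in (1, 2, 3):
        for k in (1, 2, 3, 4):
            if l != k:
                rates[f"q{l}{k}"] = float(rng.uniform(0.01, scale))
    return sf.IntensityMatrix.from_rates(rates)
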