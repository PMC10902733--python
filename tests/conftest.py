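import numpy as np
import pandas as pd
import pytest

import hfrmrp as h


@pytest.fixture(scope="session")
def frame():
    return h.build_strata_frame()


@pytest.fixture(scope="session")
def default_cfg():
    return h.SyntheticConfig()


@pytest.fixture(scope="session")
def truth(default_cfg, frame):
    return h.generate_truth_surface(default_cfg, frame)


@pytest.fixture(scope="session")
def pop(default_cfg, frame):
    return h.generate_population(default_cfg, frame)


@pytest.fixture(scope="session")
def suicides(truth, pop, default_cfg):
    return h.simulate_suicide_counts(truth, pop, default_cfg)


@pytest.fixture(scope="session")
def microdata(truth, pop, default_cfg):
    return h.simulate_survey_microdata(truth, pop, default_cfg)


def tiny_frame(n_states=3, urban_free=("ZF",)):
    """A reduced strata frame over a synthetic state list (fast tests)."""
    codes = ["ZA", "ZB", "ZC", "ZD", "ZE", "ZF"][:n_states]
    meta = pd.DataFrame(
        {"state_code": codes, "has_urban_county": [0 if c in urban_free else 1 for c in codes]}
    )
    return h.build_strata_frame(meta)


@pytest.fixture
def posterior_degenerate(frame):
    """A 'posterior' whose draws are all equal to a fixed surface (no MC noise)."""
    years = tuple(range(1990, 1993))
    rng = np.random.default_rng(5)
    surface = rng.uniform(0.1, 0.7, size=(len(frame), len(years)))
    draws = np.repeat(surface[None], 8, axis=0)
    return h.HFRPosterior(frame=frame, years=years, draws=draws)
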