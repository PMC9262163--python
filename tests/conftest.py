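import logging

import numpy as np
import pandas as pd
import pytest

from capsoc.interactions import MembershipIndex
from capsoc.simulate import (
    SimConfig,
    simulate_integration_estimates,
    simulate_population,
    simulate_survival,
)

logging.getLogger("capsoc").setLevel(logging.ERROR)


def ts(s: str) -> pd.Timestamp:
    return pd.Timestamp(s)


@pytest.fixture(scope="session")
def toy_population():
    """Three individuals: two lifelong residents of group A and one that
    joins A mid-2010; one immature female maturing mid-study."""
    individuals = pd.DataFrame(
        {
            "id": ["F1", "F2", "M1", "Y1"],
            "sex": ["F", "F", "M", "F"],
            "birth_date": [ts("1998-01-01"), ts("2000-06-15"), ts("1999-03-01"),
                           ts("2007-07-01")],
        }
    )
    membership = pd.DataFrame(
        {
            "id": ["F1", "F2", "M1", "Y1"],
            "group": ["A", "A", "A", "A"],
            "entry": [ts("2009-01-01"), ts("2009-01-01"), ts("2010-07-01"),
                      ts("2009-01-01")],
            "exit": [ts("2014-12-31")] * 4,
        }
    )
    return individuals, membership, MembershipIndex(membership)


@pytest.fixture(scope="session")
def small_survival_data():
    """A small simulated study with beta_social=0.5 plus truth-derived
    integration estimates; shared across survival-model tests."""
    cfg = SimConfig(n_groups=6, females_per_group=6, years=10, seed=42)
    rng = np.random.default_rng(cfg.seed)
    ind, mem, truth = simulate_population(cfg, rng)
    pop = simulate_survival(ind, mem, truth, cfg, rng)
    est = simulate_integration_estimates(pop, cfg, rng)
    return pop, est, cfg
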