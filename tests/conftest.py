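import logging
import warnings

import numpy as np
import pandas as pd
import pytest

from cartsurv.cohort import Cutoff, apply_exclusions, dichotomize, label_three_year
from cartsurv.synthetic import (
    TREE_MARKERS,
    fig1_profile,
    generate_cohort,
    paper2015_profile,
)

logging.getLogger("cartsurv").setLevel(logging.ERROR)
warnings.filterwarnings("ignore", message="n_perm")


@pytest.fixture(scope="session")
def paper_cohort():
    """paper2015-profile cohort used across screening tests."""
    return generate_cohort(paper2015_profile(n_patients=500, seed=1234))


@pytest.fixture(scope="session")
def fig1_cohort():
    """Unadjusted fig1-profile cohort (class-structured hazards)."""
    return generate_cohort(fig1_profile(n_patients=1000, seed=1234))


@pytest.fixture
def default_cutoffs():
    return {m: Cutoff(m, "intensity", 2) for m in TREE_MARKERS}


def tree_inputs(cohort, cutoffs):
    """Dichotomized tree features + survival arrays after survival
    exclusions (shared helper for classifier-level tests)."""
    surv, _ = apply_exclusions(cohort, "survival",
                               required=tuple(cutoffs.values()))
    feats = pd.DataFrame(
        {m: dichotomize(surv.df[cutoffs[m].column], cutoffs[m])
         for m in cutoffs},
        index=surv.df.index)
    times = surv.df["os_months"].to_numpy(dtype=float)
    events = surv.df["event"].to_numpy(dtype=float)
    labels = label_three_year(times, events)
    return surv, feats, times, events, labels


@pytest.fixture
def exp_cohort_factory():
    """Plain exponential survival data without any covariate structure."""

    def make(n, rate=0.02, censor=0.0, seed=0):
        rng = np.random.default_rng(seed)
        t = rng.exponential(1.0 / rate, n)
        if censor > 0:
            c = rng.exponential(1.0 / censor, n)
            return np.minimum(t, c), (t <= c).astype(float)
        return t, np.ones(n)

    return make
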