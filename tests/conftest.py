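import numpy as np
import pytest

from chickenlearn.hier import SamplerConfig, fit_hierarchical
from chickenlearn.models import get_model
from chickenlearn.task import CohortSpec, generate_cohort, make_design


@pytest.fixture(scope="session")
def study1():
    return make_design("study1")


@pytest.fixture(scope="session")
def study2():
    return make_design("study2")


@pytest.fixture(scope="session")
def small_cohort(study1):
    """8 reward-learning agents in the blocked design (sessions, truth)."""
    spec = CohortSpec.from_natural_means(
        8,
        study1,
        get_model("M1-2"),
        {"alpha_h": 0.32, "alpha_l": 0.20, "beta": 2.0},
        seed=101,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    """A quick converged-ish hierarchical fit reused by structural tests."""
    sessions, _ = small_cohort
    return fit_hierarchical(
        "M1-2", sessions, config=SamplerConfig(chains=2, warmup=200, draws=200), seed=7
    )


def random_paramset(model_name, rng):
    """Random in-range natural parameters for any bank model."""
    from chickenlearn.models import ParamSet

    model = get_model(model_name)
    vals = {}
    for p in model.free_params:
        if p == "theta":
            vals[p] = float(rng.normal(0, 0.8))
        elif p == "beta":
            vals[p] = float(rng.uniform(0.2, 6.0))
        else:
            vals[p] = float(rng.uniform(0.05, 0.95))
    return ParamSet.from_dict(vals)
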