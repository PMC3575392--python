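import numpy as np
import pytest

from rxagsp.io import ExpressionCohort


def make_cohort(values, genes=None, samples=None, time=None, event=None, cohort_id="c"):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return ExpressionCohort(
        cohort_id=cohort_id, genes=list(genes), samples=list(samples),
        values=values, time=time, event=event,
    )


@pytest.fixture
def cohort_factory():
    return make_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_survival(rng, n, hazard=0.1, censor=0.05):
    t_event = rng.exponential(1.0 / hazard, size=n)
    t_cens = rng.exponential(1.0 / censor, size=n)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return time, event
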