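import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from behavclust.trajectories import StatusMatrix

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=60)
settings.load_profile("ci")


def status_matrix(values, start="2017-01", men=None, indicators=None) -> StatusMatrix:
    """Build a StatusMatrix from a nested list (men x indicators x months);
    None entries become missing."""
    arr = np.array(
        [[[np.nan if x is None else float(x) for x in row] for row in man]
         for man in values]
    )
    n, v, _ = arr.shape
    return StatusMatrix(
        arr,
        men or [f"m{i}" for i in range(n)],
        indicators or [f"v{j}" for j in range(v)],
        pd.Period(start, freq="M"),
    )


def random_status_matrix(rng, n_men=None, n_ind=None, n_months=None) -> StatusMatrix:
    n = n_men or rng.integers(2, 7)
    v = n_ind or rng.integers(1, 4)
    t = n_months or rng.integers(2, 9)
    vals = rng.choice([0.0, 1.0, np.nan], size=(n, v, t), p=[0.35, 0.35, 0.3])
    return StatusMatrix(
        vals, [f"m{i}" for i in range(n)], [f"v{j}" for j in range(v)],
        pd.Period("2017-01", freq="M"),
    )


@pytest.fixture(scope="session")
def demo_cohort():
    """One small demonstration cohort shared across tests (visits, truth,
    first-visit features, spec)."""
    from behavclust import simulate

    spec = simulate.demo_cohort_spec(n_men=150, seed=11)
    visits, truth = simulate.generate_cohort(spec)
    first = simulate.generate_first_visit_features(spec, truth, visits)
    return spec, visits, truth, first
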