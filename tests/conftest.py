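import numpy as np
import pytest

from edgedyn import NodalTimeSeries, RssSeries, SyntheticSpec, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_series(rng):
    """Small random nodal series, 100 timepoints x 5 nodes."""
    return NodalTimeSeries(
        rng.normal(size=(100, 5)) * 2 + 1,
        tr_seconds=0.72,
        node_labels=[f"n{i}" for i in range(5)],
    )


def make_rss(values, tr=1.0):
    return RssSeries(values=np.asarray(values, float), tr_seconds=tr, n_edges=1)


@pytest.fixture
def small_cohort():
    """Tiny two-group cohort for pipeline plumbing tests."""
    spec = SyntheticSpec(
        n_nodes=10,
        n_timepoints=120,
        group_sizes={"A": 2, "B": 2},
        seed=42,
    )
    subjects, table = simulate_cohort(spec)
    return spec, subjects, table
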