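import numpy as np
import pytest
from hypothesis import settings

from alchemcycle import DhdlSeries, TransformationRun

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def make_series():
    """Factory for small DhdlSeries with chosen samples/interval/groups."""

    def _make(samples, interval=0.5, lam=0.5, groups=None, first_time=None):
        return DhdlSeries(
            lambda_value=lam,
            samples=np.asarray(samples, dtype=float),
            sample_interval=interval,
            first_time=first_time,
            group_samples=groups,
        )

    return _make


@pytest.fixture
def make_run(make_series):
    """Factory for a TransformationRun with per-λ constant means.

    ``mean_of_lambda`` maps λ to the constant sample value at that λ-point.
    """

    def _make(
        mean_of_lambda,
        lambdas=np.linspace(0, 1, 11),
        n_samples=4,
        groups_of_lambda=None,
        **kwargs,
    ):
        series = []
        for lam in lambdas:
            groups = None
            if groups_of_lambda is not None:
                groups = {
                    name: np.full(n_samples, val)
                    for name, val in groups_of_lambda(lam).items()
                }
                total = np.sum(list(groups.values()), axis=0)
            else:
                total = np.full(n_samples, mean_of_lambda(lam))
            series.append(make_series(total, lam=lam, groups=groups))
        defaults = dict(
            state_from="A",
            state_to="B",
            environment="solvent",
            direction_tag="forward",
            replicate_id="r1",
        )
        defaults.update(kwargs)
        return TransformationRun(series=series, **defaults)

    return _make
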