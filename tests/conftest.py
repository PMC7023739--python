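import numpy as np
import pytest

from posttermclinic.service_distributions import (
    ACTIVITY_KEYS,
    SERVICE_ACTIVITIES,
    ServiceTimeSummary,
    fit_all,
    fit_bounded_service_distribution,
    fit_ctg_check_count_distribution,
    load_service_summaries,
)

#: elicited activity means (minutes) used throughout the deterministic oracles
TABLE_MEANS = {
    "check_in": 0.457,
    "connect_ctg": 3.410,
    "ctg_scan": 26.250,
    "disconnect_ctg": 3.410,
    "consultation": 22.325,
    "check_out": 1.589,
}
ZERO_CONTENTION_LOS = sum(TABLE_MEANS.values())  # 57.441


@pytest.fixture(scope="session")
def summaries():
    return load_service_summaries()


@pytest.fixture(scope="session")
def fitted(summaries):
    return fit_all(summaries)


def make_point_mass_dists(n_checks: int = 2):
    """Every service a point mass at its elicited mean; fixed check count."""
    dists = {}
    for key in SERVICE_ACTIVITIES:
        v = TABLE_MEANS[key]
        dists[key] = fit_bounded_service_distribution(
            ServiceTimeSummary(key, v, v, v, v, 0.0)
        )
    dists["n_ctg_checks"] = fit_ctg_check_count_distribution(
        ServiceTimeSummary("n_ctg_checks", n_checks, n_checks, n_checks, n_checks, 0.0)
    )
    return dists


@pytest.fixture
def point_mass_dists():
    return make_point_mass_dists()


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
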