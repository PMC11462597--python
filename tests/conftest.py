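import numpy as np
import pytest
from scipy import stats as _stats

from spataft import (
    AdjacencyGraph,
    CohortTable,
    FactorSpec,
    SimulationScenario,
    SurvivalRecord,
    grid_queen_adjacency,
    simulate_cohort,
)


def scipy_oracle(family, eta, rho):
    """Independent parameterisation of the three AFT baselines through
    scipy's frozen distributions: Weibull(shape 1/rho, scale e^eta),
    lognormal(s=rho, scale e^eta), log-logistic = Fisk(c=1/rho, scale e^eta)."""
    if family == "weibull":
        return _stats.weibull_min(c=1 / rho, scale=np.exp(eta))
    if family == "lognormal":
        return _stats.lognorm(s=rho, scale=np.exp(eta))
    return _stats.fisk(c=1 / rho, scale=np.exp(eta))


def make_cohort(times, events, regions=None, covariates=None, factors=None):
    """Hand-build a small cohort; covariates is {name: list-of-values}."""
    n = len(times)
    regions = regions or ["r0"] * n
    covariates = covariates or {}
    records = tuple(
        SurvivalRecord(
            time=float(times[i]),
            event=int(events[i]),
            region_id=str(regions[i]),
            covariates={k: v[i] for k, v in covariates.items()},
        )
        for i in range(n)
    )
    table = CohortTable(records=records)
    if factors:
        from spataft import encode_design

        table = encode_design(table, factors)
    return table


# Printed registry mortality counts (alive, died) per level, used by the
# descriptive worked examples.
TABLE2_COUNTS = {
    "overall": {"Overall": (4691, 8278)},
    "sex": {"Male": (2351, 4949), "Female": (2340, 3329)},
    "age": {
        "< 60": (950, 1337),
        "60-69": (1498, 2373),
        "70-79": (1727, 2890),
        ">= 80": (516, 1678),
    },
    "histology": {"NSCLC": (4389, 7029), "SCLC": (302, 1249)},
    "stage": {
        "Stage I": (1310, 449),
        "Stage II": (555, 455),
        "Stage III": (782, 1255),
        "Stage IV": (1072, 4782),
        "Not stated": (972, 1337),
    },
    "ecog": {
        "Good": (2818, 3924),
        "Poor": (322, 1570),
        "Not stated": (1551, 2784),
    },
    "smoking": {
        "Ever": (3821, 7266),
        "Never": (775, 742),
        "Not stated": (95, 270),
    },
}


def cohort_from_counts(level_counts):
    """Expand {level: (alive, died)} into a cohort with arbitrary times."""
    times, events, values = [], [], []
    for level, (alive, died) in level_counts.items():
        times += [12.0] * (alive + died)
        events += [0] * alive + [1] * died
        values += [level] * (alive + died)
    return make_cohort(times, events, covariates={"factor": values})


@pytest.fixture(scope="session")
def grid_8x10():
    return grid_queen_adjacency(8, 10)


@pytest.fixture(scope="session")
def small_spatial_cohort(grid_8x10):
    """n=3040 spatial log-logistic cohort with two binary covariates."""
    scenario = SimulationScenario(
        graph=grid_8x10,
        n_per_region=np.array([38] * 80),
        beta=np.array([0.5, -0.5]),
        mu=3.0,
        rho=1.0,
        family="loglogistic",
        tau2=0.2,
        censor_fraction=0.3,
        covariate_mix={"a": {"x": 0.5, "y": 0.5}, "b": {"u": 0.5, "v": 0.5}},
        reference_levels={"a": "x", "b": "u"},
        seed=7,
    )
    cohort, W = simulate_cohort(scenario)
    return cohort, W, scenario


@pytest.fixture
def tiny_weibull_cohort():
    """5-record mixed event/censor fixture used by likelihood oracles."""
    return make_cohort(
        times=[2.0, 5.5, 1.2, 9.0, 3.3],
        events=[1, 0, 1, 1, 0],
    )


@pytest.fixture(scope="session")
def path_graph_3():
    return AdjacencyGraph(
        region_ids=("A", "B", "C"), neighbors=((1,), (0, 2), (1,))
    )


@pytest.fixture(scope="session")
def two_region_graph():
    return AdjacencyGraph(region_ids=("L", "R"), neighbors=((1,), (0,)))
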