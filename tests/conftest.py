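import numpy as np
import pytest

from cyclenoise import (
    BurstModel,
    ModelSpec,
    PartitionModel,
    RegulationProfile,
    calibrate_rate,
    make_cell_cycle,
    make_strategy,
)


@pytest.fixture
def fig1_cycle():
    """20 equal-rate stages, 2 h mean cycle."""
    return make_cell_cycle(20, 2.0)


@pytest.fixture
def fig1_model(fig1_cycle):
    """Constant unit burst rate, geometric bursts of mean 4, binomial split."""
    return ModelSpec(
        cycle=fig1_cycle,
        regulation=make_strategy("constant", 1.0, fig1_cycle),
        burst=BurstModel.geometric1(4.0),
        partition=PartitionModel.from_alpha(1.0),
    )


@pytest.fixture
def fig1_calibrated(fig1_model):
    """Same model rescaled to a steady-state mean of 150 molecules."""
    return calibrate_rate(fig1_model, 150.0)


def random_model(
    rng: np.random.Generator,
    n: int | None = None,
    burst: BurstModel | None = None,
    alpha: float | None = None,
) -> ModelSpec:
    """A random small model: n in 2..8, log-uniform stage rates, random
    non-negative burst-rate profile (at least one stage active)."""
    if n is None:
        n = int(rng.integers(2, 9))
    lambdas = tuple(np.exp(rng.uniform(np.log(0.5), np.log(20.0), n)))
    ks = rng.uniform(0.0, 10.0, n)
    ks[int(rng.integers(n))] += 1.0  # guarantee a non-zero profile
    if burst is None:
        kind = rng.integers(3)
        if kind == 0:
            burst = BurstModel.deterministic(int(rng.integers(1, 6)))
        elif kind == 1:
            burst = BurstModel.geometric0(float(rng.uniform(0.5, 8.0)))
        else:
            burst = BurstModel.geometric1(float(rng.uniform(1.0, 8.0)))
    if alpha is None:
        alpha = float(rng.choice([0.0, 0.5, 1.0, 2.0]))
    return ModelSpec(
        cycle=make_cell_cycle(n, lambdas=lambdas),
        regulation=RegulationProfile(tuple(ks)),
        burst=burst,
        partition=PartitionModel.from_alpha(alpha),
    )


# --- independent oracles (direct double-loop transcriptions; kept free of
# --- any package internals so they can arbitrate against the fast paths)


def oracle_mean(model: ModelSpec) -> float:
    """Steady-state mean via the raw double sums."""
    lam = model.cycle.lambdas
    ks = model.regulation.ks
    n = model.cycle.n
    big = sum(
        ks[j] / (lam[i] * lam[j]) for i in range(n) for j in range(n)
    )
    tri = sum(
        ks[j] / (lam[i] * lam[j]) for i in range(n) for j in range(i + 1)
    )
    L = sum(1.0 / lam[j] for j in range(n))
    return model.burst.mean_b / L * (big + tri)


def oracle_beta(model: ModelSpec) -> float:
    """Regulation parameter via the raw double sums."""
    lam = model.cycle.lambdas
    ks = model.regulation.ks
    n = model.cycle.n
    num = sum(ks[j] / (lam[i] * lam[j]) for i in range(n) for j in range(n))
    den = sum(ks[j] / (lam[i] * lam[j]) for i in range(n) for j in range(i + 1))
    return num / den


def oracle_xc(model: ModelSpec) -> np.ndarray:
    """Per-stage steady-state <x c_i> via the explicit recursive solution."""
    lam = model.cycle.lambdas
    ks = model.regulation.ks
    n = model.cycle.n
    L = sum(1.0 / lam[j] for j in range(n))
    S = sum(ks[j] / lam[j] for j in range(n))
    out = []
    for i in range(n):
        Si = sum(ks[j] / lam[j] for j in range(i + 1))
        out.append(model.burst.mean_b / lam[i] * (S + Si) / L)
    return np.asarray(out)


def oracle_eta(model: ModelSpec) -> float:
    """Closed-form noise, assembled from the oracle mean and beta."""
    b = oracle_beta(model)
    mean = oracle_mean(model)
    ratio = model.burst.second_moment_b / model.burst.mean_b
    alpha = model.partition.alpha
    return (
        (1.0 / 3.0 + (2.0 / 3.0) / (1.0 + b)) * ratio
        + (2.0 * alpha / 3.0) * b / (1.0 + b)
    ) / mean
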