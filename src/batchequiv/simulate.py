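"""Two-level lognormal simulation of unit-level quality-attribute measurements.

Each product j (reference R, test T) has a population parameter value TVP_j;
the reference is fixed at 1 and the test at ``tr_ratio / 100``. Batch means
are drawn multiplicatively around the population value,

    P_jk = TVP_j * exp(eta_IBV),    eta_IBV ~ N(0, omega2_ibv),

and unit values multiplicatively around their batch mean,

    P_ijk = P_jk * exp(eta_ABV),    eta_ABV ~ N(0, omega2_abv).

The log-scale variances are defined directly from the percent coefficients of
variation as omega² = (CV/100)²; for CV <= 20 % this differs from the exact
lognormal relation ln(1 + (CV/100)²) by under 2 %.

Reproducibility: experiment ``i`` of a scenario under master seed ``s`` is a
pure function of ``(s, scenario, i)``. Child seeds are derived with
``numpy.random.SeedSequence(s, spawn_key=(*scenario.spawn_key(), i, stream))``
where stream 0 feeds data generation and stream 1 the bootstrap, so simulation
and inference noise are decoupled and experiments can be regenerated (or run
in parallel) individually. Within an experiment the draw order is fixed:
reference batch means, reference unit noise (row-major), then the same for
the test product; each product consumes exactly N_B + N_B*N_U normal variates
regardless of the variance values (zero variance yields exactly constant
output).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

from .grid import Scenario

__all__ = [
    "ProductParams",
    "SimulatedExperiment",
    "cv_to_omega2",
    "simulate_experiment",
    "simulate_one",
    "simulate_many",
    "iter_experiments",
    "experiment_rng",
    "bootstrap_rng",
    "experiment_to_tidy",
]

DATA_STREAM = 0
BOOTSTRAP_STREAM = 1


@dataclass(frozen=True)
class ProductParams:
    """Population parameters of one product: TVP and log-scale variances."""

    tvp: float
    omega2_ibv: float
    omega2_abv: float

    def __post_init__(self) -> None:
        if self.tvp <= 0:
            raise ValueError(f"tvp must be > 0, got {self.tvp}")
        if self.omega2_ibv < 0 or self.omega2_abv < 0:
            raise ValueError("variance components must be >= 0")


@dataclass(frozen=True)
class SimulatedExperiment:
    """Unit-level values for both products of one simulated experiment.

    ``ref_values`` and ``test_values`` have shape (n_batches, n_units); row k
    holds the units of batch k, which share one batch-level factor.
    ``seed_state`` identifies the random stream that produced the experiment
    (master seed and experiment index), or ``None`` for ad-hoc generation.
    """

    ref_values: np.ndarray
    test_values: np.ndarray
    scenario: Scenario
    seed_state: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        expected = (self.scenario.n_batches, self.scenario.n_units)
        for name, arr in (("ref_values", self.ref_values), ("test_values", self.test_values)):
            if arr.shape != expected:
                raise ValueError(f"{name} has shape {arr.shape}, expected {expected}")
            if not np.all(arr > 0):
                raise ValueError(f"{name} must be strictly positive")


def cv_to_omega2(cv: float) -> float:
    """Log-scale variance from a percent CV: omega² = (CV/100)².

    This is the defining relation of the simulation model, not the lognormal
    moment relation (see :func:`batchequiv.widening.cv_to_sigma_total` for
    that one).
    """
    if cv < 0:
        raise ValueError(f"cv must be >= 0, got {cv}")
    return (cv / 100.0) ** 2


def _product_params(scenario: Scenario) -> tuple[ProductParams, ProductParams]:
    o_ibv = cv_to_omega2(scenario.ibv_cv)
    o_abv = cv_to_omega2(scenario.abv_cv)
    ref = ProductParams(tvp=1.0, omega2_ibv=o_ibv, omega2_abv=o_abv)
    test = ProductParams(tvp=scenario.tr_ratio / 100.0, omega2_ibv=o_ibv, omega2_abv=o_abv)
    return ref, test


def _draw_product(params: ProductParams, n_batches: int, n_units: int,
                  rng: np.random.Generator) -> np.ndarray:
    batch_means = params.tvp * np.exp(
        rng.normal(0.0, np.sqrt(params.omega2_ibv), size=n_batches)
    )
    unit_noise = np.exp(rng.normal(0.0, np.sqrt(params.omega2_abv), size=(n_batches, n_units)))
    return batch_means[:, None] * unit_noise


def simulate_experiment(scenario: Scenario, rng: np.random.Generator,
                        seed_state: tuple[int, int] | None = None) -> SimulatedExperiment:
    """Draw one experiment: both products, independent streams of the same rng.

    Reference is drawn before test; within each product, batch means before
    unit noise. Even a single batch (N_B = 1) draws its own batch-level
    factor, so the batch mean differs from TVP whenever IBV > 0.
    """
    ref_p, test_p = _product_params(scenario)
    ref = _draw_product(ref_p, scenario.n_batches, scenario.n_units, rng)
    test = _draw_product(test_p, scenario.n_batches, scenario.n_units, rng)
    return SimulatedExperiment(ref_values=ref, test_values=test,
                               scenario=scenario, seed_state=seed_state)


def experiment_rng(seed: int, scenario: Scenario, index: int) -> np.random.Generator:
    """Data-generation stream for experiment ``index`` of ``scenario``."""
    ss = np.random.SeedSequence(seed, spawn_key=(*scenario.spawn_key(), index, DATA_STREAM))
    return np.random.Generator(np.random.PCG64(ss))


def bootstrap_rng(seed: int, scenario: Scenario, index: int) -> np.random.Generator:
    """Bootstrap stream for experiment ``index``, independent of its data stream."""
    ss = np.random.SeedSequence(seed, spawn_key=(*scenario.spawn_key(), index, BOOTSTRAP_STREAM))
    return np.random.Generator(np.random.PCG64(ss))


def simulate_one(scenario: Scenario, seed: int, index: int) -> SimulatedExperiment:
    """Regenerate experiment ``index`` without generating its predecessors."""
    return simulate_experiment(scenario, experiment_rng(seed, scenario, index),
                               seed_state=(seed, index))


def iter_experiments(scenario: Scenario, n_experiments: int, seed: int
                     ) -> Iterator[SimulatedExperiment]:
    if n_experiments < 1:
        raise ValueError("n_experiments must be >= 1")
    for i in range(n_experiments):
        yield simulate_one(scenario, seed, i)


def simulate_many(scenario: Scenario, n_experiments: int, seed: int
                  ) -> list[SimulatedExperiment]:
    """``n_experiments`` independent experiments; element i equals simulate_one(..., i)."""
    return list(iter_experiments(scenario, n_experiments, seed))


def experiment_to_tidy(experiment: SimulatedExperiment) -> pd.DataFrame:
    """Long-format table with columns product, batch, unit, value.

    Batches and units are 1-based; products are labelled ``reference`` and
    ``test``. The format round-trips through the real-data entry point of the
    bootstrap module.
    """
    nb, nu = experiment.ref_values.shape
    frames = []
    for product, values in (("reference", experiment.ref_values),
                            ("test", experiment.test_values)):
        batch, unit = np.divmod(np.arange(nb * nu), nu)
        frames.append(pd.DataFrame({
            "product": product,
            "batch": batch + 1,
            "unit": unit + 1,
            "value": values.ravel(),
        }))
    return pd.concat(frames, ignore_index=True)
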