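"""Monte-Carlo power: probability of declaring similarity per scenario.

For each scenario, many experiments are simulated, each is tested with the
percentile-bootstrap equivalence procedure, and the probability of similarity
is the fraction of experiments whose 90 % CI falls inside the acceptance
range. The reference depth is 1000 experiments x 10,000 bootstraps per
scenario; a reduced depth (e.g. 300 x 1000) reproduces probabilities within
binomial Monte-Carlo error and is the default for interactive use and tests.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .bootstrap import DEFAULT_LIMITS, bootstrap_gmr_ci
from .grid import Scenario
from .simulate import bootstrap_rng, simulate_one

__all__ = [
    "PowerEstimate",
    "Recommendation",
    "estimate_power",
    "run_grid",
    "estimates_to_frame",
    "recommend_sample_size",
]

logger = logging.getLogger(__name__)

LONG_COLUMNS = [
    "tr_ratio", "n_batches", "n_units", "ibv_cv", "abv_cv",
    "n_experiments", "n_bootstrap", "n_passed", "probability", "mc_halfwidth",
]


@dataclass(frozen=True)
class PowerEstimate:
    """Estimated probability of similarity for one scenario.

    ``mc_halfwidth`` is the binomial 95 % half-width 1.96*sqrt(p(1-p)/n),
    reported for transparency about Monte-Carlo error.
    """

    scenario: Scenario
    n_experiments: int
    n_bootstrap: int
    n_passed: int
    probability: float
    mc_halfwidth: float

    ci_lowers: tuple[float, ...] | None = None
    ci_uppers: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.n_passed <= self.n_experiments:
            raise ValueError("n_passed must be in [0, n_experiments]")


@dataclass(frozen=True)
class Recommendation:
    """Minimal design achieving the power target for a variability condition."""

    tr_ratio: float
    ibv_cv: float
    abv_cv: float
    n_batches: int
    n_units: int
    achieved_power: float
    power_target: float
    feasible: bool


def _mc_halfwidth(p: float, n: int) -> float:
    return 1.96 * math.sqrt(p * (1.0 - p) / n)


def estimate_power(
    scenario: Scenario,
    n_experiments: int = 300,
    n_bootstrap: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    strategy: str = "stratified",
    limits: tuple[float, float] = DEFAULT_LIMITS,
    keep_ci_bounds: bool = False,
) -> PowerEstimate:
    """Simulate, bootstrap and score ``n_experiments`` experiments.

    Deterministic given ``seed``: experiment i and its bootstrap use
    independent child streams of (seed, scenario, i), so the result is
    identical whether experiments run serially or in parallel, and any single
    experiment can be replayed in isolation.

    Set ``keep_ci_bounds`` to retain the per-experiment CI bounds (used for
    the CI-distribution plots).
    """
    if n_experiments < 1:
        raise ValueError("n_experiments must be >= 1")
    n_passed = 0
    lowers: list[float] = []
    uppers: list[float] = []
    for i in range(n_experiments):
        experiment = simulate_one(scenario, seed, i)
        result = bootstrap_gmr_ci(
            experiment,
            n_bootstrap=n_bootstrap,
            alpha=alpha,
            strategy=strategy,
            rng=bootstrap_rng(seed, scenario, i),
            limits=limits,
        )
        n_passed += result.passed
        if keep_ci_bounds:
            lowers.append(result.ci_lower)
            uppers.append(result.ci_upper)
    p = n_passed / n_experiments
    return PowerEstimate(
        scenario=scenario,
        n_experiments=n_experiments,
        n_bootstrap=n_bootstrap,
        n_passed=n_passed,
        probability=p,
        mc_halfwidth=_mc_halfwidth(p, n_experiments),
        ci_lowers=tuple(lowers) if keep_ci_bounds else None,
        ci_uppers=tuple(uppers) if keep_ci_bounds else None,
    )


def _estimate_row(scenario: Scenario, n_experiments, n_bootstrap, seed,
                  alpha, strategy, limits) -> dict:
    est = estimate_power(scenario, n_experiments, n_bootstrap, seed,
                         alpha=alpha, strategy=strategy, limits=limits)
    return {
        "tr_ratio": scenario.tr_ratio,
        "n_batches": scenario.n_batches,
        "n_units": scenario.n_units,
        "ibv_cv": scenario.ibv_cv,
        "abv_cv": scenario.abv_cv,
        "n_experiments": est.n_experiments,
        "n_bootstrap": est.n_bootstrap,
        "n_passed": est.n_passed,
        "probability": est.probability,
        "mc_halfwidth": est.mc_halfwidth,
    }


def _scenario_from_row(row) -> Scenario:
    return Scenario(row["tr_ratio"], int(row["n_batches"]), int(row["n_units"]),
                    row["ibv_cv"], row["abv_cv"])


def run_grid(
    scenarios: Sequence[Scenario],
    n_experiments: int = 300,
    n_bootstrap: int = 1000,
    seed: int = 0,
    workers: int = 1,
    alpha: float = 0.05,
    strategy: str = "stratified",
    limits: tuple[float, float] = DEFAULT_LIMITS,
    checkpoint: str | Path | None = None,
    resume: bool = False,
) -> list[PowerEstimate]:
    """One power estimate per scenario, in input order.

    Because every scenario's randomness is keyed to (seed, scenario), the
    worker count cannot change the numbers. With ``checkpoint`` set, finished
    rows are appended to a long-format CSV as they complete, and ``resume``
    skips scenarios already present in that file, so an interrupted sweep
    picks up where it left off.
    """
    scenarios = list(scenarios)
    if not scenarios:
        raise ValueError("scenario collection must be non-empty")

    done: dict[tuple, dict] = {}
    checkpoint = Path(checkpoint) if checkpoint is not None else None
    if checkpoint is not None and checkpoint.exists():
        if resume:
            prior = pd.read_csv(checkpoint)
            for _, row in prior.iterrows():
                done[_scenario_from_row(row).spawn_key()] = row[LONG_COLUMNS].to_dict()
            logger.info("resuming: %d of %d scenarios already done", len(done), len(scenarios))
        else:
            checkpoint.unlink()

    todo = [s for s in scenarios if s.spawn_key() not in done]
    args = dict(n_experiments=n_experiments, n_bootstrap=n_bootstrap, seed=seed,
                alpha=alpha, strategy=strategy, limits=limits)

    def _record(scenario: Scenario, row: dict) -> None:
        done[scenario.spawn_key()] = row
        if checkpoint is not None:
            header = not checkpoint.exists()
            pd.DataFrame([row], columns=LONG_COLUMNS).to_csv(
                checkpoint, mode="a", header=header, index=False)

    if workers > 1 and len(todo) > 1:
        from joblib import Parallel, delayed
        rows = Parallel(n_jobs=workers)(delayed(_estimate_row)(s, **args) for s in todo)
        for scenario, row in zip(todo, rows):
            _record(scenario, row)
    else:
        for k, scenario in enumerate(todo):
            try:
                row = _estimate_row(scenario, **args)
            except Exception:
                logger.exception("scenario %s failed; continuing", scenario)
                continue
            _record(scenario, row)
            if (k + 1) % 25 == 0 or k + 1 == len(todo):
                logger.info("grid progress: %d/%d scenarios", k + 1, len(todo))

    estimates = []
    for scenario in scenarios:
        row = done.get(scenario.spawn_key())
        if row is None:
            continue
        estimates.append(PowerEstimate(
            scenario=scenario,
            n_experiments=int(row["n_experiments"]),
            n_bootstrap=int(row["n_bootstrap"]),
            n_passed=int(row["n_passed"]),
            probability=float(row["probability"]),
            mc_halfwidth=float(row["mc_halfwidth"]),
        ))
    return estimates


def estimates_to_frame(estimates: Iterable[PowerEstimate]) -> pd.DataFrame:
    """Long-format table of power estimates (one row per scenario)."""
    rows = []
    for est in estimates:
        s = est.scenario
        rows.append({
            "tr_ratio": s.tr_ratio, "n_batches": s.n_batches, "n_units": s.n_units,
            "ibv_cv": s.ibv_cv, "abv_cv": s.abv_cv,
            "n_experiments": est.n_experiments, "n_bootstrap": est.n_bootstrap,
            "n_passed": est.n_passed, "probability": est.probability,
            "mc_halfwidth": est.mc_halfwidth,
        })
    return pd.DataFrame(rows, columns=LONG_COLUMNS)


def recommend_sample_size(
    tr_ratio: float,
    ibv_cv: float,
    abv_cv: float,
    power_target: float = 0.80,
    grid_results: Iterable[PowerEstimate] = (),
    prefer: str = "total",
) -> Recommendation:
    """Smallest design in ``grid_results`` meeting the power target.

    Among designs with probability >= ``power_target`` at the queried
    (tr_ratio, ibv_cv, abv_cv), picks the minimiser of total observations
    N_B*N_U, ties broken by fewer batches (``prefer="total"``). With
    ``prefer="batches"`` designs are ranked by fewer batches first — useful
    when inter-batch variability dominates and batches are the scarce
    resource. If no design qualifies, the best-powered design is returned
    with ``feasible=False``.
    """
    if prefer not in ("total", "batches"):
        raise ValueError(f"prefer must be 'total' or 'batches', got {prefer!r}")
    matches = [e for e in grid_results
               if e.scenario.tr_ratio == tr_ratio
               and e.scenario.ibv_cv == ibv_cv
               and e.scenario.abv_cv == abv_cv]
    if not matches:
        raise LookupError(
            f"no grid results for tr_ratio={tr_ratio}, ibv_cv={ibv_cv}, abv_cv={abv_cv}")

    def rank(e: PowerEstimate):
        s = e.scenario
        if prefer == "total":
            return (s.n_total, s.n_batches)
        return (s.n_batches, s.n_total)

    qualifying = [e for e in matches if e.probability >= power_target]
    if qualifying:
        best = min(qualifying, key=rank)
        feasible = True
    else:
        best = max(matches, key=lambda e: e.probability)
        feasible = False
    return Recommendation(
        tr_ratio=tr_ratio, ibv_cv=ibv_cv, abv_cv=abv_cv,
        n_batches=best.scenario.n_batches, n_units=best.scenario.n_units,
        achieved_power=best.probability, power_target=power_target,
        feasible=feasible,
    )
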