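"""Percentile-bootstrap equivalence test on the geometric mean ratio.

The equivalence statistic is the geometric mean ratio (GMR)

    theta = exp( mean(log test units) - mean(log reference units) ),

with all units of a product pooled. A non-parametric bootstrap resamples each
product independently with replacement; the 90 % percentile confidence
interval is the interval between the 100*alpha and 100*(1-alpha) empirical
quantiles (alpha = 0.05) of the resampled GMRs, computed by linear
interpolation of order statistics (the "type 7" convention, numpy's default).
Similarity is concluded when the whole interval lies inside the acceptance
range, by default 90.00-111.11 % (0.9 to 1/0.9, symmetric on the log scale).

Three resampling strategies are provided:

``stratified`` (default)
    Keep the batches fixed and redraw N_U units with replacement within each
    batch of a product. The bootstrap distribution then reflects within-batch
    (measurement) variability; batch effects move the observed GMR but not
    the interval width. This is the scheme that reproduces published power
    surfaces for multi-batch designs.
``flat``
    Pool the N_B * N_U units of a product and redraw that many with
    replacement. Reflects the total (inter- plus intra-batch) variability.
``hierarchical``
    Redraw N_B batches with replacement, then N_U units with replacement
    within each drawn batch. Respects the clustering of units in batches but
    is very conservative for few batches and degenerate at N_B = 1, where all
    three strategies coincide.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .simulate import SimulatedExperiment

__all__ = [
    "DEFAULT_LIMITS",
    "EquivalenceResult",
    "geometric_mean_ratio",
    "equivalence_decision",
    "bootstrap_gmr_ci",
    "read_tidy",
    "format_limits_percent",
]

#: Default acceptance range: +/-10 % on the ratio scale, i.e. (0.9, 1/0.9).
#: The upper limit is carried at full precision, displayed as 111.11 %.
DEFAULT_LIMITS: tuple[float, float] = (0.9, 1.0 / 0.9)


@dataclass(frozen=True)
class EquivalenceResult:
    """Observed GMR, its percentile-bootstrap CI and the equivalence verdict."""

    gmr_observed: float
    ci_lower: float
    ci_upper: float
    passed: bool
    limits: tuple[float, float]
    n_bootstrap: int
    alpha: float = 0.05
    strategy: str = "stratified"

    def __post_init__(self) -> None:
        if not (0 < self.ci_lower <= self.ci_upper):
            raise ValueError("require 0 < ci_lower <= ci_upper")

    def to_json(self, seed=None) -> str:
        payload = {
            "gmr": self.gmr_observed,
            "ci_lower": self.ci_lower,
            "ci_upper": self.ci_upper,
            "passed": self.passed,
            "limits": list(self.limits),
            "n_bootstrap": self.n_bootstrap,
            "alpha": self.alpha,
            "strategy": self.strategy,
            "seed": seed,
        }
        return json.dumps(payload, indent=2)


def _validated_log(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError(f"{name} must be non-empty")
    if not np.all(arr > 0):
        raise ValueError(f"{name} must be strictly positive (geometric mean undefined)")
    return np.log(arr)


def geometric_mean_ratio(test_units, ref_units) -> float:
    """exp(mean(log test) - mean(log ref)) over all pooled units."""
    lt = _validated_log(test_units, "test_units")
    lr = _validated_log(ref_units, "ref_units")
    return float(np.exp(lt.mean() - lr.mean()))


def equivalence_decision(ci_lower: float, ci_upper: float,
                         limits: tuple[float, float] = DEFAULT_LIMITS) -> bool:
    """True iff the whole CI lies inside the acceptance range (inclusive)."""
    if ci_lower > ci_upper:
        raise ValueError("ci_lower must be <= ci_upper")
    lo, hi = limits
    return bool(ci_lower >= lo and ci_upper <= hi)


def _flat_means(logv: np.ndarray, n_bootstrap: int, rng: np.random.Generator,
                indices: np.ndarray | None) -> np.ndarray:
    flat = logv.ravel()
    n = flat.size
    if indices is None:
        indices = rng.integers(0, n, size=(n_bootstrap, n))
    return flat[indices].mean(axis=1)


def _stratified_means(logv: np.ndarray, n_bootstrap: int,
                      rng: np.random.Generator) -> np.ndarray:
    nb, nu = logv.shape
    unit_idx = rng.integers(0, nu, size=(n_bootstrap, nb, nu))
    return logv[np.arange(nb)[None, :, None], unit_idx].mean(axis=(1, 2))


def _hierarchical_means(logv: np.ndarray, n_bootstrap: int,
                        rng: np.random.Generator) -> np.ndarray:
    nb, nu = logv.shape
    batch_idx = rng.integers(0, nb, size=(n_bootstrap, nb))
    unit_idx = rng.integers(0, nu, size=(n_bootstrap, nb, nu))
    return logv[batch_idx[..., None], unit_idx].mean(axis=(1, 2))


def _extract_matrices(experiment) -> tuple[np.ndarray, np.ndarray]:
    """(ref, test) value matrices from an experiment or a tidy table."""
    if isinstance(experiment, SimulatedExperiment):
        return experiment.ref_values, experiment.test_values
    if isinstance(experiment, pd.DataFrame):
        required = {"product", "batch", "value"}
        missing = required - set(experiment.columns)
        if missing:
            raise ValueError(f"tidy table lacks columns: {sorted(missing)}")
        out = []
        for label in ("reference", "test"):
            sub = experiment[experiment["product"] == label]
            if sub.empty:
                raise ValueError(f"tidy table has no rows for product {label!r}")
            pivot = [g["value"].to_numpy(dtype=float) for _, g in sub.groupby("batch")]
            sizes = {len(g) for g in pivot}
            if len(sizes) != 1:
                raise ValueError(
                    f"product {label!r} has ragged batches (sizes {sorted(sizes)}); "
                    "a rectangular batch x unit layout is required"
                )
            out.append(np.vstack(pivot))
        return out[0], out[1]
    raise TypeError(f"unsupported experiment type: {type(experiment).__name__}")


def bootstrap_gmr_ci(
    experiment,
    n_bootstrap: int = 10_000,
    alpha: float = 0.05,
    strategy: str = "stratified",
    rng: np.random.Generator | None = None,
    limits: tuple[float, float] = DEFAULT_LIMITS,
    indices: tuple[np.ndarray, np.ndarray] | None = None,
) -> EquivalenceResult:
    """Bootstrap the GMR and test it against the acceptance range.

    Parameters
    ----------
    experiment : SimulatedExperiment or pandas.DataFrame
        Either a simulated experiment or a tidy measurement table with columns
        ``product`` (values ``reference`` and ``test``), ``batch`` and
        ``value``; batches must be rectangular.
    n_bootstrap : int
        Number of resamples B (>= 1).
    alpha : float
        Nominal one-sided type I error, in (0, 0.5); the CI spans the alpha
        and 1-alpha quantiles (alpha = 0.05 gives a 90 % interval).
    strategy : {"stratified", "flat", "hierarchical"}
        Resampling scheme; see module docstring.
    rng : numpy.random.Generator, optional
        Source of resampling randomness. Required unless ``indices`` is given.
        The reference product's indices are drawn before the test product's.
    limits : pair of float
        Acceptance range on the ratio scale; comparisons are inclusive.
    indices : pair of int arrays, optional
        Explicit flat resample indices ``(ref_idx, test_idx)``, each of shape
        (B, N_B*N_U); overrides ``rng`` and forces the flat strategy. Intended
        for exact, replayable checks.
    """
    if n_bootstrap < 1:
        raise ValueError("n_bootstrap must be >= 1")
    if not 0.0 < alpha < 0.5:
        raise ValueError(f"alpha must be in (0, 0.5), got {alpha}")
    if strategy not in ("stratified", "flat", "hierarchical"):
        raise ValueError(
            f"strategy must be 'stratified', 'flat' or 'hierarchical', got {strategy!r}")
    if indices is None and rng is None:
        raise ValueError("either rng or explicit indices must be provided")

    ref, test = _extract_matrices(experiment)
    log_ref = _validated_log(ref, "reference values")
    log_test = _validated_log(test, "test values")

    gmr = float(np.exp(log_test.mean() - log_ref.mean()))

    if indices is not None:
        ref_idx, test_idx = (np.asarray(ix) for ix in indices)
        if ref_idx.shape != test_idx.shape or ref_idx.ndim != 2:
            raise ValueError("indices must be two equal-shape (B, n) integer arrays")
        n_bootstrap = ref_idx.shape[0]
        ref_means = _flat_means(log_ref, n_bootstrap, rng, ref_idx)
        test_means = _flat_means(log_test, n_bootstrap, rng, test_idx)
    elif strategy == "flat":
        ref_means = _flat_means(log_ref, n_bootstrap, rng, None)
        test_means = _flat_means(log_test, n_bootstrap, rng, None)
    elif strategy == "stratified":
        ref_means = _stratified_means(log_ref, n_bootstrap, rng)
        test_means = _stratified_means(log_test, n_bootstrap, rng)
    else:
        ref_means = _hierarchical_means(log_ref, n_bootstrap, rng)
        test_means = _hierarchical_means(log_test, n_bootstrap, rng)

    theta = np.exp(test_means - ref_means)
    ci_lower, ci_upper = np.quantile(theta, [alpha, 1.0 - alpha], method="linear")
    passed = equivalence_decision(float(ci_lower), float(ci_upper), limits)
    return EquivalenceResult(
        gmr_observed=gmr,
        ci_lower=float(ci_lower),
        ci_upper=float(ci_upper),
        passed=passed,
        limits=limits,
        n_bootstrap=int(n_bootstrap),
        alpha=float(alpha),
        strategy="flat" if indices is not None else strategy,
    )


def read_tidy(path) -> pd.DataFrame:
    """Read a tidy measurement CSV (columns product, batch, unit, value)."""
    df = pd.read_csv(path)
    missing = {"product", "batch", "value"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def format_limits_percent(limits: tuple[float, float] = DEFAULT_LIMITS) -> str:
    """Render an acceptance range as percentages, e.g. '90.00-111.11%'."""
    return f"{limits[0] * 100:.2f}-{limits[1] * 100:.2f}%"
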