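"""Design grid of simulation scenarios.

A scenario is one point of the factorial design space over which statistical
power to declare in-vitro equivalence is mapped: the true test/reference ratio
(T/R, in percent), the number of batches per product (N_B), the number of
units measured per batch (N_U), and the inter-batch (IBV) and intra-batch
(ABV) coefficients of variation, both in percent.

Percent values are carried as percentages (e.g. ``7.5``) throughout the public
interface; conversion to fractions happens only inside the math.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import asdict, dataclass
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Scenario",
    "build_paper_grid",
    "build_custom_grid",
    "grid_to_frame",
    "grid_to_csv",
    "grid_to_json",
    "TR_LEVELS",
    "NB_LEVELS",
    "NU_LEVELS",
    "IBV_LEVELS",
    "ABV_LEVELS",
]

#: Factor levels of the reference design grid (3 * 5 * 3 * 7 * 7 = 2205 scenarios).
TR_LEVELS: tuple[float, ...] = (100.0, 97.5, 95.0)
NB_LEVELS: tuple[int, ...] = (1, 2, 3, 6, 12)
NU_LEVELS: tuple[int, ...] = (6, 12, 24)
IBV_LEVELS: tuple[float, ...] = (0.0, 2.5, 5.0, 7.5, 10.0, 15.0, 20.0)
ABV_LEVELS: tuple[float, ...] = (0.0, 2.5, 5.0, 7.5, 10.0, 15.0, 20.0)


@dataclass(frozen=True, order=True)
class Scenario:
    """One point of the design grid.

    Parameters
    ----------
    tr_ratio : float
        True population test/reference ratio in percent (100 = identical
        products). Must lie in the open interval (0, 200).
    n_batches : int
        Batches per product, >= 1.
    n_units : int
        Units (replicates) measured per batch, >= 1.
    ibv_cv : float
        Inter-batch coefficient of variation, percent, >= 0.
    abv_cv : float
        Intra-batch coefficient of variation, percent, >= 0.
    """

    tr_ratio: float
    n_batches: int
    n_units: int
    ibv_cv: float
    abv_cv: float

    def __post_init__(self) -> None:
        if not 0.0 < self.tr_ratio < 200.0:
            raise ValueError(f"tr_ratio must be in (0, 200), got {self.tr_ratio}")
        if int(self.n_batches) != self.n_batches or self.n_batches < 1:
            raise ValueError(f"n_batches must be a positive integer, got {self.n_batches}")
        if int(self.n_units) != self.n_units or self.n_units < 1:
            raise ValueError(f"n_units must be a positive integer, got {self.n_units}")
        if self.ibv_cv < 0:
            raise ValueError(f"ibv_cv must be >= 0, got {self.ibv_cv}")
        if self.abv_cv < 0:
            raise ValueError(f"abv_cv must be >= 0, got {self.abv_cv}")
        object.__setattr__(self, "tr_ratio", float(self.tr_ratio))
        object.__setattr__(self, "n_batches", int(self.n_batches))
        object.__setattr__(self, "n_units", int(self.n_units))
        object.__setattr__(self, "ibv_cv", float(self.ibv_cv))
        object.__setattr__(self, "abv_cv", float(self.abv_cv))

    @property
    def n_total(self) -> int:
        """Total observations per product (N_B * N_U)."""
        return self.n_batches * self.n_units

    def spawn_key(self) -> tuple[int, ...]:
        """Stable non-negative integer key identifying this scenario.

        Used to derive independent, reproducible random streams per scenario.
        Percent fields are scaled by 1000 so any grid value with up to three
        decimal places maps to a distinct key.
        """
        return (
            round(self.tr_ratio * 1000),
            self.n_batches,
            self.n_units,
            round(self.ibv_cv * 1000),
            round(self.abv_cv * 1000),
        )


def _sorted_levels(values: Sequence[float], *, descending: bool = False) -> list[float]:
    return sorted(set(values), reverse=descending)


def build_custom_grid(
    tr_levels: Sequence[float],
    nb_levels: Sequence[int],
    nu_levels: Sequence[int],
    ibv_levels: Sequence[float],
    abv_levels: Sequence[float],
) -> list[Scenario]:
    """Cartesian product of the given factor levels, deterministically ordered.

    Duplicates within a level list are collapsed. Ordering is lexicographic in
    (T/R, N_B, N_U, IBV, ABV) with T/R descending (so identical products come
    first, matching the customary table order) and every other axis ascending.

    Raises
    ------
    ValueError
        If any list is empty or any value violates the ``Scenario`` invariants;
        the message names the offending field.
    """
    names = ("tr_levels", "nb_levels", "nu_levels", "ibv_levels", "abv_levels")
    lists = (tr_levels, nb_levels, nu_levels, ibv_levels, abv_levels)
    for name, values in zip(names, lists):
        if len(values) == 0:
            raise ValueError(f"{name} must be non-empty")
    axes = (
        _sorted_levels(tr_levels, descending=True),
        _sorted_levels(nb_levels),
        _sorted_levels(nu_levels),
        _sorted_levels(ibv_levels),
        _sorted_levels(abv_levels),
    )
    return [Scenario(*combo) for combo in itertools.product(*axes)]


def build_paper_grid() -> list[Scenario]:
    """The full reference design grid of 2205 scenarios.

    Cartesian product of T/R in {100, 97.5, 95} %, N_B in {1, 2, 3, 6, 12},
    N_U in {6, 12, 24}, and IBV, ABV each in {0, 2.5, 5, 7.5, 10, 15, 20} %.
    Ordering is deterministic (see :func:`build_custom_grid`) and stable
    across calls.
    """
    return build_custom_grid(TR_LEVELS, NB_LEVELS, NU_LEVELS, IBV_LEVELS, ABV_LEVELS)


def grid_to_frame(scenarios: Iterable[Scenario]) -> pd.DataFrame:
    """Tabulate scenarios with columns tr_ratio, n_batches, n_units, ibv_cv, abv_cv."""
    return pd.DataFrame([asdict(s) for s in scenarios])


def grid_to_csv(scenarios: Iterable[Scenario], path) -> None:
    grid_to_frame(scenarios).to_csv(path, index=False)


def grid_to_json(scenarios: Iterable[Scenario]) -> str:
    return json.dumps([asdict(s) for s in scenarios])
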