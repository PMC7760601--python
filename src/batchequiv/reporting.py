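"""Run configuration, table emission and figures.

Wide tables mirror the customary presentation of power surfaces for this
design: one table per T/R level, row blocks of N_B x IBV, column blocks of
N_U x ABV, cells as integer-rounded percent probabilities. The long format
retains full precision alongside.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd
import yaml

from . import __version__
from .bootstrap import DEFAULT_LIMITS
from .power import PowerEstimate, estimates_to_frame

__all__ = [
    "RunConfig",
    "load_config",
    "write_long_csv",
    "write_paper_tables",
    "plot_power_curves",
    "plot_ci_distributions",
    "REFERENCE_CELLS",
]

#: Published reference probabilities (percent) for spot-check scenarios,
#: keyed by (tr_ratio, n_batches, n_units, ibv_cv, abv_cv). Used only for
#: the optional comparison report written next to regenerated tables.
REFERENCE_CELLS: dict[tuple, int] = {
    (100.0, 1, 12, 2.5, 7.5): 80,
    (100.0, 1, 12, 5.0, 2.5): 81,
    (100.0, 3, 12, 7.5, 7.5): 80,
    (95.0, 6, 12, 5.0, 5.0): 91,
    (100.0, 3, 6, 0.0, 0.0): 100,
}

_CONFIG_FIELDS = {
    "master_seed", "n_experiments", "n_bootstrap", "alpha", "strategy",
    "limits", "power_target", "workers", "output_dir",
}


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of a simulation run, serialized with outputs."""

    master_seed: int = 0
    n_experiments: int = 1000
    n_bootstrap: int = 10_000
    alpha: float = 0.05
    strategy: str = "stratified"
    limits: tuple[float, float] = DEFAULT_LIMITS
    power_target: float = 0.80
    workers: int = 1
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if self.n_experiments < 1:
            raise ValueError("n_experiments must be >= 1")
        if self.n_bootstrap < 1:
            raise ValueError("n_bootstrap must be >= 1")
        if not 0.0 < self.alpha < 0.5:
            raise ValueError(f"alpha must be in (0, 0.5), got {self.alpha}")
        if self.strategy not in ("stratified", "flat", "hierarchical"):
            raise ValueError(
                f"strategy must be 'stratified', 'flat' or 'hierarchical', got {self.strategy!r}")
        lo, hi = self.limits
        if not 0 < lo <= hi:
            raise ValueError(f"limits must satisfy 0 < lo <= hi, got {self.limits}")
        if not 0.0 < self.power_target <= 1.0:
            raise ValueError(f"power_target must be in (0, 1], got {self.power_target}")
        if self.workers < 1:
            raise ValueError("workers must be >= 1")
        object.__setattr__(self, "limits", (float(lo), float(hi)))

    def dump(self, output_dir: Path | str | None = None) -> Path:
        """Write the config plus code version next to the outputs, for provenance."""
        out = Path(output_dir if output_dir is not None else self.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        payload = asdict(self)
        payload["limits"] = list(self.limits)
        payload["version"] = __version__
        path = out / "run_config.yaml"
        path.write_text(yaml.safe_dump(payload, sort_keys=True))
        return path


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus keyword overrides.

    Flag-style overrides take precedence over file values. Unknown keys in
    either source raise a descriptive error.
    """
    values: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a mapping")
        loaded.pop("version", None)
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    unknown = set(values) - _CONFIG_FIELDS
    if unknown:
        raise ValueError(
            f"unknown config keys: {sorted(unknown)}; valid keys: {sorted(_CONFIG_FIELDS)}")
    if "limits" in values:
        values["limits"] = tuple(values["limits"])
    return RunConfig(**values)


def write_long_csv(estimates: Iterable[PowerEstimate], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    estimates_to_frame(estimates).to_csv(path, index=False)
    return path


def _wide_table(df: pd.DataFrame) -> pd.DataFrame:
    pivot = df.pivot_table(
        index=["n_batches", "ibv_cv"],
        columns=["n_units", "abv_cv"],
        values="probability",
        aggfunc="first",
    )
    if pivot.isna().any().any():
        missing = [
            f"n_batches={rb}, ibv_cv={ri}, n_units={cu}, abv_cv={ca}"
            for (rb, ri) in pivot.index
            for (cu, ca) in pivot.columns
            if pd.isna(pivot.loc[(rb, ri), (cu, ca)])
        ]
        raise ValueError("grid is ragged; missing cells: " + "; ".join(missing))
    return (pivot * 100).round(0).astype(int)


def write_paper_tables(estimates: Iterable[PowerEstimate],
                       output_dir: str | Path) -> list[Path]:
    """Per T/R level, a wide percent table; plus the long CSV and a comparison
    report against the bundled reference cells (for whichever are present).

    Raises
    ------
    ValueError
        If the estimates are empty or do not fill a factorial
        (N_B x IBV) x (N_U x ABV) grid for some T/R level; the error names
        the missing cells.
    """
    estimates = list(estimates)
    if not estimates:
        raise ValueError("no estimates to tabulate")
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = estimates_to_frame(estimates)

    written = [write_long_csv(estimates, out / "power_long.csv")]
    for tr, sub in df.groupby("tr_ratio", sort=False):
        wide = _wide_table(sub)
        path = out / f"power_table_tr{tr:g}.csv"
        wide.to_csv(path)
        written.append(path)

    comparisons = []
    for _, row in df.iterrows():
        key = (row["tr_ratio"], int(row["n_batches"]), int(row["n_units"]),
               row["ibv_cv"], row["abv_cv"])
        if key in REFERENCE_CELLS:
            comparisons.append({
                "tr_ratio": key[0], "n_batches": key[1], "n_units": key[2],
                "ibv_cv": key[3], "abv_cv": key[4],
                "reference_percent": REFERENCE_CELLS[key],
                "estimated_percent": round(row["probability"] * 100, 1),
            })
    if comparisons:
        path = out / "reference_comparison.csv"
        pd.DataFrame(comparisons).to_csv(path, index=False)
        written.append(path)
    return written


def plot_power_curves(estimates: Iterable[PowerEstimate],
                      output_dir: str | Path,
                      power_target: float = 0.80) -> list[Path]:
    """Power-curve panels: probability vs IBV (panelled by N_U x ABV, one line
    per N_B) and vs ABV (panelled by N_B x IBV, one line per N_U), each with a
    horizontal reference line at the power target. One figure per T/R level
    and orientation, written as SVG with deterministic metadata.
    """
    df = estimates_to_frame(list(estimates))
    if df.empty:
        raise ValueError("no estimates to plot")
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    specs = [
        ("ibv_cv", "abv_cv", "n_units", "n_batches", "inter-batch CV (%)", "ibv"),
        ("abv_cv", "ibv_cv", "n_batches", "n_units", "intra-batch CV (%)", "abv"),
    ]
    with plt.rc_context({"svg.hashsalt": "batchequiv", "figure.max_open_warning": 0}):
        for tr, sub in df.groupby("tr_ratio", sort=False):
            for x, panel_row, panel_col, hue, xlabel, tag in specs:
                rows = sorted(sub[panel_row].unique())
                cols = sorted(sub[panel_col].unique())
                fig, axes = plt.subplots(
                    len(rows), len(cols), sharex=True, sharey=True, squeeze=False,
                    figsize=(2.2 * len(cols) + 1, 1.8 * len(rows) + 1),
                )
                for i, rv in enumerate(rows):
                    for j, cv in enumerate(cols):
                        ax = axes[i][j]
                        cell = sub[(sub[panel_row] == rv) & (sub[panel_col] == cv)]
                        for hv, line in cell.groupby(hue):
                            line = line.sort_values(x)
                            ax.plot(line[x], line["probability"], marker="o",
                                    markersize=2, label=f"{hue}={hv:g}")
                        ax.axhline(power_target, ls="--", color="grey", lw=0.8)
                        ax.set_ylim(-0.05, 1.05)
                        if i == 0:
                            ax.set_title(f"{panel_col}={cv:g}", fontsize=8)
                        if j == len(cols) - 1:
                            ax.text(1.02, 0.5, f"{panel_row}={rv:g}", fontsize=7,
                                    transform=ax.transAxes, rotation=270, va="center")
                axes[-1][0].set_xlabel(xlabel)
                axes[0][0].set_ylabel("P(similarity)")
                handles, labels = axes[0][0].get_legend_handles_labels()
                if handles:
                    fig.legend(handles, labels, loc="lower right", fontsize=7)
                path = out / f"power_vs_{tag}_tr{tr:g}.svg"
                fig.savefig(path, metadata={"Date": None})
                plt.close(fig)
                written.append(path)
    return written


def plot_ci_distributions(estimates: Iterable[PowerEstimate],
                          output_dir: str | Path,
                          limits: tuple[float, float] = DEFAULT_LIMITS) -> list[Path]:
    """Boxplots of per-experiment CI bounds across the grid.

    Requires estimates produced with ``keep_ci_bounds=True``. Boxes span
    Q1-Q3 with whiskers at 1.5*IQR; the 5th and 95th percentiles are overlaid
    as markers since both summaries are of interest; dashed lines mark the
    acceptance limits. One figure (lower and upper bound rows) per T/R level.
    """
    import numpy as np

    estimates = [e for e in estimates if e.ci_lowers is not None]
    if not estimates:
        raise ValueError("no estimates carry CI bounds; rerun with keep_ci_bounds=True")
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    by_tr: dict[float, list[PowerEstimate]] = {}
    for e in estimates:
        by_tr.setdefault(e.scenario.tr_ratio, []).append(e)
    written = []
    with plt.rc_context({"svg.hashsalt": "batchequiv"}):
        for tr, group in by_tr.items():
            group = sorted(group, key=lambda e: (e.scenario.n_units, e.scenario.n_batches))
            labels = [f"NB={e.scenario.n_batches}\nNU={e.scenario.n_units}" for e in group]
            fig, (ax_lo, ax_hi) = plt.subplots(
                2, 1, sharex=True, figsize=(max(4, 0.9 * len(group)), 5))
            for ax, attr in ((ax_lo, "ci_lowers"), (ax_hi, "ci_uppers")):
                data = [list(getattr(e, attr)) for e in group]
                ax.boxplot(data, tick_labels=labels, whis=1.5, showfliers=False)
                for k, vals in enumerate(data, start=1):
                    ax.plot([k, k], np.percentile(vals, [5, 95]), "x", color="tab:red", ms=4)
                for lim in limits:
                    ax.axhline(lim, ls="--", color="grey", lw=0.8)
            ax_lo.set_ylabel("lower 90% CI bound")
            ax_hi.set_ylabel("upper 90% CI bound")
            fig.suptitle(f"T/R = {tr:g}%")
            path = out / f"ci_bounds_tr{tr:g}.svg"
            fig.savefig(path, metadata={"Date": None})
            plt.close(fig)
            written.append(path)
    return written
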