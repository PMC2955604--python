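"""Structure and delay selection by validation BIC.

A grid over hidden-node counts and delay sets is fitted with multistart
training; the selected model maximizes the Bayesian information
criterion on the validation split.  Scanning the delay grid doubles as
a system-delay identification strategy: when the model delay matches
the true system delay the validation BIC peaks, and even a mismatched
delay typically dominates the no-delay model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from ._rng import derive_seed
from .hybrid_balance import HybridModelSpec
from .training import TimeSeriesDataset, TrainOptions, criteria, fit_multistart

__all__ = ["SelectionTable", "grid_search", "select_best", "delay_scan_report", "DelayScanReport"]

_COLUMNS = [
    "nodes", "delays", "n_w", "seed", "best_restart_seed",
    "bic_train", "bic_valid", "bic_test",
    "mse_train", "mse_valid", "mse_test",
    "error",
]


def format_delays(delay_set) -> str:
    """Canonical string form of a delay set ('0', '120', '80;120', ...)."""
    if delay_set is None:
        return "0"
    offs = np.atleast_1d(np.asarray(delay_set, float))
    offs = offs[offs > 0]
    if offs.size == 0:
        return "0"
    return ";".join(f"{o:g}" for o in sorted(offs))


@dataclass
class SelectionTable:
    """Grid-search results, one row per (nodes, delay set) grid point."""

    df: pd.DataFrame
    fits: dict = field(default_factory=dict)  # (nodes, delays str) -> FitResult

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SelectionTable":
        df = pd.read_csv(path, dtype={"delays": str})
        return cls(df)


def grid_search(
    node_counts: Sequence[int],
    delay_sets: Sequence,
    datasets: dict,
    n_restarts: int,
    seed: int,
    *,
    spec_factory: Callable[[int, object], HybridModelSpec],
    opts: TrainOptions | None = None,
) -> SelectionTable:
    """Fit every (hidden nodes, delay set) grid point with multistart.

    ``spec_factory(nodes, delay_set)`` builds the hybrid model of one
    grid point; ``datasets`` holds the 'train', 'valid' and 'test'
    splits.  Each grid point gets its own deterministically derived
    seed, so results do not depend on execution order; individual
    failures are recorded in the table, not fatal.
    """
    if not len(node_counts) or not len(delay_sets):
        raise ValueError("node and delay grids must be non-empty")
    train, valid = datasets["train"], datasets["valid"]
    test = datasets.get("test")
    rows, fits = [], {}
    for nodes in node_counts:
        for dset in delay_sets:
            dstr = format_delays(dset)
            point_seed = derive_seed(seed, "grid", nodes, dstr)
            row = {
                "nodes": int(nodes), "delays": dstr, "seed": point_seed, "error": "",
            }
            try:
                spec = spec_factory(int(nodes), dset)
                fit = fit_multistart(spec, train, valid, n_restarts, point_seed, opts)
                row["n_w"] = fit.n_w
                row["best_restart_seed"] = fit.seed
                for split, ds in (("train", train), ("valid", valid), ("test", test)):
                    if ds is None:
                        row[f"bic_{split}"] = math.nan
                        row[f"mse_{split}"] = math.nan
                        continue
                    if split in fit.criteria:
                        crit = fit.criteria[split]
                    else:
                        crit = criteria(spec, fit.params, ds, opts)
                    row[f"bic_{split}"] = crit["BIC"]
                    row[f"mse_{split}"] = crit["MSE"]
                fits[(int(nodes), dstr)] = fit
            except Exception as exc:
                row["error"] = f"{type(exc).__name__}: {exc}"
                row["n_w"] = math.nan
                row["best_restart_seed"] = -1
                for split in ("train", "valid", "test"):
                    row[f"bic_{split}"] = -math.inf
                    row[f"mse_{split}"] = math.inf
            rows.append(row)
    return SelectionTable(pd.DataFrame(rows, columns=_COLUMNS), fits)


def select_best(table: SelectionTable | pd.DataFrame):
    """Row with maximal validation BIC (ties: fewer parameters, then first)."""
    df = table.df if isinstance(table, SelectionTable) else table
    if df.empty:
        raise ValueError("selection table is empty")
    best_bic = df["bic_valid"].max()
    cand = df[df["bic_valid"] == best_bic]
    if "n_w" in cand and cand["n_w"].notna().any():
        cand = cand[cand["n_w"] == cand["n_w"].min()]
    return cand.iloc[0]


@dataclass
class DelayScanReport:
    """Per-delay best validation BIC and the implied system delay."""

    per_delay: pd.DataFrame  # columns: delays, bic_valid (best over nodes)
    estimated_delay: str | None
    indeterminate: bool
    no_delay_dominated: bool | None
    grid_edge: bool
    strayed: list


def _delay_sort_key(dstr: str) -> float:
    return max(float(x) for x in dstr.split(";"))


def delay_scan_report(table: SelectionTable | pd.DataFrame) -> DelayScanReport:
    """Summarize a delay scan as a system-delay identification.

    Reports the best validation BIC per delay set and its argmax; flags
    whether the no-delay model is dominated, whether the winner sits on
    the edge of a single-delay grid, and rows whose validation BIC
    strays more than 3 MAD from their delay group's best (diagnostics
    only).
    """
    df = table.df if isinstance(table, SelectionTable) else table
    delays = df["delays"].unique()
    if len(delays) < 2:
        raise ValueError("delay scan requires at least two delay values")
    per = (
        df.groupby("delays")["bic_valid"].max().reset_index()
        .sort_values("delays", key=lambda s: s.map(_delay_sort_key))
        .reset_index(drop=True)
    )
    finite = per[np.isfinite(per["bic_valid"])]
    indeterminate = finite.empty or bool(np.all(finite["bic_valid"] == finite["bic_valid"].iloc[0]))
    estimated = None if indeterminate else str(finite.loc[finite["bic_valid"].idxmax(), "delays"])

    no_delay_dominated = None
    if "0" in set(per["delays"]):
        bic0 = per.loc[per["delays"] == "0", "bic_valid"].iloc[0]
        others = per.loc[per["delays"] != "0", "bic_valid"]
        no_delay_dominated = bool((others > bic0).any())

    grid_edge = False
    if estimated is not None and ";" not in estimated:
        single = [d for d in per["delays"] if ";" not in d and d != "0"]
        vals = sorted(float(d) for d in single)
        if vals and float(estimated) in (vals[0], vals[-1]):
            grid_edge = True

    resid = df["bic_valid"] - df["delays"].map(per.set_index("delays")["bic_valid"])
    finite_resid = resid[np.isfinite(resid)]
    mad = float(np.median(np.abs(finite_resid - np.median(finite_resid)))) if len(finite_resid) else 0.0
    strayed = (
        df.index[np.abs(resid - np.median(finite_resid)) > 3 * mad].tolist()
        if mad > 0
        else []
    )
    return DelayScanReport(
        per_delay=per,
        estimated_delay=estimated,
        indeterminate=indeterminate,
        no_delay_dominated=no_delay_dominated,
        grid_edge=grid_edge,
        strayed=strayed,
    )
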