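"""Reference-table generation and file I/O.

The three reference tables give the participant numbers needed for 80%
power under frequentist (p < .05) and default-Bayesian (BF10 > 10)
success criteria across the catalog designs at d = .4/.5/.6, plus a 90%
power variant.  :func:`reproduce_table` regenerates any subset of rows at
configurable fidelity (replications, grid, seed); cells with a closed-form
solution use the analytic search, everything else runs the Monte-Carlo
minimal-N search.  All outputs carry full provenance (reps, seed, grid
step, Monte-Carlo SE) and round-trip through JSON.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .power_engine import MinN, analytic_min_n, find_min_n
from .scenarios import build_scenario

logger = logging.getLogger("powerref")

__all__ = ["ReferenceTable", "TableCell", "reproduce_table",
           "write_outputs", "read_reference_table", "read_long_csv"]


@dataclass(frozen=True)
class TableCell:
    """One (row, effect-size column) cell of a reference table."""

    row: str
    scenario: str
    mode: str
    d: float
    target_power: float
    n_per_group: int
    n_total: int
    estimate: float
    se: float
    method: str
    step: int

    def to_dict(self):
        return asdict(self)


@dataclass(frozen=True)
class ReferenceTable:
    """A regenerated reference table plus its generation settings."""

    table: int
    cells: tuple
    reps: int | None
    seed: int
    columns: tuple

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([c.to_dict() for c in self.cells])

    def to_dict(self):
        return {"table": self.table, "reps": self.reps, "seed": self.seed,
                "columns": list(self.columns),
                "cells": [c.to_dict() for c in self.cells]}


# row label -> (scenario name, kwargs, analytic kind or None)
# Printed reference values live in the documentation, not here: every cell
# is recomputed.
_ROWS: dict[str, tuple] = {
    "between_2_levels": ("t_between", {}, "independent"),
    "between_2_levels_null": ("t_between_null", {}, "tost_independent"),
    "between_3_levels_similar": ("three_between_similar", {}, None),
    "between_3_levels_ordered": ("three_between_ordered", {}, None),
    "within_2_levels": ("t_within", {}, "paired"),
    "within_2_levels_null": ("t_within_null", {}, "tost_paired"),
    "within_3_levels_similar": ("three_within_similar", {}, None),
    "within_3_levels_ordered": ("three_within_ordered", {}, None),
    "correlation": ("correlation", {}, "correlation"),
    "rm2x2_main_effect": ("rm2x2_main", {}, None),
    "rm2x2_interaction": ("rm2x2_interaction_null_cell", {}, None),
    "splitplot_main_between_r5": ("splitplot_main_between", {"r": 0.5}, None),
    "splitplot_main_between_r9": ("splitplot_main_between", {"r": 0.9}, None),
    "splitplot_main_within": ("splitplot_main_within", {}, None),
    "splitplot_interaction": ("splitplot_interaction_null_cell", {}, None),
    "ancova_r5": ("ancova", {"r": 0.5}, None),
    "ancova_r9": ("ancova", {"r": 0.9}, None),
}

_TABLE_SPECS = {
    8: {"mode": "frequentist", "target_power": 0.8, "bf_null": 1 / 10},
    9: {"mode": "bayesian", "target_power": 0.8, "bf_null": 1 / 10},
    10: {"mode": "frequentist", "target_power": 0.9, "bf_null": 1 / 10},
}


def table_rows() -> tuple[str, ...]:
    """Stable row identifiers of the reference tables."""
    return tuple(_ROWS)


def _cell(row: str, d: float, table_spec: dict, reps, seed, step,
          analytic: bool) -> TableCell:
    scenario_name, kwargs, analytic_kind = _ROWS[row]
    mode = table_spec["mode"]
    target = table_spec["target_power"]
    sc = build_scenario(scenario_name, d=d, mode=mode,
                        bf_null=table_spec["bf_null"], **kwargs)
    if analytic and analytic_kind is not None and mode == "frequentist":
        eff = d / 2.0 if analytic_kind == "correlation" else d
        if analytic_kind.startswith("tost"):
            res = analytic_min_n(0.0, target, kind=analytic_kind,
                                 bound=0.1 if "correlation" in analytic_kind
                                 else 0.2)
        else:
            res = analytic_min_n(eff, target, kind=analytic_kind)
    else:
        res = find_min_n(sc, target_power=target, reps=reps, seed=seed,
                         step=step)
    se = float(np.sqrt(max(res.estimate * (1 - res.estimate), 0.0)
                       / res.reps)) if res.reps else 0.0
    logger.info("table cell %s d=%.2g (%s): n=%d per group (total %d), "
                "power %.3f +/- %.3f", row, d, mode, res.n, res.n_total,
                res.estimate, se)
    return TableCell(row=row, scenario=scenario_name, mode=mode, d=d,
                     target_power=target, n_per_group=res.n,
                     n_total=res.n_total, estimate=res.estimate, se=se,
                     method=res.method, step=res.step)


def reproduce_table(table: int, columns=(0.4, 0.5, 0.6), reps: int | None = None,
                    seed: int = 0, rows=None, step: int | None = None,
                    analytic: bool = True) -> ReferenceTable:
    """Recompute reference-table cells from scratch.

    Parameters
    ----------
    table : {8, 9, 10}
        8: frequentist at 80% power; 9: Bayesian (BF10 > 10) at 80% power;
        10: 90% power.  Table 10 regenerates both modes' d = .4 column by
        default when ``columns`` is left at the d grid.
    columns : sequence of float
        Effect-size columns to compute.
    reps, seed, step
        Monte-Carlo settings forwarded to :func:`find_min_n`.  Lower
        ``reps`` (e.g. 500) give a fast smoke table with wider SEs.
    rows : sequence of str, optional
        Subset of :func:`table_rows`; default all.
    analytic : bool
        Use the closed-form search where one exists (simple t, correlation
        and TOST rows under a frequentist criterion).

    Null-hypothesis rows are TOST designs under the frequentist mode and
    BF10 < 1/10 designs under the Bayesian mode; their cells do not depend
    on d.  Infeasible cells raise rather than being silently dropped.
    """
    if table not in _TABLE_SPECS:
        raise ValueError("table must be 8, 9 or 10")
    spec = _TABLE_SPECS[table]
    if table == 10 and columns == (0.4, 0.5, 0.6):
        columns = (0.4,)
    use_rows = tuple(rows) if rows is not None else tuple(_ROWS)
    unknown = set(use_rows) - set(_ROWS)
    if unknown:
        raise KeyError(f"unknown rows: {sorted(unknown)}")
    cells = []
    for row in use_rows:
        for d in columns:
            cells.append(_cell(row, float(d), spec, reps, seed, step,
                               analytic))
    return ReferenceTable(table=table, cells=tuple(cells),
                          reps=reps, seed=seed, columns=tuple(columns))


def write_outputs(obj, path, format: str = "json") -> None:
    """Serialize a ReferenceTable (or any dataclass result) to csv or json."""
    if format == "csv":
        frame = obj.to_frame() if hasattr(obj, "to_frame") else \
            pd.DataFrame([asdict(obj)])
        frame.to_csv(path, index=False)
    elif format == "json":
        payload = obj.to_dict() if hasattr(obj, "to_dict") else asdict(obj)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
    else:
        raise ValueError("format must be csv or json")


def read_reference_table(path) -> ReferenceTable:
    """Inverse of :func:`write_outputs` for JSON reference tables."""
    with open(path) as fh:
        payload = json.load(fh)
    cells = tuple(TableCell(**c) for c in payload["cells"])
    return ReferenceTable(table=payload["table"], cells=cells,
                          reps=payload["reps"], seed=payload["seed"],
                          columns=tuple(payload["columns"]))


def read_long_csv(path) -> pd.DataFrame:
    """Read a long-format observations CSV (Participant,Condition,Response).

    Rows with missing values are permitted (absent observations are simply
    left out of the file); malformed response values are reported with
    their line numbers.
    """
    df = pd.read_csv(path, dtype={"Participant": str, "Condition": str})
    required = ["Participant", "Condition", "Response"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"long CSV must have columns {required}; "
                         f"missing {missing}")
    coerced = pd.to_numeric(df["Response"], errors="coerce")
    bad = df.index[coerced.isna() & df["Response"].notna()]
    if len(bad):
        lines = ", ".join(str(i + 2) for i in bad[:10])  # +2: header + 1-based
        raise ValueError(f"non-numeric Response values on line(s) {lines}")
    df["Response"] = coerced
    return df
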