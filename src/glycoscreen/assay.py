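"""Functional-assay metrics: lactate-screen hit calling, extracellular-flux
(Seahorse) parameters, energy-map coordinates and the glucose-uptake rate.

Flux traces follow the standard stress-test layouts: the glycolysis test
measures ECAR at baseline and after glucose, oligomycin and 2-deoxyglucose
injections; the mito test measures OCR at baseline and after oligomycin,
FCCP and rotenone/antimycin.  Parameters are differences of per-phase,
per-cell aggregates against the non-glycolytic / non-mitochondrial floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

GLYCOLYSIS_PHASES = ("baseline", "glucose", "oligomycin", "2dg")
RESPIRATION_PHASES = ("baseline", "oligomycin", "fccp", "rot_aa")

#: vendor-style per-phase aggregation: the last baseline point, the maximal
#: response to a stimulation, the minimal rate after an inhibitor
_PHASE_KIND = {
    "baseline": "last",
    "glucose": "max",
    "oligomycin": "max",
    "fccp": "max",
    "2dg": "min",
    "rot_aa": "min",
}


@dataclass
class SeahorseTrace:
    """Tidy per-well rate series: columns well, phase, timepoint, rate, cells."""

    data: pd.DataFrame
    phases: tuple[str, ...] = GLYCOLYSIS_PHASES

    def __post_init__(self) -> None:
        need = {"well", "phase", "timepoint", "rate", "cells"}
        missing = need - set(self.data.columns)
        if missing:
            raise ValueError(f"trace lacks columns: {sorted(missing)}")
        present = set(self.data["phase"])
        absent = [p for p in self.phases if p not in present]
        if absent:
            raise ValueError(f"missing phases: {absent}")
        if (self.data["cells"] <= 0).any():
            raise ValueError("cell counts must be positive")

    def phase_aggregate(self, phase: str, mode: str = "vendor") -> float:
        """Per-cell aggregate rate for one phase, averaged over wells."""
        sub = self.data[self.data["phase"] == phase]
        per_cell = sub.assign(norm=sub["rate"] / sub["cells"])
        if mode == "mean":
            return float(per_cell.groupby("well")["norm"].mean().mean())
        kind = _PHASE_KIND.get(phase, "mean")
        grouped = per_cell.sort_values("timepoint").groupby("well")["norm"]
        if kind == "last":
            agg = grouped.last()
        elif kind == "max":
            agg = grouped.max()
        elif kind == "min":
            agg = grouped.min()
        else:
            agg = grouped.mean()
        return float(agg.mean())


@dataclass(frozen=True)
class FluxParams:
    glycolysis: float = np.nan
    glycolytic_capacity: float = np.nan
    basal_respiration: float = np.nan
    maximal_respiration: float = np.nan


def glycolysis_params(trace: SeahorseTrace, mode: str = "vendor") -> FluxParams:
    """Glycolysis and glycolytic capacity from an ECAR stress-test trace.

    Non-glycolytic acidification is the post-2-DG aggregate; glycolysis is
    the post-glucose aggregate minus that floor; capacity the post-oligomycin
    aggregate minus the floor.  All per-cell normalized.
    """
    non_glyc = trace.phase_aggregate("2dg", mode)
    return FluxParams(
        glycolysis=trace.phase_aggregate("glucose", mode) - non_glyc,
        glycolytic_capacity=trace.phase_aggregate("oligomycin", mode) - non_glyc,
    )


def respiration_params(trace: SeahorseTrace, mode: str = "vendor") -> FluxParams:
    """Basal and maximal respiration from an OCR mito stress-test trace."""
    non_mito = trace.phase_aggregate("rot_aa", mode)
    return FluxParams(
        basal_respiration=trace.phase_aggregate("baseline", mode) - non_mito,
        maximal_respiration=trace.phase_aggregate("fccp", mode) - non_mito,
    )


def lactate_hit_call(
    table: pd.DataFrame,
    control: str = "control",
    cutoff: float = 0.70,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Flag conditions whose silencing drops lactate to <= cutoff x control.

    ``table`` is tidy (columns: condition, value) with control-normalized
    per-cell lactate.  A condition is a hit when its mean is at most
    ``cutoff`` times the control mean AND a two-sided rank-sum test against
    control gives p < alpha.  Conditions with fewer than 2 replicates are
    flagged unevaluable rather than silently judged.
    """
    if control not in set(table["condition"]):
        raise ValueError(f"control condition {control!r} absent")
    ctrl = table.loc[table["condition"] == control, "value"].to_numpy(float)
    if ctrl.mean() <= 0:
        raise ValueError("control mean must be positive")
    rows = []
    for cond, sub in table.groupby("condition", sort=False):
        vals = sub["value"].to_numpy(float)
        if cond == control:
            rows.append({"condition": cond, "mean_ratio": 1.0, "p": 1.0,
                         "hit": False, "evaluable": True})
            continue
        if len(vals) < 2:
            rows.append({"condition": cond, "mean_ratio": np.nan, "p": np.nan,
                         "hit": False, "evaluable": False})
            continue
        ratio = vals.mean() / ctrl.mean()
        p = float(mannwhitneyu(vals, ctrl, alternative="two-sided").pvalue)
        rows.append({
            "condition": cond,
            "mean_ratio": ratio,
            "p": p,
            "hit": bool(ratio <= cutoff and p < alpha),
            "evaluable": True,
        })
    return pd.DataFrame(rows).set_index("condition")


def energy_map(
    baseline_ecar: pd.Series, baseline_ocr: pd.Series, reference: str
) -> pd.DataFrame:
    """Per-condition relative (ECAR, OCR) coordinates with quadrant labels.

    Coordinates are ratios to the reference condition.  Quadrants:
    energetic (x>=1, y>=1), glycolytic (x>=1, y<1), aerobic (x<1, y>=1),
    quiescent (x<1, y<1); the reference itself sits on the (1,1) boundary
    and is labeled energetic by convention.
    """
    if reference not in baseline_ecar.index or reference not in baseline_ocr.index:
        raise ValueError(f"reference condition {reference!r} absent")
    x = baseline_ecar / baseline_ecar[reference]
    y = baseline_ocr / baseline_ocr[reference]
    quadrant = np.where(
        (x >= 1) & (y >= 1), "energetic",
        np.where((x >= 1), "glycolytic", np.where(y >= 1, "aerobic", "quiescent")),
    )
    return pd.DataFrame({"x": x, "y": y, "quadrant": quadrant})


def glucose_uptake_rate(
    conc_2dg6p_fmol_per_ul: float,
    volume_ul: float,
    n_cells: float,
    minutes: float,
) -> float:
    """Glucose-uptake rate in fmol/cell/min:
    ([2DG6P] x sample volume) / (cell number x uptake time)."""
    if n_cells <= 0 or minutes <= 0:
        raise ValueError("cell number and uptake time must be positive")
    if conc_2dg6p_fmol_per_ul < 0 or volume_ul <= 0:
        raise ValueError("concentration must be >= 0 and volume > 0")
    return conc_2dg6p_fmol_per_ul * volume_ul / (n_cells * minutes)
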