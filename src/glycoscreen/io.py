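"""Tab-separated and TIFF readers/writers plus bundle validation and the
machine-readable run report.

Conventions: TSV with a header row, UTF-8, '.' decimal separator; expression
and metabolite matrices carry features on rows and sample/line identifiers
as columns; annotation and survival tables are indexed by sample identifier.
Floats round-trip at 15 significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .datatypes import CellLinePanel, CohortTable, RegulationTable, ValidationError

_FLOAT_FMT = "%.15g"


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    bad = df.columns[df.dtypes == object]
    if len(bad):
        for col in bad:
            culprit = df[pd.to_numeric(df[col], errors="coerce").isna()][col]
            if len(culprit):
                raise ValidationError(
                    f"{path}: non-numeric value {culprit.iloc[0]!r} in column "
                    f"{col!r}, row {culprit.index[0]!r}"
                )
    return df


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def read_table(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_cohort(cohort: CohortTable, outdir) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "samples": outdir / "samples.tsv",
    }
    write_matrix(cohort.expression, paths["expression"])
    write_table(cohort.samples, paths["samples"])
    return paths


def read_cohort(expression_path, samples_path) -> CohortTable:
    expr = read_matrix(expression_path)
    samples = read_table(samples_path)
    missing = expr.columns.difference(samples.index)
    if len(missing):
        raise ValidationError(
            f"{expression_path}: samples missing from {samples_path}: "
            f"{list(missing[:5])} ({len(missing)} total)"
        )
    return CohortTable(expression=expr, samples=samples.loc[expr.columns])


def write_panel(panel: CellLinePanel, outdir) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "panel_expression.tsv",
        "metabolites": outdir / "panel_metabolites.tsv",
    }
    write_matrix(panel.expression, paths["expression"])
    write_matrix(panel.metabolites, paths["metabolites"])
    return paths


def read_panel(expression_path, metabolites_path) -> CellLinePanel:
    expr = read_matrix(expression_path)
    metab = read_matrix(metabolites_path)
    if not expr.columns.equals(metab.columns):
        raise ValidationError(
            f"cell-line identifiers differ between {expression_path} and "
            f"{metabolites_path}"
        )
    return CellLinePanel(expression=expr, metabolites=metab)


def write_regulation(table: RegulationTable, path) -> None:
    write_table(table.table, path, index=False)


def read_regulation(path) -> RegulationTable:
    return RegulationTable(pd.read_csv(path, sep="\t"))


def write_image(image_channels: dict[str, np.ndarray], path) -> None:
    """Write named channels as a multi-page float32 TIFF (one page/channel)."""
    stack = np.stack([np.asarray(image_channels[k], dtype=np.float32)
                      for k in sorted(image_channels)])
    tifffile.imwrite(path, stack, photometric="minisblack",
                     metadata={"channels": sorted(image_channels)})


def read_image(path, channel_names=None) -> dict[str, np.ndarray]:
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    names = channel_names or [f"ch{i}" for i in range(arr.shape[0])]
    return {name: arr[i] for i, name in enumerate(names)}


def write_labels(labels: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(labels, dtype=np.uint16))


def write_newick(newick: str, path) -> None:
    Path(path).write_text(newick + "\n")


# --------------------------------------------------------------------------
# report assembly


def run_report(stage_results: dict[str, dict], outdir) -> Path:
    """Assemble a machine-readable JSON report, one section per stage.

    ``stage_results`` maps stage name -> JSON-serializable summary dict.
    Deterministic given deterministic inputs (no timestamps).
    """
    if not stage_results:
        raise ValueError("no stage results to report")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "report.json"

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not serializable: {type(o)}")

    path.write_text(json.dumps(stage_results, indent=2, sort_keys=True,
                               default=_default) + "\n")
    lines = ["glycoscreen run report", "======================"]
    for stage, summary in stage_results.items():
        lines.append(f"\n[{stage}]")
        for k, v in summary.items():
            lines.append(f"  {k}: {v}")
    (outdir / "report.txt").write_text("\n".join(lines) + "\n")
    return path
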