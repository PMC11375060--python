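"""In-memory containers shared across pipeline stages.

Matrices are pandas DataFrames with genes/metabolites on rows and
samples/cell lines on columns; per-sample annotations live in a DataFrame
indexed by sample identifier.  Validation happens at construction so that
downstream stages can assume aligned, finite inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: annotation columns every cohort sample table must carry
COHORT_REQUIRED_COLUMNS = ("subtype", "time", "event")

#: covariates entering the multivariable proportional-hazards fit
MULTIVARIABLE_COVARIATES = ("age", "tumor_size", "nodal_status",
                            "hormone_receptor", "her2", "grade")


class ValidationError(ValueError):
    """Raised when an input bundle violates its schema."""


@dataclass
class CohortTable:
    """Expression matrix plus per-sample subtype, covariates and survival.

    ``expression``: gene x sample, log2 scale.
    ``samples``: indexed by sample id; must contain 'subtype', 'time' (years,
    > 0), 'event' (0/1, death related to disease) and any covariates.
    """

    expression: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in COHORT_REQUIRED_COLUMNS if c not in self.samples.columns]
        if missing:
            raise ValidationError(f"sample table lacks columns: {missing}")
        if not self.expression.columns.equals(self.samples.index):
            extra = self.expression.columns.difference(self.samples.index)
            if len(extra):
                raise ValidationError(
                    f"samples present in expression but not annotated: "
                    f"{list(extra[:5])} ({len(extra)} total)"
                )
            self.samples = self.samples.loc[self.expression.columns]
        if self.samples["subtype"].isna().any():
            bad = self.samples.index[self.samples["subtype"].isna()]
            raise ValidationError(f"samples lacking a subtype: {list(bad[:5])}")
        t = self.samples["time"].to_numpy(float)
        if not np.all(t > 0):
            raise ValidationError("survival times must be > 0")
        ev = self.samples["event"].to_numpy()
        if not np.isin(ev, (0, 1)).all():
            raise ValidationError("event indicator must be 0/1")
        if not np.isfinite(self.expression.to_numpy(float)).all():
            raise ValidationError("expression matrix contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.expression.shape[1]

    @property
    def genes(self) -> pd.Index:
        return self.expression.index

    def group_mask(self, target_group: str) -> np.ndarray:
        """Boolean mask of samples belonging to ``target_group``."""
        subtypes = self.samples["subtype"]
        if target_group not in set(subtypes):
            raise ValidationError(f"unknown target group {target_group!r}")
        return (subtypes == target_group).to_numpy()


@dataclass
class CellLinePanel:
    """Paired gene x line expression and metabolite x line log10 concentrations.

    ``gene_modules`` / ``metabolite_blocks`` are optional ground-truth labels
    ('glycolytic' / 'fao' / 'null') attached by the simulator for recovery
    tests; real panels leave them empty.
    """

    expression: pd.DataFrame
    metabolites: pd.DataFrame
    gene_modules: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))
    metabolite_blocks: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))

    def __post_init__(self) -> None:
        if not self.expression.columns.equals(self.metabolites.columns):
            raise ValidationError(
                "cell-line identifiers differ between expression and metabolite "
                "matrices"
            )

    @property
    def n_lines(self) -> int:
        return self.expression.shape[1]


@dataclass
class RegulationTable:
    """Differential-regulation table: gene, log2fc, fdr, direction (up/down)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"gene", "log2fc", "fdr", "direction"}
        missing = need - set(self.table.columns)
        if missing:
            raise ValidationError(f"regulation table lacks columns: {sorted(missing)}")
        fdr = self.table["fdr"].to_numpy(float)
        if ((fdr < 0) | (fdr > 1)).any():
            raise ValidationError("fdr must lie in [0, 1]")
        sign_ok = np.where(
            self.table["log2fc"].to_numpy(float) < 0,
            self.table["direction"] == "down",
            self.table["direction"] == "up",
        )
        nonzero = self.table["log2fc"].to_numpy(float) != 0
        if not sign_ok[nonzero].all():
            raise ValidationError("direction inconsistent with sign of log2fc")

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class CellImage:
    """Named 2-D channels (or z-stacks) plus the physical pixel size."""

    channels: dict[str, np.ndarray]
    pixel_size_nm: float

    def __post_init__(self) -> None:
        shapes = {ch.shape[-2:] for ch in self.channels.values()}
        if len(shapes) > 1:
            raise ValidationError(f"channels disagree on shape: {shapes}")
        if self.pixel_size_nm <= 0:
            raise ValidationError("pixel size must be positive")
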