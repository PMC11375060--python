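"""Direction statistics over a differential-regulation table.

Given a knockdown-vs-control table (gene, log2FC, FDR), these utilities
compute the fraction of downregulated genes, the probability that k
independent random genes are all downregulated (p_down ** k, evaluated in
log space), and a significance summary for a user-supplied gene panel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import RegulationTable


@dataclass(frozen=True)
class DirectionSummary:
    n_up: int
    n_down: int
    n_zero: int  # genes with log2fc exactly 0, excluded from the ratio

    @property
    def n_total(self) -> int:
        return self.n_up + self.n_down

    @property
    def p_down(self) -> float:
        return self.n_down / self.n_total


def direction_proportions(table: RegulationTable | pd.DataFrame) -> DirectionSummary:
    """Count up/down regulated genes; zero-fold-change genes are set aside."""
    df = table.table if isinstance(table, RegulationTable) else table
    if len(df) == 0:
        raise ValueError("empty regulation table")
    lfc = df["log2fc"].to_numpy(float)
    n_zero = int((lfc == 0).sum())
    n_down = int((lfc < 0).sum())
    n_up = int((lfc > 0).sum())
    if n_up + n_down == 0:
        raise ValueError("no non-zero fold changes")
    return DirectionSummary(n_up=n_up, n_down=n_down, n_zero=n_zero)


def joint_direction_probability(p: float, k: int) -> float:
    """P(k independent random genes all share the direction) = p ** k.

    Computed in log space for stability at large k; treats genes as
    independent Bernoulli(p) draws.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if k < 0:
        raise ValueError("k must be >= 0")
    if k == 0:
        return 1.0
    if p == 0.0:
        return 0.0
    return math.exp(k * math.log(p))


def direction_tail_probability(p: float, k: int, at_least: int) -> float:
    """Exact binomial generalization: P(X >= at_least) for X ~ Bin(k, p)."""
    from scipy.stats import binom

    if at_least <= 0:
        return 1.0
    return float(binom.sf(at_least - 1, k, p))


def panel_summary(
    table: RegulationTable | pd.DataFrame,
    panel: list[str],
    fc_cutoff: float = 1.5,
    fdr_cutoff: float = 0.05,
    two_sided: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Per-gene regulation status for a panel (e.g. the glycolytic enzymes).

    ``significant`` means the linear fold change reaches ``fc_cutoff`` toward
    downregulation (or in either direction when ``two_sided``) at
    FDR < ``fdr_cutoff``.  Panel genes missing from the table are reported,
    never dropped silently.  Returns the per-gene frame plus counts:
    present / missing / downregulated / significant.
    """
    df = table.table if isinstance(table, RegulationTable) else table
    df = df.set_index("gene") if "gene" in df.columns else df
    missing = [g for g in panel if g not in df.index]
    present = [g for g in panel if g in df.index]
    sub = df.loc[present]
    lfc = sub["log2fc"].to_numpy(float)
    fdr = sub["fdr"].to_numpy(float)
    log2_cut = np.log2(fc_cutoff)
    if two_sided:
        passes_fc = np.abs(lfc) >= log2_cut
    else:
        passes_fc = lfc <= -log2_cut
    significant = passes_fc & (fdr < fdr_cutoff)
    out = pd.DataFrame(
        {
            "log2fc": lfc,
            "fdr": fdr,
            "direction": np.where(lfc < 0, "down", "up"),
            "significant": significant,
        },
        index=pd.Index(present, name="gene"),
    )
    counts = {
        "n_panel": len(panel),
        "n_present": len(present),
        "n_missing": len(missing),
        "missing": missing,
        "n_down": int((lfc < 0).sum()),
        "n_up": int((lfc > 0).sum()),
        "n_significant": int(significant.sum()),
    }
    return out, counts
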