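"""Per-gene fold-change + rank-sum screen of one subtype against the rest.

For each gene the fold change (FC) is the ratio of mean expression in the
target group (e.g. TNBC) over the rest, computed on the linear scale after
back-transforming log2 intensities; the p-value is a two-sided Wilcoxon
rank-sum test.  Genes are classified overexpressed (FC >= 1.2, p < 0.05),
underexpressed (FC <= 0.8, p < 0.05) or neutral; thresholds inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .datatypes import CohortTable, ValidationError


@dataclass(frozen=True)
class GeneScreenRecord:
    gene: str
    fc: float
    log2fc: float
    p: float
    klass: str  # overexpressed | underexpressed | neutral


def _has_ties(a: np.ndarray, b: np.ndarray) -> bool:
    both = np.concatenate([a, b])
    return len(np.unique(both)) < len(both)


def ranksum_p(group1: np.ndarray, group0: np.ndarray) -> float:
    """Two-sided rank-sum p: exact when both groups <= 10 and tie-free,
    normal approximation with continuity and tie correction otherwise."""
    if np.all(np.concatenate([group1, group0]) == group1[0]):
        return 1.0  # degenerate: every observation tied, no evidence either way
    exact = min(len(group1), len(group0)) <= 10 and not _has_ties(group1, group0)
    res = mannwhitneyu(
        group1, group0,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return float(res.pvalue)


def group_fold_change(
    values: np.ndarray,
    groups: np.ndarray,
    scale: str = "log2",
    fc_on_log_means: bool = False,
) -> tuple[float, float]:
    """Fold change (group 1 over group 0 means) and rank-sum p for one gene.

    ``scale='log2'`` linearizes with ``2**x`` before averaging (default,
    since fold change on intensity data conventionally means the ratio of
    linear means); ``fc_on_log_means=True`` instead ratios the raw means as
    a sensitivity mode.  The rank-sum test is scale-invariant.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups).astype(bool)
    g1, g0 = values[groups], values[~groups]
    if len(g1) < 2 or len(g0) < 2:
        raise ValueError("each group needs at least 2 samples")
    if scale not in ("log2", "linear"):
        raise ValueError(f"unknown scale {scale!r}")
    if scale == "log2" and not fc_on_log_means:
        m1, m0 = np.exp2(g1).mean(), np.exp2(g0).mean()
    else:
        m1, m0 = g1.mean(), g0.mean()
    if m0 <= 0:
        raise ValueError("reference-group mean is not positive; cannot form a ratio")
    return m1 / m0, ranksum_p(g1, g0)


def classify(fc: float, p: float, over: float, under: float, alpha: float) -> str:
    if p < alpha and fc >= over:
        return "overexpressed"
    if p < alpha and fc <= under:
        return "underexpressed"
    return "neutral"


def expression_screen(
    cohort: CohortTable,
    target_group: str = "TNBC",
    over_threshold: float = 1.2,
    under_threshold: float = 0.8,
    alpha: float = 0.05,
    scale: str = "log2",
    fc_on_log_means: bool = False,
) -> pd.DataFrame:
    """Screen every gene for differential expression in ``target_group``.

    Returns one row per gene with fc, log2fc, p, class and -log10 p (volcano
    coordinates).  Classification per ``classify`` with inclusive thresholds.
    """
    if not under_threshold < 1.0 < over_threshold:
        raise ValidationError("thresholds must satisfy under < 1 < over")
    mask = cohort.group_mask(target_group)
    rows = []
    for gene in cohort.genes:
        fc, p = group_fold_change(
            cohort.expression.loc[gene].to_numpy(float), mask,
            scale=scale, fc_on_log_means=fc_on_log_means,
        )
        rows.append(
            {
                "gene": gene,
                "fc": fc,
                "log2fc": np.log2(fc),
                "p": p,
                "neg_log10_p": -np.log10(p) if p > 0 else np.inf,
                "class": classify(fc, p, over_threshold, under_threshold, alpha),
            }
        )
    return pd.DataFrame(rows).set_index("gene")
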