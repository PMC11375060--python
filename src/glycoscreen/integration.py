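"""Expression–metabolomics integration over a cell-line panel.

For each gene, lines are ranked by expression and the upper/lower tertiles
labeled HIGH/LOW (middle tertile set aside).  Per metabolite, the fold
change between the HIGH-group and LOW-group mean concentrations (linear
scale, back-transformed from log10) is stored as log2 FC, with a two-sided
rank-sum test per (gene, metabolite) pair; metabolites significant in at
least ``min_comparisons`` gene stratifications are retained.  Retained FC
matrices are clustered with Ward's method (Euclidean distance) to expose
the glycolytic vs fatty-acid-oxidation axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import mannwhitneyu

from .datatypes import CellLinePanel


@dataclass
class MetaboliteFCMatrix:
    """Gene-stratification x metabolite log2 FC with significance mask."""

    log2fc: pd.DataFrame  # genes x metabolites
    sig_mask: pd.DataFrame  # boolean, same shape
    retained: list[str]  # metabolites significant in >= min_comparisons rows

    @property
    def retained_log2fc(self) -> pd.DataFrame:
        return self.log2fc[self.retained]


@dataclass(frozen=True)
class Dendrogram:
    """Ward merge tree: scipy linkage matrix + labels in input order."""

    linkage: np.ndarray  # (n-1, 4) scipy format
    labels: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    @property
    def leaf_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.linkage)
        return [self.labels[i] for i in order]

    def cut(self, n_clusters: int) -> pd.Series:
        assign = hierarchy.fcluster(self.linkage, n_clusters, criterion="maxclust")
        return pd.Series(assign, index=self.labels)

    def to_newick(self) -> str:
        """Serialize the merge tree as a Newick string with merge heights."""
        n = len(self.labels)
        height = {i: 0.0 for i in range(n)}
        node = {i: self.labels[i] for i in range(n)}
        for k, (a, b, h, _) in enumerate(self.linkage):
            a, b = int(a), int(b)
            la = h - height[a]
            lb = h - height[b]
            node[n + k] = f"({node[a]}:{la:.6g},{node[b]}:{lb:.6g})"
            height[n + k] = h
        return node[n + len(self.linkage) - 1] + ";"


def tertile_labels(values: pd.Series) -> pd.Series:
    """LOW / MID / HIGH tertile labels for one gene across the panel.

    Lines are ranked ascending; the bottom floor(n/3) are LOW, the top
    floor(n/3) HIGH.  Ties are broken by a stable sort on (value, line id),
    so the labeling is deterministic even for constant input.
    """
    values = pd.Series(values)
    n = len(values)
    if n < 6:
        raise ValueError("tertile labeling needs at least 6 lines")
    k = n // 3
    order = values.to_frame("v").assign(_id=values.index.astype(str))
    order = order.sort_values(["v", "_id"], kind="stable").index
    labels = pd.Series("MID", index=values.index, dtype=object)
    labels[order[:k]] = "LOW"
    labels[order[n - k:]] = "HIGH"
    return labels


def metabolite_fc_matrix(
    panel: CellLinePanel,
    genes=None,
    alpha: float = 0.05,
    min_comparisons: int = 2,
    linear_means: bool = True,
) -> MetaboliteFCMatrix:
    """Per-gene HIGH-vs-LOW metabolite fold changes with the >=2-hit filter.

    Metabolite means are taken on the linear scale (10**x back-transform of
    the log10 matrix) because the quantity of interest is the average
    concentration; ``linear_means=False`` averages on the log scale instead.
    Significance per pair is a two-sided rank-sum HIGH vs LOW at ``alpha``
    (uncorrected).
    """
    genes = list(genes) if genes is not None else list(panel.expression.index)
    metab_log10 = panel.metabolites
    metab_lin = np.power(10.0, metab_log10)
    fc_rows, sig_rows = [], []
    for gene in genes:
        labels = tertile_labels(panel.expression.loc[gene])
        hi = (labels == "HIGH").to_numpy()
        lo = (labels == "LOW").to_numpy()
        if not hi.any() or not lo.any():
            raise ValueError(f"empty tertile group for gene {gene!r}")
        if linear_means:
            mh = metab_lin.loc[:, hi].mean(axis=1)
            ml = metab_lin.loc[:, lo].mean(axis=1)
            fc = mh / ml
        else:
            fc = np.power(
                10.0, metab_log10.loc[:, hi].mean(axis=1) - metab_log10.loc[:, lo].mean(axis=1)
            )
        fc_rows.append(np.log2(fc))
        with warnings.catch_warnings(), np.errstate(invalid="ignore"):
            warnings.simplefilter("ignore")
            pvals = mannwhitneyu(
                metab_log10.loc[:, hi].to_numpy(),
                metab_log10.loc[:, lo].to_numpy(),
                alternative="two-sided",
                axis=1,
            ).pvalue
        pvals = np.where(np.isnan(pvals), 1.0, pvals)  # all-tied rows
        sig_rows.append(pvals < alpha)
    log2fc = pd.DataFrame(fc_rows, index=genes, columns=metab_log10.index)
    sig = pd.DataFrame(sig_rows, index=genes, columns=metab_log10.index)
    retained = list(sig.columns[sig.sum(axis=0) >= min_comparisons])
    return MetaboliteFCMatrix(log2fc=log2fc, sig_mask=sig, retained=retained)


def ward_cluster(matrix: pd.DataFrame, axis: str = "rows") -> Dendrogram:
    """Agglomerative Ward clustering (Euclidean distance) of rows or columns."""
    if axis not in ("rows", "columns"):
        raise ValueError("axis must be 'rows' or 'columns'")
    X = matrix if axis == "rows" else matrix.T
    if X.shape[0] < 2:
        raise ValueError("need at least 2 items to cluster")
    arr = X.to_numpy(float)
    if not np.isfinite(arr).all():
        raise ValueError("matrix contains missing or non-finite values")
    Z = hierarchy.linkage(arr, method="ward", metric="euclidean")
    return Dendrogram(linkage=Z, labels=[str(i) for i in X.index])
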