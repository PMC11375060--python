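"""Monte Carlo null for gene-set enrichment of prognostic flags.

Question: given that K of the N genes in a cohort are prognostic, how
surprising is it that >= m genes of a k-gene family are?  The null draws
random k-gene sets uniformly without replacement from the universe and
counts how many contain at least m flagged genes; the closed-form answer is
the upper tail of a hypergeometric distribution, used here as the exact
oracle the empirical null must agree with.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom


@dataclass(frozen=True)
class MonteCarloResult:
    n_universe: int
    n_significant_universe: int
    set_size: int
    threshold: int
    n_sets: int
    n_exceed: int
    p_empirical: float
    seed: int

    @property
    def p_conservative(self) -> float:
        """(n_exceed + 1) / (n_sets + 1) — the add-one permutation variant."""
        return (self.n_exceed + 1) / (self.n_sets + 1)


def hypergeometric_tail(
    n_universe: int, n_significant: int, set_size: int, threshold: int
) -> float:
    """P(X >= threshold) for X ~ Hypergeometric(n_universe, n_significant,
    set_size): the exact sampling-without-replacement null."""
    if not 0 <= n_significant <= n_universe:
        raise ValueError("need 0 <= n_significant <= n_universe")
    if not 0 <= set_size <= n_universe:
        raise ValueError("need 0 <= set_size <= n_universe")
    if threshold < 0 or threshold > set_size:
        if threshold <= 0:
            return 1.0
        return 0.0
    if threshold == 0:
        return 1.0
    return float(hypergeom.sf(threshold - 1, n_universe, n_significant, set_size))


def empirical_set_pvalue(
    flags,
    set_size: int,
    threshold: int,
    n_sets: int = 10_000,
    seed: int = 0,
    chunk: int = 512,
) -> MonteCarloResult:
    """Empirical p that a random gene set has >= threshold flagged members.

    Sets are drawn uniformly without replacement (independently of each
    other) from a counter-based Philox stream keyed by ``seed``, so a fixed
    seed reproduces the draws exactly.  The reported p is the raw ratio
    ``n_exceed / n_sets`` (no add-one correction); the conservative variant
    is available on the result.
    """
    flags = np.asarray(flags).astype(bool)
    n_universe = flags.size
    if set_size > n_universe:
        raise ValueError("set_size exceeds universe size")
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    rng = np.random.Generator(np.random.Philox(key=seed))
    n_exceed = 0
    done = 0
    while done < n_sets:
        m = min(chunk, n_sets - done)
        # vectorized sampling without replacement: the set_size smallest
        # random keys per row form a uniform random subset
        keys = rng.random((m, n_universe))
        idx = np.argpartition(keys, set_size - 1, axis=1)[:, :set_size]
        counts = flags[idx].sum(axis=1)
        n_exceed += int((counts >= threshold).sum())
        done += m
    return MonteCarloResult(
        n_universe=n_universe,
        n_significant_universe=int(flags.sum()),
        set_size=set_size,
        threshold=threshold,
        n_sets=n_sets,
        n_exceed=n_exceed,
        p_empirical=n_exceed / n_sets,
        seed=seed,
    )
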