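"""Tertile stratification, metabolite fold-change matrix, and Ward
clustering against a brute-force agglomeration oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest

import glycoscreen as gs
from glycoscreen.integration import tertile_labels, ward_cluster


# ------------------------------------------------------------------- tertiles

def test_tertile_counts_and_error():
    labels = tertile_labels(pd.Series([3.0, 1, 2, 6, 5, 4],
                                      index=list("abcdef")))
    assert (labels == "LOW").sum() == 2
    assert (labels == "HIGH").sum() == 2
    assert (labels == "MID").sum() == 2
    assert labels["b"] == "LOW" and labels["d"] == "HIGH"
    with pytest.raises(ValueError):
        tertile_labels(pd.Series([1.0, 2, 3, 4, 5]))


def test_tertile_counts_floor_rule():
    for n in (6, 7, 8, 9, 46):
        vals = pd.Series(np.arange(n, dtype=float), index=[f"L{i}" for i in range(n)])
        labels = tertile_labels(vals)
        assert (labels == "LOW").sum() == n // 3
        assert (labels == "HIGH").sum() == n // 3


def test_tertile_ties_broken_by_identifier():
    vals = pd.Series(np.zeros(6), index=list("fedcba"))
    labels = tertile_labels(vals)
    # stable sort on (value, id): 'a','b' lowest, 'e','f' highest
    assert labels["a"] == "LOW" and labels["b"] == "LOW"
    assert labels["e"] == "HIGH" and labels["f"] == "HIGH"
    assert list(tertile_labels(vals)) == list(tertile_labels(vals))


def test_lowest_ranked_line_is_low():
    vals = pd.Series(np.random.default_rng(0).normal(size=9),
                     index=[f"L{i}" for i in range(9)])
    labels = tertile_labels(vals)
    assert labels[vals.idxmin()] == "LOW"


# ------------------------------------------------------------------ FC matrix

def _toy_panel():
    """6 lines; gene g orders lines 0..5; metabolite HIGH-mean 2x LOW-mean."""
    lines = [f"L{i}" for i in range(6)]
    expr = pd.DataFrame([[0.0, 1, 2, 3, 4, 5]], index=["g"], columns=lines)
    # linear values: LOW lines {1,1}, HIGH lines {2,2} -> log10
    metab = pd.DataFrame(
        [np.log10([1.0, 1.0, 5.0, 5.0, 2.0, 2.0])], index=["m"], columns=lines
    )
    return gs.CellLinePanel(expression=expr, metabolites=metab)


def test_fc_forced_arithmetic():
    fcm = gs.metabolite_fc_matrix(_toy_panel(), alpha=0.05, min_comparisons=1)
    assert fcm.log2fc.loc["g", "m"] == pytest.approx(1.0)


def test_constant_metabolite_never_significant():
    panel = _toy_panel()
    panel.metabolites.loc["m"] = 0.5
    fcm = gs.metabolite_fc_matrix(panel, min_comparisons=1)
    assert fcm.log2fc.loc["g", "m"] == pytest.approx(0.0)
    assert not fcm.sig_mask.loc["g", "m"]
    assert "m" not in fcm.retained


def test_fc_invariant_under_concentration_rescaling():
    panel = _toy_panel()
    fcm1 = gs.metabolite_fc_matrix(panel, min_comparisons=1)
    panel.metabolites.loc["m"] += np.log10(7.5)  # multiply linear values by 7.5
    fcm2 = gs.metabolite_fc_matrix(panel, min_comparisons=1)
    assert fcm1.log2fc.loc["g", "m"] == pytest.approx(fcm2.log2fc.loc["g", "m"])


def test_log_mean_mode_differs():
    lines = [f"L{i}" for i in range(6)]
    expr = pd.DataFrame([[0.0, 1, 2, 3, 4, 5]], index=["g"], columns=lines)
    metab = pd.DataFrame([np.log10([1.0, 4.0, 1, 1, 2.0, 9.0])],
                         index=["m"], columns=lines)
    panel = gs.CellLinePanel(expression=expr, metabolites=metab)
    lin = gs.metabolite_fc_matrix(panel, min_comparisons=1).log2fc.loc["g", "m"]
    logm = gs.metabolite_fc_matrix(panel, min_comparisons=1,
                                   linear_means=False).log2fc.loc["g", "m"]
    assert lin != pytest.approx(logm)


def test_planted_block_sign_recovery():
    cfg = gs.SimConfig(seed=2, n_lines=46, n_genes=20, n_metabolites=40)
    panel = gs.simulate_cellline_panel(cfg)
    fcm = gs.metabolite_fc_matrix(panel)
    informative = panel.gene_modules[panel.gene_modules != "null"].index
    kept = [m for m in fcm.retained if panel.metabolite_blocks[m] != "null"]
    assert len(kept) >= 10
    signs = np.sign(fcm.log2fc.loc[informative, kept].to_numpy())
    expected = np.outer(
        [1 if panel.gene_modules[g] == "glycolytic" else -1 for g in informative],
        [1 if panel.metabolite_blocks[m] == "glycolytic" else -1 for m in kept],
    )
    assert (signs == expected).mean() > 0.95


def test_null_blocks_pass_filter_at_nominal_rate():
    """With no planted correlation, metabolites should clear the >=2-hit
    filter no more often than chance predicts (the exact rank-sum test is
    conservative, so only the upper bound is binding)."""
    from scipy.stats import binom

    n_genes, n_met, alpha = 6, 30, 0.05
    passes = total = 0
    for seed in range(5):
        cfg = gs.SimConfig(seed=seed, n_lines=24, n_genes=n_genes,
                           n_metabolites=n_met,
                           block_structure={"glycolytic": 0.0, "fao": 0.0})
        fcm = gs.metabolite_fc_matrix(gs.simulate_cellline_panel(cfg), alpha=alpha)
        passes += len(fcm.retained)
        total += n_met
    # P(significant in >=2 of 6 independent tests at level alpha)
    p_pass = float(binom.sf(1, n_genes, alpha))
    bound = p_pass + 3.0 * np.sqrt(p_pass * (1 - p_pass) / total)
    assert passes / total <= bound


# ----------------------------------------------------------------------- Ward

def bruteforce_ward(points):
    """Exhaustive agglomeration: at each step merge the pair minimizing the
    Ward distance, recomputed from raw points (independent of scipy)."""
    clusters = [[i] for i in range(len(points))]
    pts = np.asarray(points, float)
    if pts.ndim == 1:
        pts = pts[:, None]
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            ca, cb = pts[clusters[a]], pts[clusters[b]]
            na, nb = len(ca), len(cb)
            d2 = ((ca.mean(0) - cb.mean(0)) ** 2).sum()
            ward = np.sqrt(2.0 * na * nb / (na + nb) * d2)
            if best is None or ward < best[0]:
                best = (ward, a, b)
        h, a, b = best
        heights.append(h)
        merged = clusters[a] + clusters[b]
        clusters = [c for i, c in enumerate(clusters) if i not in (a, b)]
        clusters.append(merged)
    return np.array(heights)


def test_ward_identical_rows_merge_at_zero():
    m = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]],
                     index=["a", "b", "c"])
    dend = ward_cluster(m, "rows")
    assert dend.heights[0] == pytest.approx(0.0)


def test_ward_heights_match_bruteforce_oracle():
    points = [0.0, 1.0, 10.0]
    m = pd.DataFrame({"x": points}, index=["p0", "p1", "p10"])
    dend = ward_cluster(m, "rows")
    np.testing.assert_allclose(np.sort(dend.heights),
                               np.sort(bruteforce_ward(points)), rtol=1e-10)
    # first merge is the close pair
    assert set(dend.cut(2)[["p0", "p1"]]) == {dend.cut(2)["p0"]}
    rng = np.random.default_rng(3)
    pts2 = rng.normal(size=(6, 3))
    m2 = pd.DataFrame(pts2, index=[f"r{i}" for i in range(6)])
    np.testing.assert_allclose(np.sort(ward_cluster(m2, "rows").heights),
                               np.sort(bruteforce_ward(pts2)), rtol=1e-8)


def test_ward_permutation_changes_only_leaf_order():
    rng = np.random.default_rng(4)
    m = pd.DataFrame(rng.normal(size=(8, 4)), index=[f"r{i}" for i in range(8)])
    perm = m.sample(frac=1.0, random_state=1)
    h1 = np.sort(ward_cluster(m, "rows").heights)
    h2 = np.sort(ward_cluster(perm, "rows").heights)
    np.testing.assert_allclose(h1, h2, rtol=1e-10)


def test_ward_rejects_missing_values_and_single_item():
    m = pd.DataFrame([[1.0, np.nan], [2.0, 3.0]])
    with pytest.raises(ValueError):
        ward_cluster(m, "rows")
    with pytest.raises(ValueError):
        ward_cluster(pd.DataFrame([[1.0, 2.0]]), "rows")


def test_newick_roundtrip_leaves():
    import io as _io

    from Bio import Phylo

    m = pd.DataFrame(np.random.default_rng(5).normal(size=(5, 3)),
                     index=["a", "b", "c", "d", "e"])
    nwk = ward_cluster(m, "rows").to_newick()
    tree = Phylo.read(_io.StringIO(nwk), "newick")
    assert sorted(t.name for t in tree.get_terminals()) == ["a", "b", "c", "d", "e"]
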