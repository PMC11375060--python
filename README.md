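# glycoscreen

Prognostic gene screening and glycolytic-metabolism integration for
breast-cancer cohorts, with a synthetic-data generator that makes the whole
pipeline testable without external downloads.

## What it is for

Studies of gene families in cancer cohorts repeatedly need the same chain
of analyses: *is the family differentially expressed in an aggressive
subtype?  Do its members predict survival?  Is the number of prognostic
members more than chance?  Does expression track a metabolic phenotype
across cell lines?  Do functional assays and imaging confirm the
mechanism?*  `glycoscreen` implements that chain as a reusable library for
the triple-negative breast cancer (TNBC) / glycolysis setting:

* **Subtype screen** — per-gene fold change (ratio of linear-scale group
  means) of TNBC vs all other subtypes with a two-sided Wilcoxon rank-sum
  test; classification at FC ≥ 1.2 / ≤ 0.8, p < 0.05.
* **Survival screen** — Kaplan–Meier estimation; univariate and
  multivariable Cox proportional-hazards fits (Efron ties, Wald
  inference); HR-per-SD gene screening at HR ≥ 1.2 / ≤ 0.8, p < 0.01;
  mean-split HIGH/LOW markers; early ([0,5) y) and late (5–20 y, landmark)
  windows; odds ratios with Woolf CIs and Pearson chi-square for 2×2
  tables.
* **Monte Carlo gene-set null** — P(random k-gene set contains ≥ m
  prognostic genes) by resampling without replacement, with the exact
  hypergeometric tail as built-in oracle.
* **Metabolomic integration** — per-gene tertile HIGH/LOW stratification
  of a cell-line panel, metabolite fold-change matrices (linear-scale
  means of log10 concentrations) with a ≥ 2-comparison significance
  filter, and Ward/Euclidean clustering with Newick export.
* **Assay metrics** — lactate-screen hit calling (≥ 30% drop + rank-sum
  p < 0.05), glycolysis / glycolytic capacity and basal / maximal
  respiration from extracellular-flux traces, energy-map quadrants, and
  the glucose-uptake rate formula ([2DG6P]·volume)/(cells·time).
* **Regulation statistics** — up/down direction proportions of a
  knockdown differential-expression table and the coordinated-
  downregulation probability p_down^k.
* **Image quantification** — per-cell membrane localization via a 600 nm
  boundary "corona": total marker intensity and the mean-corona /
  mean-cell intensity ratio, from exact Euclidean distance transforms.
* **Synthetic data** — generators for all of the above with planted,
  recoverable effects (subtype shifts, per-SD log hazard ratios,
  gene-module↔metabolite-block correlations, direction proportions,
  membrane fractions).

See `docs/methods.md` for models, defaults and numerical choices.

## Worked example

Plant a twofold-per-SD hazard gene in a simulated cohort and screen it:

```python
import numpy as np
import glycoscreen as gs

cfg = gs.SimConfig(seed=2, n_samples=800, n_genes=8,
                   planted_log_hr={"G0001": float(np.log(1.8))})
cohort = gs.simulate_cohort(cfg)
screen = gs.prognostic_screen(cohort, hr_hi=1.2, hr_lo=0.8, alpha=0.01)
print(screen.loc[screen["significant_uni"],
                 ["hr_uni", "ci_low", "ci_high", "p_uni"]])
```

```
         hr_uni    ci_low   ci_high         p_uni
gene
G0001  1.776452  1.547517  2.039256  3.265785e-16
```

The planted gene (true HR 1.8 per SD of expression) is the only one
flagged: its estimated hazard ratio is 1.78 with a 95% CI covering the
truth, and it survives multivariable adjustment for age, tumor size, nodal
status, hormone-receptor status, HER2 and grade.  The `examples/`
directory holds one narrative script per capability (subtype screen,
survival, Monte Carlo null, integration, assays, corona imaging,
regulation statistics); each prints its numbers with a line on what they
mean.

A thin CLI mirrors the stages for shell use:

```bash
glycoscreen simulate --seed 4 --out sim/
glycoscreen de   --expression sim/expression.tsv --samples sim/samples.tsv --out de.tsv
glycoscreen mc   --flags flags.tsv --set-size 44 --threshold 10 --n-sets 10000 --seed 1 --out mc.json
```

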