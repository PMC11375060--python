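"""Per-gene prognostic Cox screen with early/late follow-up windows on a
simulated cohort with one planted hazard gene."""

import numpy as np

import glycoscreen as gs

cfg = gs.SimConfig(seed=2, n_samples=800, n_genes=8,
                   planted_log_hr={"G0001": float(np.log(1.8))})
cohort = gs.simulate_cohort(cfg)

screen = gs.prognostic_screen(cohort, hr_hi=1.2, hr_lo=0.8, alpha=0.01)
cols = ["hr_uni", "ci_low", "ci_high", "p_uni", "significant_uni",
        "hr_multi", "significant_multi"]
print(screen.loc[screen["significant_uni"], cols])
print()
print("hr_uni is the hazard ratio per SD of expression for death related to")
print("disease; the planted gene (true HR 1.8) passes the HR/P criterion and")
print("stays significant after covariate adjustment (hr_multi).")

# Kaplan-Meier by mean-split marker, early window
vals = cohort.expression.loc["G0001"].to_numpy(float)
labels = gs.dichotomize_by_mean(vals)
t, e = gs.restrict_window(cohort.samples["time"], cohort.samples["event"],
                          "early")
for grp in ("HIGH", "LOW"):
    est = gs.km_estimate(t[labels == grp], e[labels == grp])
    last = est.survival[-1] if est.times.size else 1.0
    print(f"KM 5-year survival, marker {grp}: {last:.3f}")
print("HIGH-expressing patients fare worse, as planted.")
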