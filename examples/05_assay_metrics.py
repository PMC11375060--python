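"""Flux-assay parameter extraction, lactate hit-calling, the energy map and
the glucose-uptake rate formula."""

import pandas as pd

import glycoscreen as gs


def trace(phase_rates, cells=2.0e4, phases=gs.assay.GLYCOLYSIS_PHASES):
    rows = [("w1", ph, t, r, cells)
            for ph, rates in phase_rates.items() for t, r in enumerate(rates)]
    return gs.SeahorseTrace(
        pd.DataFrame(rows, columns=["well", "phase", "timepoint", "rate", "cells"]),
        phases=phases)


ecar = trace({"baseline": [9.0, 10.0], "glucose": [38.0, 40.0],
              "oligomycin": [58.0, 60.0], "2dg": [11.0, 10.0]})
p = gs.glycolysis_params(ecar)
print(f"glycolysis          = {p.glycolysis * 2e4:.1f} mpH/min/2e4 cells")
print(f"glycolytic capacity = {p.glycolytic_capacity * 2e4:.1f}")
print("(post-glucose and post-oligomycin ECAR minus the non-glycolytic")
print(" floor measured after 2-deoxyglucose, per cell)")

lactate = pd.DataFrame(
    [("control", v) for v in (0.98, 1.02, 0.99, 1.01)]
    + [("siGENE1", v) for v in (0.55, 0.60, 0.58, 0.57)]
    + [("siGENE2", v) for v in (0.95, 0.90, 1.00, 0.92)],
    columns=["condition", "value"])
hits = gs.lactate_hit_call(lactate, control="control", cutoff=0.70)
print()
print(hits[["mean_ratio", "p", "hit"]])
print("a hit needs a >= 30% drop in per-cell lactate AND rank-sum p < 0.05")

em = gs.energy_map(pd.Series({"ctrl": 10.0, "kd": 6.0}),
                   pd.Series({"ctrl": 40.0, "kd": 25.0}), "ctrl")
print()
print(em)
print("the knockdown shifts from the energetic toward the quiescent quadrant")

rate = gs.glucose_uptake_rate(10.0, 50.0, 10_000, 10.0)
print(f"\nglucose uptake rate = {rate} fmol/cell/min "
      "([2DG6P] x volume / (cells x minutes))")
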