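"""Coordinated-downregulation statistics on a knockdown regulation table."""

import glycoscreen as gs

cfg = gs.SimConfig(seed=6, n_regulated=17329, p_down=0.535)
table = gs.simulate_regulation_table(cfg)

summ = gs.direction_proportions(table)
print(f"{summ.n_down} of {summ.n_total} genes downregulated "
      f"(p_down = {summ.p_down:.3f})")

k = 24
joint = gs.joint_direction_probability(summ.p_down, k)
print(f"P({k} random genes all downregulated) = p_down^{k} = {joint:.3g}")
print()
print("If a defined panel of 24 glycolytic genes is all downregulated, this")
print("probability says how (im)plausible that is under independent random")
print("direction assignment — a coordinated-regulation signature.")

panel = list(table.table["gene"].iloc[:6])
per_gene, counts = gs.panel_summary(table, panel, fc_cutoff=1.5,
                                    fdr_cutoff=0.05)
print(f"\npanel of {counts['n_panel']}: {counts['n_down']} down, "
      f"{counts['n_significant']} significantly so (|FC| >= 1.5, FDR < 0.05)")
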