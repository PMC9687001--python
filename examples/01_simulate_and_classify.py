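"""Generate a synthetic fraction-profiling experiment and classify modes.

Prints the per-stage mode table and how well the classifier recovers the
planted labels (evaluated on genes without program/trend dynamics, whose
planted mode is stage-stable).
"""

import pandas as pd

import polymodes as pm

cfg = pm.GeneratorConfig(n_genes=2000, seed=7)
sim = pm.generate(cfg)
tpm = pm.compute_tpm(sim.counts, sim.annotation["transcript_length"])

assigns = pd.concat(
    [pm.classify_stage(tpm, sim.sheet, s) for s in pm.STAGES],
    ignore_index=True)

print("mode counts per stage (columns are modes; none = unclassified):")
print(assigns.pivot_table(index="stage", columns="mode", values="gene_id",
                          aggfunc="count", fill_value=0))

truth = sim.truth_genes
clean = truth.index[(truth["program"] == "neither") & (truth["trend_slope"] == 0)]
merged = assigns.merge(truth[["mode"]].rename(columns={"mode": "true_mode"}),
                       left_on="gene_id", right_index=True)
m = merged[merged["gene_id"].isin(clean) & (merged["true_mode"] != "background")]
for mode in "1234":
    recall = (m.loc[m["true_mode"] == mode, "mode"] == mode).mean()
    print(f"planted mode {mode}: recall {recall:.1%}")
print("A recall near 1 means the rule lattice recovers what the generator "
      "planted; mode 2/3 sit closest to the tertile cuts and recover lowest.")

print("\nmedian TE per mode at GV (expected ordering 1 > 2 > 3):")
gv = assigns.query("stage == 'GV'")
print(gv.groupby("mode")["TE"].median().round(3))
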