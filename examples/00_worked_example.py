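"""Classify the hand-verified 12-gene fixture and print every quantity.

The fixture is built so TPM = 100 x count and all TE/CPE values can be
checked by hand (see examples/worked_example/README.md).
"""

import polymodes as pm

cm, annot, expected = pm.worked_example()
tpm = pm.compute_tpm(cm, annot["transcript_length"])

for stage in ("GV", "8C"):
    res = pm.classify_stage(tpm, cm.samples, stage).set_index("gene_id")
    print(f"\n=== {stage} ===")
    cols = res[["A", "P", "M", "TE", "rho", "mode"]].round(4)
    print(cols.to_string())
    exp = expected.query("stage == @stage").set_index("gene_id")["mode"]
    agree = (res["mode"].loc[exp.index] == exp).all()
    print(f"modes match the documented labels: {agree}")

feats = pm.utr_features(annot)
print("\nCPE counts per 3'UTR (g_mat holds the overlapping TTTTATTTTAT pair):")
print(feats["cpe_count"].to_dict())
print("genes retained by the >100 nt UTR filter:",
      list(pm.utr_filter(annot)))
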