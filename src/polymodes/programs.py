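"""Maternal / embryonic program classification.

Maternal transcripts are deposited in the oocyte before fertilization and
degraded after embryonic genome activation (EGA; major EGA at the
eight-cell stage in bovine); embryonic transcripts are produced by the
embryo's own genome.  Operationally:

* maternal — strongly upregulated (FDR < 0.05, FC > 4) toward the oocyte
  in BOTH the GV-vs-late and MII-vs-late transcriptome contrasts, where
  "late" pools the eight-cell, morula and blastocyst stages;
* embryonic — strongly upregulated (same gates) toward the late pool in
  the late-vs-oocyte contrast (oocyte pool = GV + MII);
* neither — everything else.

The pooled three-stage contrast is the default; ``pairwise=True`` demands
the gate in every pairwise stage contrast instead.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io import CountMatrix
from .normalize import de_two_group

LATE_STAGES = ("8C", "MOR", "BL")
OOCYTE_STAGES = ("GV", "MII")


def classify_programs(de_gv: pd.DataFrame, de_mii: pd.DataFrame,
                      de_late: pd.DataFrame, log2fc: float = 2.0,
                      fdr: float = 0.05) -> pd.DataFrame:
    """Label genes maternal / embryonic / neither from three DE tables.

    ``de_gv`` and ``de_mii`` must be oriented oocyte-positive (log2FC > 0
    means higher in the oocyte stage than in the pooled late stages);
    ``de_late`` late-positive.  Gates: log2FC > ``log2fc`` (FC > 4) and
    fdr < ``fdr`` — maternal requires both oocyte contrasts to pass.
    """
    tabs = {"gv": de_gv, "mii": de_mii, "late": de_late}
    genes = de_gv["gene_id"]
    for name, tab in tabs.items():
        if not tab["gene_id"].equals(genes):
            raise ValueError(f"DE table {name!r} is not on the same gene universe")
    gv_up = (de_gv["log2FC"] > log2fc) & (de_gv["fdr"] < fdr)
    mii_up = (de_mii["log2FC"] > log2fc) & (de_mii["fdr"] < fdr)
    late_up = (de_late["log2FC"] > log2fc) & (de_late["fdr"] < fdr)
    maternal = (gv_up & mii_up).to_numpy()
    embryonic = late_up.to_numpy() & ~maternal
    label = np.where(maternal, "maternal", np.where(embryonic, "embryonic", "neither"))
    return pd.DataFrame({
        "gene_id": genes,
        "label": label,
        "log2FC_gv": de_gv["log2FC"], "fdr_gv": de_gv["fdr"],
        "log2FC_mii": de_mii["log2FC"], "fdr_mii": de_mii["fdr"],
        "log2FC_late": de_late["log2FC"], "fdr_late": de_late["fdr"],
    })


def run_program_contrasts(counts: CountMatrix, pairwise: bool = False,
                          log2fc: float = 2.0, fdr: float = 0.05,
                          **de_kwargs) -> pd.DataFrame:
    """Run the transcriptome contrasts and classify programs.

    Uses only transcriptome samples.  With ``pairwise=True`` the maternal
    (embryonic) gate must hold in every oocyte-stage-vs-late-stage
    (late-vs-oocyte) pairwise contrast rather than against the pooled
    group.
    """
    sheet = counts.samples
    trans = counts.subset_samples(sheet["sample_type"] == "transcriptome")
    stages = trans.samples["stage"]
    if not pairwise:
        group = np.where(stages.isin(LATE_STAGES), "late",
                         np.where(stages.isin(OOCYTE_STAGES), stages, "other"))
        keep_gv = np.isin(group, ["GV", "late"])
        keep_mii = np.isin(group, ["MII", "late"])
        de_gv = de_two_group(trans.counts.loc[:, keep_gv], group[keep_gv],
                             "GV", "late", **de_kwargs)
        de_mii = de_two_group(trans.counts.loc[:, keep_mii], group[keep_mii],
                              "MII", "late", **de_kwargs)
        pooled = np.where(stages.isin(LATE_STAGES), "late",
                          np.where(stages.isin(OOCYTE_STAGES), "oocyte", "other"))
        keep_late = np.isin(pooled, ["late", "oocyte"])
        de_late = de_two_group(trans.counts.loc[:, keep_late], pooled[keep_late],
                               "late", "oocyte", **de_kwargs)
        return classify_programs(de_gv, de_mii, de_late, log2fc=log2fc, fdr=fdr)
    # pairwise-AND variant
    genes = trans.genes
    mat_ok = np.ones(len(genes), dtype=bool)
    emb_ok = np.ones(len(genes), dtype=bool)
    store = {}
    for oo in OOCYTE_STAGES:
        for late in LATE_STAGES:
            keep = stages.isin([oo, late]).to_numpy()
            de = de_two_group(trans.counts.loc[:, keep], stages[keep], oo, late,
                              **de_kwargs)
            store[(oo, late)] = de
            mat_ok &= ((de["log2FC"] > log2fc) & (de["fdr"] < fdr)).to_numpy()
            emb_ok &= ((de["log2FC"] < -log2fc) & (de["fdr"] < fdr)).to_numpy()
    label = np.where(mat_ok, "maternal", np.where(emb_ok, "embryonic", "neither"))
    first = store[(OOCYTE_STAGES[0], LATE_STAGES[0])]
    return pd.DataFrame({"gene_id": genes, "label": label,
                         "log2FC_gv": first["log2FC"], "fdr_gv": first["fdr"]})


def mode_program_proportions(modes: pd.DataFrame, labels: pd.DataFrame) -> pd.DataFrame:
    """Maternal/embryonic/neither proportions within each (stage, mode).

    Proportions are counts of labelled genes in the mode divided by the
    mode's size, so the three sum to 1.  Empty modes yield an NA row with
    a warning.
    """
    lab = labels.set_index("gene_id")["label"]
    rows = []
    for (stage, mode), grp in modes[modes["mode"] != "none"].groupby(["stage", "mode"]):
        glab = lab.reindex(grp["gene_id"]).fillna("neither")
        n = len(grp)
        rows.append({
            "stage": stage, "mode": mode, "n_genes": n,
            "prop_maternal": (glab == "maternal").sum() / n,
            "prop_embryonic": (glab == "embryonic").sum() / n,
            "prop_neither": (glab == "neither").sum() / n,
        })
    observed = {(r["stage"], r["mode"]) for r in rows}
    for stage in modes["stage"].unique():
        for mode in ("1", "2", "3", "4"):
            if (stage, mode) not in observed:
                warnings.warn(f"empty mode {mode} at stage {stage}")
                rows.append({"stage": stage, "mode": mode, "n_genes": 0,
                             "prop_maternal": np.nan, "prop_embryonic": np.nan,
                             "prop_neither": np.nan})
    return pd.DataFrame(rows).sort_values(["stage", "mode"]).reset_index(drop=True)
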