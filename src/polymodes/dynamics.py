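"""Cross-stage translation / transcription dynamics.

Five analyses relate the translatome (polysome-bound mRNA, F8-F10) to the
transcriptome across the six developmental stages:

* :func:`stage_correlation` — per-stage Spearman correlation between every
  gradient fraction sample (F3-F10, each replicate) and the stage's mean
  transcriptome, summarized as mean +/- s.e.m.; a dip marks stages where
  polysome occupancy poorly reflects mRNA abundance (major EGA);
* :func:`polysome_vs_transcriptome_de` — NB-LRT contrast of polysome
  samples against transcriptome samples within a stage, with up/down sets
  at a configurable fold-change gate (FC > 8 by default here);
* :func:`persistence_flow` — per-gene Up/Down/NS trajectory strings across
  stages (the Sankey view of set persistence);
* :func:`stage_trend` — linear model of polysome log2(TPM+1) on the stage
  index controlling for fraction identity; the top-k most dynamic genes
  are ranked by FDR then |slope| (k = 90 by default);
* :func:`discordance` — per consecutive-stage transition, genes whose
  transcription and translation change significantly in opposite
  directions (gold: transcription down / translation up; blue: the
  reverse), plus the transition-level Spearman rho between the two log2FC
  vectors;
* :func:`stage_specific_sets` — one-vs-rest stage-specific highly
  translated / transcribed gene sets and their intersections.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .design import GRADIENT_FRACTIONS, POLYSOME_FRACTIONS, STAGE_INDEX, STAGES
from .io import CountMatrix
from .normalize import bh_adjust, de_two_group

TRANSITIONS = tuple(zip(STAGES[:-1], STAGES[1:]))


# ---------------------------------------------------------------------------
# translatome-transcriptome correlation (per stage)


def stage_correlation(tpm: pd.DataFrame, sheet: pd.DataFrame,
                      floor: float = 1.0, method: str = "spearman") -> pd.DataFrame:
    """Correlation of each F3-F10 fraction sample with the mean transcriptome.

    Computed on log2(TPM+1) over genes expressed (TPM >= ``floor``) in the
    fraction sample or the transcriptome vector.  Returns one row per
    (stage, fraction, replicate) plus per-stage summary columns mean_rho
    and sem_rho.
    """
    corr = stats.spearmanr if method == "spearman" else stats.pearsonr
    rows = []
    for stage in sheet["stage"].unique():
        trans = sheet[(sheet["stage"] == stage)
                      & (sheet["sample_type"] == "transcriptome")]
        frac = sheet[(sheet["stage"] == stage) & (sheet["sample_type"] == "fraction")
                     & sheet["fraction"].isin(GRADIENT_FRACTIONS)]
        if trans.empty or frac.empty:
            continue
        tvec = tpm[list(trans["sample_id"])].mean(axis=1)
        tlog = np.log2(tvec + 1.0)
        for _, s in frac.iterrows():
            fvec = tpm[s["sample_id"]]
            use = (fvec >= floor) | (tvec >= floor)
            rho = corr(np.log2(fvec[use] + 1.0), tlog[use])[0] if use.sum() > 2 else np.nan
            rows.append({"stage": stage, "fraction": int(s["fraction"]),
                         "replicate": int(s["replicate"]),
                         "sample_id": s["sample_id"], "rho": rho,
                         "n_genes": int(use.sum())})
    out = pd.DataFrame(rows)
    summ = out.groupby("stage")["rho"].agg(
        mean_rho="mean", sem_rho=lambda v: v.std(ddof=1) / np.sqrt(len(v)))
    return out.merge(summ, on="stage")


# ---------------------------------------------------------------------------
# polysome vs transcriptome DE


def polysome_vs_transcriptome_de(counts: CountMatrix, stage: str,
                                 log2fc_gate: float = 3.0, fdr_gate: float = 0.05,
                                 **de_kwargs):
    """NB-LRT of polysome (F8-F10) vs transcriptome samples for one stage.

    Returns (DE table oriented polysome-positive, up set, down set) with
    up = log2FC > gate & fdr < gate, down the mirror image; the sets are
    disjoint by construction.
    """
    sheet = counts.samples
    sel = (sheet["stage"] == stage) & (
        ((sheet["sample_type"] == "fraction")
         & sheet["fraction"].isin(POLYSOME_FRACTIONS))
        | (sheet["sample_type"] == "transcriptome"))
    sub = counts.subset_samples(sel.to_numpy())
    if (sub.samples["sample_type"] == "fraction").sum() == 0 \
            or (sub.samples["sample_type"] == "transcriptome").sum() == 0:
        raise ValueError(f"stage {stage}: need both polysome and transcriptome samples")
    group = np.where(sub.samples["sample_type"] == "fraction", "polysome",
                     "transcriptome")
    de = de_two_group(sub.counts, group, "polysome", "transcriptome", **de_kwargs)
    sig = de["fdr"] < fdr_gate
    up = set(de.loc[sig & (de["log2FC"] > log2fc_gate), "gene_id"])
    down = set(de.loc[sig & (de["log2FC"] < -log2fc_gate), "gene_id"])
    return de, up, down


def persistence_flow(sets_by_stage: dict[str, tuple[set, set]],
                     universe) -> pd.DataFrame:
    """Per-gene Up/Down/NS trajectory strings across the stage series.

    ``sets_by_stage`` maps each stage to its (up, down) gene sets.  Counts
    over all trajectory classes conserve the gene universe.
    """
    stages = [s for s in STAGES if s in sets_by_stage]
    letters = []
    for g in universe:
        word = "".join(
            "U" if g in sets_by_stage[s][0]
            else "D" if g in sets_by_stage[s][1] else "N"
            for s in stages)
        letters.append(word)
    return pd.DataFrame({"gene_id": list(universe), "trajectory": letters})


# ---------------------------------------------------------------------------
# stage trend (linear model controlling for fraction)


def stage_trend(tpm: pd.DataFrame, sheet: pd.DataFrame, top_k: int = 90
                ) -> tuple[pd.DataFrame, pd.Index]:
    """Linear stage-trend model on polysome fractions.

    Per gene, ordinary least squares of log2(TPM+1) on the stage index
    (GV=0 ... BL=5, equally spaced) with categorical indicators for the
    polysome fraction (F9, F10 vs F8 baseline), so pure fraction structure
    cannot masquerade as a stage trend.  Two-sided t-test on the stage
    coefficient, BH correction, and the top-k most dynamic genes by (fdr,
    |slope|).
    """
    sel = sheet[(sheet["sample_type"] == "fraction")
                & sheet["fraction"].isin(POLYSOME_FRACTIONS)]
    if sel["stage"].nunique() < 3:
        raise ValueError("stage trend requires polysome samples from >= 3 stages")
    ids = list(sel["sample_id"])
    y = np.log2(tpm[ids].to_numpy(dtype=float) + 1.0)
    stage_idx = sel["stage"].map(STAGE_INDEX).to_numpy(dtype=float)
    cols = [np.ones(len(ids)), stage_idx]
    fr = sel["fraction"].astype(int).to_numpy()
    for f in sorted(set(fr))[1:]:
        cols.append((fr == f).astype(float))
    X = np.column_stack(cols)
    n, p = X.shape
    pinv = np.linalg.pinv(X)
    beta = y @ pinv.T                      # genes x p
    resid = y - beta @ X.T
    dof = n - p
    s2 = (resid ** 2).sum(axis=1) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(s2 * xtx_inv[1, 1], 1e-300))
    slope = beta[:, 1]
    t = slope / se
    pval = 2.0 * stats.t.sf(np.abs(t), dof)
    fdr = bh_adjust(pval)
    out = pd.DataFrame({
        "gene_id": tpm.index, "slope": slope, "se": se, "t": t,
        "p_value": pval, "fdr": fdr,
        "direction": np.where(slope >= 0, "up", "down"),
    })
    ranked = out.sort_values(["fdr", "slope"],
                             key=lambda c: c if c.name == "fdr" else -c.abs())
    top = pd.Index(ranked["gene_id"].head(top_k))
    return out, top


# ---------------------------------------------------------------------------
# transcription/translation discordance


def discordance(de_transcriptome: pd.DataFrame, de_polysome: pd.DataFrame,
                transition: tuple[str, str] | str = "",
                log2fc_gate: float = 1.0, fdr_gate: float = 0.05
                ) -> tuple[pd.DataFrame, float]:
    """Classify genes by transcription-vs-translation concordance.

    Both DE tables must be oriented later-stage-positive on the same gene
    universe.  gold = transcription down, translation up (both significant
    at FC > 2, FDR < 0.05 by default); blue = the reverse; concordant =
    both significant, same direction; ns otherwise.  Also returns the
    Spearman rho between the two log2FC vectors.
    """
    if not de_transcriptome["gene_id"].equals(de_polysome["gene_id"]):
        raise ValueError("DE tables must share one gene universe")
    t_fc = de_transcriptome["log2FC"].to_numpy()
    t_sig = (de_transcriptome["fdr"] < fdr_gate).to_numpy()
    p_fc = de_polysome["log2FC"].to_numpy()
    p_sig = (de_polysome["fdr"] < fdr_gate).to_numpy()
    t_up = t_sig & (t_fc > log2fc_gate)
    t_dn = t_sig & (t_fc < -log2fc_gate)
    p_up = p_sig & (p_fc > log2fc_gate)
    p_dn = p_sig & (p_fc < -log2fc_gate)
    cls = np.where(t_dn & p_up, "gold",
                   np.where(t_up & p_dn, "blue",
                            np.where((t_up & p_up) | (t_dn & p_dn),
                                     "concordant", "ns")))
    rho = stats.spearmanr(t_fc, p_fc)[0]
    name = "->".join(transition) if isinstance(transition, tuple) else str(transition)
    out = pd.DataFrame({
        "gene_id": de_transcriptome["gene_id"], "transition": name,
        "class": cls, "log2FC_transcriptome": t_fc, "fdr_transcriptome":
        de_transcriptome["fdr"], "log2FC_polysome": p_fc,
        "fdr_polysome": de_polysome["fdr"],
    })
    return out, float(rho)


def transition_discordance(counts: CountMatrix, transition: tuple[str, str],
                           log2fc_gate: float = 1.0, fdr_gate: float = 0.05,
                           **de_kwargs) -> tuple[pd.DataFrame, float]:
    """Run both DE contrasts of one consecutive-stage transition and classify."""
    a, b = transition
    sheet = counts.samples
    trans = counts.subset_samples(((sheet["sample_type"] == "transcriptome")
                                   & sheet["stage"].isin([a, b])).to_numpy())
    poly = counts.subset_samples(((sheet["sample_type"] == "fraction")
                                  & sheet["fraction"].isin(POLYSOME_FRACTIONS)
                                  & sheet["stage"].isin([a, b])).to_numpy())
    de_t = de_two_group(trans.counts, trans.samples["stage"], b, a, **de_kwargs)
    de_p = de_two_group(poly.counts, poly.samples["stage"], b, a, **de_kwargs)
    return discordance(de_t, de_p, transition, log2fc_gate, fdr_gate)


# ---------------------------------------------------------------------------
# stage-specific sets


def stage_specific_sets(counts: CountMatrix, log2fc_gate: float = 2.0,
                        fdr_gate: float = 0.05, **de_kwargs) -> pd.DataFrame:
    """Per-stage specifically & highly translated / transcribed gene sets.

    A gene is stage-specific in a modality when its one-vs-rest contrast
    (stage vs all other stages pooled) passes FC > 4 and FDR < 0.05.  The
    translated modality uses polysome samples (F8-F10), the transcribed
    modality transcriptome samples.  Returns a long table with the per-
    stage sets and their intersection flag.
    """
    sheet = counts.samples
    missing = set(STAGES) - set(sheet["stage"])
    if missing:
        raise ValueError(f"all six stages required; missing {sorted(missing)}")
    rows = []
    for modality, mask in (
            ("translated", (sheet["sample_type"] == "fraction")
             & sheet["fraction"].isin(POLYSOME_FRACTIONS)),
            ("transcribed", sheet["sample_type"] == "transcriptome")):
        sub = counts.subset_samples(mask.to_numpy())
        for stage in STAGES:
            group = np.where(sub.samples["stage"] == stage, "this", "rest")
            de = de_two_group(sub.counts, group, "this", "rest", **de_kwargs)
            hits = de.loc[(de["log2FC"] > log2fc_gate) & (de["fdr"] < fdr_gate),
                          "gene_id"]
            rows.extend({"stage": stage, "modality": modality, "gene_id": g}
                        for g in hits)
    long = pd.DataFrame(rows, columns=["stage", "modality", "gene_id"])
    if long.empty:
        long["in_both"] = pd.Series(dtype=bool)
        return long
    both = long.groupby(["stage", "gene_id"])["modality"].nunique()
    long["in_both"] = [
        both.get((s, g), 0) == 2 for s, g in zip(long["stage"], long["gene_id"])]
    return long
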