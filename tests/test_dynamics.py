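"""Cross-stage dynamics: correlations, contrasts, trends, discordance."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import polymodes as pm
from polymodes.dynamics import discordance, persistence_flow, stage_trend


# ---------------------------------------------------------------------------
# stage correlation


def test_stage_correlation_identical_vectors():
    sheet = pm.make_sample_sheet(stages=("GV",), n_fraction_replicates=1,
                                 n_transcriptome_replicates=1)
    rng = np.random.default_rng(0)
    vec = rng.lognormal(3, 1, size=300)
    tpm = pd.DataFrame({s: vec for s in sheet["sample_id"]},
                       index=[f"g{i}" for i in range(300)])
    out = pm.stage_correlation(tpm, sheet)
    assert np.allclose(out["rho"], 1.0)


def test_stage_correlation_independent_vectors_near_zero():
    sheet = pm.make_sample_sheet(stages=("GV",), n_fraction_replicates=1,
                                 n_transcriptome_replicates=1)
    rng = np.random.default_rng(1)
    tpm = pd.DataFrame(
        rng.lognormal(3, 1, size=(5000, len(sheet))),
        index=[f"g{i}" for i in range(5000)], columns=list(sheet["sample_id"]))
    out = pm.stage_correlation(tpm, sheet)
    assert out["rho"].abs().max() < 0.05


def test_minimum_coupling_stage_identified(default_sim, default_tpm):
    """The stage with the planted weakest coupling (8C) has the lowest
    mean translatome-transcriptome correlation."""
    out = pm.stage_correlation(default_tpm, default_sim.sheet)
    summary = out.groupby("stage")["mean_rho"].first()
    assert summary.idxmin() == "8C"
    assert (out.groupby("stage")["sem_rho"].first() >= 0).all()


# ---------------------------------------------------------------------------
# polysome vs transcriptome DE


def test_polysome_vs_transcriptome_null_and_sets(default_sim):
    """With a planted-structure-free generator the FC>8 contrast calls
    almost nothing; up/down sets are always disjoint."""
    null_cfg = pm.GeneratorConfig(
        n_genes=1500, stages=("GV",), mode_proportions={},
        maternal_fraction=0.0, embryonic_fraction=0.0, n_trend_genes=0,
        coupling_sd={"GV": 0.0}, seed=77)
    sim = pm.generate(null_cfg)
    de, up, down = pm.polysome_vs_transcriptome_de(sim.counts, "GV")
    assert len(up & down) == 0
    assert (len(up) + len(down)) <= 0.001 * len(de)
    # power: planted 8-fold polysome enrichment on 100 genes is recovered
    rng = np.random.default_rng(88)
    n = 2000
    rows = []
    for f in (8, 9, 10):
        for r in (1, 2):
            rows.append({"sample_id": f"GV_F{f}_r{r}", "stage": "GV",
                         "sample_type": "fraction", "fraction": f,
                         "replicate": r})
    for r in (1, 2, 3):
        rows.append({"sample_id": f"GV_T_r{r}", "stage": "GV",
                     "sample_type": "transcriptome", "fraction": pd.NA,
                     "replicate": r})
    sheet = pd.DataFrame(rows)
    mu = np.full(n, 200.0)
    enrich = np.ones(n)
    planted = rng.choice(n, size=100, replace=False)
    enrich[planted] = 8.0
    r_nb = 1 / 0.2
    cols = {}
    for _, s in sheet.iterrows():
        m = mu * enrich if s["sample_type"] == "fraction" else mu
        cols[s["sample_id"]] = rng.negative_binomial(r_nb, r_nb / (r_nb + m))
    counts = pm.CountMatrix(
        pd.DataFrame(cols, index=[f"g{i}" for i in range(n)]), sheet)
    planted_ids = {f"g{i}" for i in planted}
    # recovery at the significance gate (the persistence-set definition):
    # an exactly 8-fold planting straddles the strict FC>8 cut, so the
    # fold-change gate is checked for specificity instead
    de2, up_fdr, _ = pm.polysome_vs_transcriptome_de(counts, "GV",
                                                     log2fc_gate=0.0)
    assert len(up_fdr & planted_ids) >= 90
    _, up_strict, _ = pm.polysome_vs_transcriptome_de(counts, "GV")
    assert up_strict <= planted_ids


def test_persistence_flow_trajectories():
    universe = ["g1", "g2", "g3"]
    sets = {s: ({"g1"}, set()) for s in pm.STAGES}
    sets["8C"] = ({"g1"}, {"g2"})
    out = persistence_flow(sets, universe).set_index("gene_id")
    assert out.loc["g1", "trajectory"] == "UUUUUU"
    assert out.loc["g2", "trajectory"] == "NNNDNN"
    assert out.loc["g3", "trajectory"] == "NNNNNN"
    assert len(out) == len(universe)  # conservation


def test_persistence_planted_early_occupancy_lost_after_ega(default_sim):
    """Down-trend genes are polysome-enriched early and lose the call by
    the eight-cell stage."""
    sets = {}
    for s in pm.STAGES:
        _, up, down = pm.polysome_vs_transcriptome_de(default_sim.counts, s,
                                                      log2fc_gate=1.0)
        sets[s] = (up, down)
    down_genes = default_sim.truth_genes.query("trend_slope < 0").index
    flow = persistence_flow(sets, down_genes).set_index("gene_id")
    early_up = flow["trajectory"].str[0] == "U"
    lost_late = ~flow["trajectory"].str[3].isin(["U"])
    assert (early_up & lost_late).mean() >= 0.8


# ---------------------------------------------------------------------------
# stage trend


def test_stage_trend_noiseless_linear_recovery():
    sheet = pm.make_sample_sheet(n_fraction_replicates=1,
                                 n_transcriptome_replicates=1)
    poly = sheet[(sheet["sample_type"] == "fraction")
                 & sheet["fraction"].isin(pm.POLYSOME_FRACTIONS)]
    genes = ["lin", "flat"]
    tpm = pd.DataFrame(0.0, index=genes, columns=list(sheet["sample_id"]))
    for _, s in poly.iterrows():
        idx = pm.STAGES.index(s["stage"])
        tpm.loc["lin", s["sample_id"]] = 2.0 ** (3 + 0.5 * idx) - 1
        tpm.loc["flat", s["sample_id"]] = 2.0 ** (2 + 0.3 * (int(s["fraction"]) - 8)) - 1
    out, top = stage_trend(tpm, sheet, top_k=1)
    res = out.set_index("gene_id")
    assert res.loc["lin", "slope"] == pytest.approx(0.5, abs=1e-6)
    assert res.loc["lin", "p_value"] < 1e-6
    # pure fraction structure is absorbed by the fraction covariate
    assert abs(res.loc["flat", "slope"]) < 1e-6
    assert list(top) == ["lin"]


def test_stage_trend_confound_control():
    """Stage-constant genes with strong fraction-only structure stay near
    slope 0: the fraction covariate absorbs the gradient signal."""
    cfg = pm.GeneratorConfig(
        n_genes=1000, maternal_fraction=0.0, embryonic_fraction=0.0,
        n_trend_genes=0, coupling_sd={s: 0.0 for s in pm.STAGES}, seed=44)
    sim = pm.generate(cfg)
    tpm = pm.compute_tpm(sim.counts, sim.annotation["transcript_length"])
    out, top = stage_trend(tpm, sim.sheet, top_k=50)
    res = out.set_index("gene_id")
    structured = sim.truth_genes.query("mode in ['1', '4']").index
    flat = sim.truth_genes.query("mode == 'background'").index
    med_structured = res.loc[structured, "slope"].abs().median()
    med_flat = res.loc[flat, "slope"].abs().median()
    # strong fraction structure buys no stage slope beyond counting noise
    assert med_structured < 0.1
    assert med_structured < 1.5 * med_flat


def test_stage_trend_top90_mostly_planted(default_sim, default_tpm):
    out, top = stage_trend(default_tpm, default_sim.sheet, top_k=90)
    planted = set(default_sim.truth_genes.query("trend_slope != 0").index)
    assert len(set(top) & planted) >= 80


# ---------------------------------------------------------------------------
# discordance


def _de(genes, fc, fdr):
    return pd.DataFrame({"gene_id": genes, "log2FC": fc, "LR_stat": 1.0,
                         "p_value": fdr, "fdr": fdr, "flag": ""})


def test_discordance_rule_instantiation():
    genes = ["gold", "conc", "ns"]
    de_t = _de(genes, [-2.0, 2.0, 0.1], [1e-3, 1e-3, 0.9])
    de_p = _de(genes, [1.5, 2.0, 0.0], [1e-3, 1e-3, 0.9])
    out, rho = discordance(de_t, de_p, ("GV", "MII"))
    res = out.set_index("gene_id")
    assert res.loc["gold", "class"] == "gold"
    assert res.loc["conc", "class"] == "concordant"
    assert res.loc["ns", "class"] == "ns"
    assert -1 <= rho <= 1


def test_discordance_planted_gold_recovery():
    """100 planted gold genes in a GV->MII transition are recovered with
    few false calls among the null background."""
    cfg = pm.GeneratorConfig(
        n_genes=2100, stages=("GV", "MII"), mode_proportions={},
        maternal_fraction=0.0, embryonic_fraction=0.0, n_trend_genes=0,
        coupling_sd={"GV": 0.0, "MII": 0.0},
        discordant={("GV", "MII"): (100, 0)}, seed=55)
    sim = pm.generate(cfg)
    calls, rho = pm.transition_discordance(sim.counts, ("GV", "MII"))
    res = calls.set_index("gene_id")
    gold_true = sim.truth_genes.query("discordant_class == 'gold'").index
    nulls = sim.truth_genes.query("discordant_class == ''").index
    assert (res.loc[gold_true, "class"] == "gold").sum() >= 85
    assert (res.loc[nulls, "class"] == "gold").sum() <= 5


def test_discordance_partitions_universe(default_sim):
    calls, _ = pm.transition_discordance(default_sim.counts, ("GV", "MII"))
    assert set(calls["gene_id"]) == set(default_sim.counts.genes)
    assert calls["class"].isin(["gold", "blue", "concordant", "ns"]).all()


# ---------------------------------------------------------------------------
# stage-specific sets


def test_stage_specific_planted_recovery():
    cfg = pm.GeneratorConfig(
        n_genes=1200, mode_proportions={}, maternal_fraction=0.0,
        embryonic_fraction=0.0, n_trend_genes=0,
        coupling_sd={s: 0.0 for s in pm.STAGES},
        stage_specific={"8C": 40}, seed=66)
    sim = pm.generate(cfg)
    out = pm.stage_specific_sets(sim.counts)
    planted = set(sim.truth_genes.query("specific_stage == '8C'").index)
    hits = out.query("stage == '8C'")
    translated = set(hits.query("modality == 'translated'")["gene_id"])
    transcribed = set(hits.query("modality == 'transcribed'")["gene_id"])
    both = translated & transcribed
    assert len(both & planted) / len(planted) >= 0.9
    background = set(sim.truth_genes.index) - planted
    called = set(out["gene_id"])
    assert len(called & background) <= 0.01 * len(background)
    # planted genes appear in the intersection flag
    flagged = set(hits[hits["in_both"]]["gene_id"])
    assert len(flagged & planted) / len(planted) >= 0.9
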