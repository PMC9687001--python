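"""End-to-end pipeline: ingest or simulate -> normalize -> QC -> classify
-> features -> programs -> dynamics, with a manifest for reproducibility.

Every threshold lives in :class:`PipelineConfig`; nothing is hard-coded in
the stages.  Dispersions are estimated once per modality (transcriptome /
polysome samples under a stage design) and reused across that modality's
contrasts, which keeps genome-scale runs fast without changing any
contrast's model.
"""

from __future__ import annotations

import hashlib
import json
import platform
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import POLYSOME_FRACTIONS, STAGES
from .dynamics import (TRANSITIONS, persistence_flow,
                       polysome_vs_transcriptome_de, stage_correlation,
                       stage_specific_sets, stage_trend,
                       transition_discordance)
from .features import te_feature_correlation, utr_features
from .io import (CountMatrix, read_annotation, read_counts, read_sample_sheet,
                 write_table)
from .modes import ModeConfig, classify_stage
from .normalize import compute_tpm, estimate_dispersion, tmm_factors
from .programs import mode_program_proportions, run_program_contrasts
from .qc import pca, replicate_correlation
from .simulate import GeneratorConfig, generate


@dataclass
class PipelineConfig:
    """All inputs and thresholds of a pipeline run."""

    outdir: str = "polymodes_results"
    seed: int = 1234
    # either a simulate block ...
    simulate: dict | None = None
    # ... or paths to real inputs
    counts_path: str | None = None
    sample_sheet_path: str | None = None
    annotation_path: str | None = None
    utr3_fasta_path: str | None = None
    # thresholds (defaults follow the analysis conventions: FDR 0.05 and
    # linear fold-change gates 2 / 4 / 8 depending on the contrast)
    expression_floor: float = 1.0
    te_eps: float = 0.25
    monosome_factor: float = 2.0
    fdr_gate: float = 0.05
    program_log2fc_gate: float = 2.0       # FC > 4
    poly_vs_trans_log2fc_gate: float = 3.0  # FC > 8
    discordance_log2fc_gate: float = 1.0   # FC > 2
    stage_specific_log2fc_gate: float = 2.0  # FC > 4
    top_k_dynamic: int = 90

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def mode_config(self) -> ModeConfig:
        return ModeConfig(expression_floor=self.expression_floor,
                          te_eps=self.te_eps,
                          monosome_factor=self.monosome_factor,
                          fdr_gate=self.fdr_gate)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_inputs(cfg: PipelineConfig):
    """Load or simulate the pipeline inputs per the config."""
    if cfg.simulate is not None:
        sim_kwargs = dict(cfg.simulate)
        sim_kwargs.setdefault("seed", cfg.seed)
        sim = generate(GeneratorConfig(**sim_kwargs))
        return sim.counts, sim.annotation, sim
    if not (cfg.counts_path and cfg.sample_sheet_path and cfg.annotation_path):
        raise ValueError("need either a simulate block or input paths")
    sheet = read_sample_sheet(cfg.sample_sheet_path)
    counts = read_counts(cfg.counts_path, sheet)
    annot = read_annotation(cfg.annotation_path, fasta=cfg.utr3_fasta_path)
    return counts, annot.reindex(counts.genes), None


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run every analysis stage, writing TSVs and a manifest.

    Reruns with the same config and inputs are bit-identical.  A stage
    failure leaves partial outputs in place and records the failure point
    in the manifest before re-raising.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__, "python": platform.python_version(),
        "seed": cfg.seed, "config": asdict(cfg), "stage_reached": None,
        "input_hashes": {}, "gene_counts": {},
    }
    for key in ("counts_path", "sample_sheet_path", "annotation_path",
                "utr3_fasta_path"):
        p = getattr(cfg, key)
        if p:
            manifest["input_hashes"][key] = _sha256(Path(p))

    def checkpoint(stage: str) -> None:
        manifest["stage_reached"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      default=str))

    try:
        checkpoint("load")
        counts, annot, sim = load_inputs(cfg)
        sheet = counts.samples
        stages = [s for s in STAGES if s in set(sheet["stage"])]
        manifest["gene_counts"]["input"] = int(len(counts.genes))
        if sim is not None:
            sim.truth_genes.reset_index().pipe(write_table, out / "truth_genes.tsv")
            write_table(sim.truth_stage, out / "truth_stage.tsv")

        checkpoint("normalize")
        tpm = compute_tpm(counts, annot["transcript_length"])
        factors = tmm_factors(counts)
        write_table(factors.rename_axis("sample_id").reset_index(),
                    out / "tmm_factors.tsv")

        checkpoint("qc")
        repcor = replicate_correlation(tpm, sheet, floor=cfg.expression_floor)
        write_table(repcor, out / "replicate_correlation.tsv")
        pres = pca(tpm, n_components=4)
        coords = pres.coordinates.rename_axis("sample_id").reset_index()
        write_table(coords, out / "pca_coordinates.tsv")

        checkpoint("classify")
        mode_cfg = cfg.mode_config()
        assignments = pd.concat(
            [classify_stage(tpm, sheet, s, mode_cfg) for s in stages],
            ignore_index=True)
        write_table(assignments, out / "mode_assignments.tsv")
        manifest["gene_counts"]["classified"] = int(
            (assignments["mode"] != "none").sum())
        manifest["gene_counts"]["per_stage_universe"] = int(len(counts.genes))

        checkpoint("features")
        feats = utr_features(annot)
        write_table(feats.reset_index(), out / "utr_features.tsv")
        te_tab = assignments[["gene_id", "stage", "A", "P", "M", "TE"]]
        corr = te_feature_correlation(te_tab, feats)
        write_table(corr, out / "te_feature_correlations.tsv")

        # dispersions shared within each modality
        checkpoint("dispersion")
        trans_mask = (sheet["sample_type"] == "transcriptome").to_numpy()
        poly_mask = ((sheet["sample_type"] == "fraction")
                     & sheet["fraction"].isin(POLYSOME_FRACTIONS)).to_numpy()
        disp_kwargs = {}
        if trans_mask.sum() >= len(stages) + 1:
            X_t = pd.get_dummies(sheet.loc[trans_mask, "stage"]).to_numpy(float)
            phi_t = estimate_dispersion(counts.counts.loc[:, trans_mask], X_t)
            disp_trans = phi_t.common
        else:
            disp_trans = None
        all_mask = trans_mask | poly_mask
        X_a = pd.get_dummies(
            sheet.loc[all_mask, ["stage", "sample_type"]].astype(str).agg(
                "_".join, axis=1)).to_numpy(float)
        phi_a = estimate_dispersion(counts.counts.loc[:, all_mask], X_a)
        disp_all = phi_a.common

        checkpoint("programs")
        from .programs import LATE_STAGES, OOCYTE_STAGES
        have = set(stages)
        if set(OOCYTE_STAGES) <= have and have & set(LATE_STAGES):
            labels = run_program_contrasts(counts, log2fc=cfg.program_log2fc_gate,
                                           fdr=cfg.fdr_gate,
                                           dispersion=disp_trans)
            write_table(labels, out / "program_labels.tsv")
            props = mode_program_proportions(assignments, labels)
            write_table(props, out / "mode_program_proportions.tsv")
        else:
            warnings.warn("oocyte/late stages incomplete; program "
                          "classification skipped")

        checkpoint("dynamics")
        sc = stage_correlation(tpm, sheet, floor=cfg.expression_floor)
        write_table(sc, out / "stage_correlation.tsv")
        sets = {}
        de_rows = []
        for s in stages:
            de, up, down = polysome_vs_transcriptome_de(
                counts, s, log2fc_gate=cfg.poly_vs_trans_log2fc_gate,
                fdr_gate=cfg.fdr_gate, dispersion=disp_all)
            de["stage"] = s
            de_rows.append(de)
            sets[s] = (up, down)
        write_table(pd.concat(de_rows, ignore_index=True),
                    out / "polysome_vs_transcriptome_de.tsv")
        flow = persistence_flow(sets, counts.genes)
        write_table(flow, out / "persistence_trajectories.tsv")
        if len(stages) >= 3:
            trend, top = stage_trend(tpm, sheet, top_k=cfg.top_k_dynamic)
            write_table(trend, out / "stage_trend.tsv")
            write_table(pd.DataFrame({"gene_id": top}),
                        out / "top_dynamic_genes.tsv")
        disc_rows = []
        rhos = []
        for tr in TRANSITIONS:
            if tr[0] not in stages or tr[1] not in stages:
                continue
            calls, rho = transition_discordance(
                counts, tr, log2fc_gate=cfg.discordance_log2fc_gate,
                fdr_gate=cfg.fdr_gate, dispersion=disp_all)
            disc_rows.append(calls)
            rhos.append({"transition": "->".join(tr), "spearman_rho": rho})
        if disc_rows:
            write_table(pd.concat(disc_rows, ignore_index=True),
                        out / "discordance_calls.tsv")
            write_table(pd.DataFrame(rhos), out / "discordance_rho.tsv")
        if set(stages) == set(STAGES):
            spec = stage_specific_sets(
                counts, log2fc_gate=cfg.stage_specific_log2fc_gate,
                fdr_gate=cfg.fdr_gate, dispersion=disp_all)
            write_table(spec, out / "stage_specific_sets.tsv")

        manifest["gene_counts"]["unclassified"] = int(
            (assignments["mode"] == "none").sum())
        manifest["gene_counts"]["conserved"] = bool(
            manifest["gene_counts"]["classified"]
            + manifest["gene_counts"]["unclassified"]
            == len(counts.genes) * len(stages))
        checkpoint("done")
    except Exception as exc:  # pragma: no cover - failure bookkeeping
        manifest["error"] = repr(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      default=str))
        raise
    return out
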