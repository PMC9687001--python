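"""Seeded generator of complete synthetic fraction-profiling experiments.

The generator emulates the study design the analysis assumes: six
developmental stages, ten gradient fractions with two replicates each,
three transcriptome replicates per stage, negative-binomial counts
(var = mu + phi mu^2), planted translational-selectivity modes with
characteristic fraction-loading profiles, maternal/embryonic abundance
programs, stage-trend genes, stage-dependent translatome-transcriptome
coupling, and 3'UTR sequences whose CPE content and length are coupled to
translational efficiency.  Ground truth is returned alongside the data so
every downstream operation can be scored against what was planted.

Loading templates are length-10 simplex vectors (config data, not code
constants); per-gene profiles add Dirichlet jitter around the template.
All randomness flows from one seeded generator — same seed, bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import FRACTIONS, STAGE_INDEX, STAGES
from .features import scan_cpe
from .io import CountMatrix, validate_sample_sheet

# Fraction-loading templates: how a gene's mRNA distributes over F1-F10.
# mode1 concentrates on polysomes at low abundance; mode2 rises toward
# polysomes from a large free pool; mode3 sits in the free fractions with a
# flat, low ribosomal profile; mode4 concentrates on monosomes; background
# is uniform.
DEFAULT_TEMPLATES: dict[str, tuple[float, ...]] = {
    "1": (0.005, 0.005, 0.010, 0.015, 0.020, 0.040, 0.105, 0.220, 0.280, 0.300),
    "2": (0.430, 0.322, 0.006, 0.010, 0.016, 0.024, 0.034, 0.044, 0.052, 0.062),
    "3": (0.374, 0.372, 0.030, 0.030, 0.030, 0.031, 0.031, 0.032, 0.034, 0.036),
    "4": (0.050, 0.040, 0.210, 0.220, 0.200, 0.110, 0.070, 0.035, 0.033, 0.032),
    "background": (0.1,) * 10,
}

# Log2-mean abundance by mode: mode-1 transcripts are non-abundant, modes
# 2/3 abundant, mode 4 intermediate, background broad.
DEFAULT_ABUNDANCE = {
    "1": (2.2, 0.6), "2": (8.8, 0.55), "3": (8.8, 0.55), "4": (6.0, 1.0),
    "background": (5.0, 2.0),
}

# Per-stage sd (log2) of the translatome-specific abundance perturbation;
# largest at the eight-cell stage, where major EGA decouples polysome
# occupancy from the transcriptome.
DEFAULT_COUPLING_SD = {"GV": 0.2, "MII": 0.25, "2C": 0.3, "8C": 0.7,
                       "MOR": 0.35, "BL": 0.25}


@dataclass
class GeneratorConfig:
    """Study-design parameters of the synthetic experiment."""

    n_genes: int = 4000
    stages: tuple[str, ...] = STAGES
    n_fraction_replicates: int = 2
    n_transcriptome_replicates: int = 3
    mode_proportions: dict[str, float] = field(
        default_factory=lambda: {"1": 0.125, "2": 0.125, "3": 0.125, "4": 0.125})
    maternal_fraction: float = 0.30
    embryonic_fraction: float = 0.20
    program_log2fc: float = 4.0      # total oocyte-vs-late contrast
    dispersion: float = 0.2          # NB phi; var = mu + phi mu^2
    lib_size_log_sd: float = 0.2
    fraction_lib_size: float = 1.0e6
    transcriptome_lib_size: float = 2.0e6
    templates: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_TEMPLATES))
    abundance: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ABUNDANCE))
    loading_jitter_concentration: float = 50.0  # per fraction, on average
    coupling_sd: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COUPLING_SD))
    n_trend_genes: int = 90
    trend_log2_slope: float = 1.4    # per stage step, applied to fractions
    trend_abundance: tuple[float, float] = (6.5, 0.8)  # log2 mean, sd
    te_cpe_coupling: float = 0.8     # exponent of the CPE rate in 1/TE
    discordant: dict[tuple[str, str], tuple[int, int]] = field(default_factory=dict)
    # planted discordant shifts must clear the FC>2 calling gate with the
    # design's n=3 transcriptome power; 8-fold opposing shifts do
    discordant_log2fc: float = 3.0
    stage_specific: dict[str, int] = field(default_factory=dict)
    stage_specific_log2fc: float = 4.0
    seed: int = 1234

    def validate(self) -> None:
        if sum(self.mode_proportions.values()) > 1.0 + 1e-9:
            raise ValueError("mode proportions must sum to <= 1")
        if self.maternal_fraction + self.embryonic_fraction > 1.0 + 1e-9:
            raise ValueError("program fractions must sum to <= 1")
        for k, t in self.templates.items():
            if len(t) != 10 or abs(sum(t) - 1.0) > 1e-6:
                raise ValueError(f"template {k!r} must be a length-10 simplex vector")


@dataclass
class SyntheticExperiment:
    counts: CountMatrix
    annotation: pd.DataFrame
    truth_genes: pd.DataFrame   # per-gene planted structure
    truth_stage: pd.DataFrame   # per (gene, stage): coupling offset, true TE
    config: GeneratorConfig

    @property
    def sheet(self) -> pd.DataFrame:
        return self.counts.samples


def make_sample_sheet(stages=STAGES, n_fraction_replicates: int = 2,
                      n_transcriptome_replicates: int = 3) -> pd.DataFrame:
    rows = []
    for stage in stages:
        for f in FRACTIONS:
            for r in range(1, n_fraction_replicates + 1):
                rows.append({"sample_id": f"{stage}_F{f}_r{r}", "stage": stage,
                             "sample_type": "fraction", "fraction": f,
                             "replicate": r})
        for r in range(1, n_transcriptome_replicates + 1):
            rows.append({"sample_id": f"{stage}_T_r{r}", "stage": stage,
                         "sample_type": "transcriptome", "fraction": pd.NA,
                         "replicate": r})
    return validate_sample_sheet(pd.DataFrame(rows))


def _exact_labels(rng: np.random.Generator, n: int,
                  proportions: dict[str, float], rest: str) -> np.ndarray:
    """Label vector with deterministic class counts, randomly placed."""
    labels = []
    for k, p in proportions.items():
        labels.extend([k] * int(round(p * n)))
    labels.extend([rest] * (n - len(labels)))
    labels = np.array(labels, dtype=object)
    rng.shuffle(labels)
    return labels


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    mean = np.maximum(mean, 1e-12)
    if phi <= 0:
        return rng.poisson(mean)
    r = 1.0 / phi
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


_BG_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)
_CPE_INSERT = "TTTTAT"


def _random_utr(rng: np.random.Generator, length: int, n_motifs: int) -> str:
    """Random 3'UTR with ~n_motifs inserted CPEs (plus chance matches)."""
    seq = _BG_ALPHABET[rng.integers(0, 4, size=length)].tobytes().decode()
    if n_motifs == 0 or length < 10:
        return seq
    slots = max(length // max(n_motifs, 1), len(_CPE_INSERT) + 2)
    out = []
    pos = 0
    for k in range(n_motifs):
        lo = k * slots
        hi = min((k + 1) * slots - len(_CPE_INSERT), length - len(_CPE_INSERT))
        if lo >= hi:
            break
        at = int(rng.integers(lo, hi))
        out.append(seq[pos:at])
        out.append(_CPE_INSERT)
        pos = at + len(_CPE_INSERT)
    out.append(seq[pos:])
    return "".join(out)[:length]


def generate(config: GeneratorConfig | None = None,
             seed: int | None = None) -> SyntheticExperiment:
    """Generate a complete synthetic experiment with ground truth.

    Per gene g and stage s the transcriptome mean is a log-normal abundance
    draw times the program multiplier; a fraction sample's mean is that
    abundance times the gene's loading weight w_gf, a translatome coupling
    perturbation, and any planted stage-trend multiplier.  Expected counts
    are proportional to mean x transcript length, scaled to the sample's
    library size; observed counts are NB(mean, phi).
    """
    cfg = replace(config) if config is not None else GeneratorConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    stages = list(cfg.stages)
    genes = pd.Index([f"g{i:05d}" for i in range(n)], name="gene_id")

    mode = _exact_labels(rng, n, cfg.mode_proportions, "background")
    program = _exact_labels(
        rng, n, {"maternal": cfg.maternal_fraction,
                 "embryonic": cfg.embryonic_fraction}, "neither")

    # stage-trend genes drawn from the unstructured background pool
    trend_slope = np.zeros(n)
    pool = np.flatnonzero((mode == "background") & (program == "neither"))
    n_trend = min(cfg.n_trend_genes, len(pool))
    trend_idx = rng.choice(pool, size=n_trend, replace=False)
    half = n_trend // 2
    trend_slope[trend_idx[:half]] = cfg.trend_log2_slope
    trend_slope[trend_idx[half:]] = -cfg.trend_log2_slope

    # planted discordant genes (per consecutive transition) and
    # stage-specific genes, also from the clean background pool
    taken = set(trend_idx)
    free_pool = [i for i in pool if i not in taken]
    disc_class = np.array([""] * n, dtype=object)
    disc_transition = np.array([""] * n, dtype=object)
    for (a, b), (n_gold, n_blue) in cfg.discordant.items():
        for cls, k in (("gold", n_gold), ("blue", n_blue)):
            pick, free_pool = free_pool[:k], free_pool[k:]
            disc_class[pick] = cls
            disc_transition[pick] = f"{a}->{b}"
    specific_stage = np.array([""] * n, dtype=object)
    for stage, k in cfg.stage_specific.items():
        pick, free_pool = free_pool[:k], free_pool[k:]
        specific_stage[pick] = stage

    # abundance and loading profiles
    base_log2 = np.empty(n)
    for m in set(mode):
        mu, sd = cfg.abundance[m]
        sel = mode == m
        base_log2[sel] = rng.normal(mu, sd, size=int(sel.sum()))
    # trend genes are drawn well-expressed so their trajectories stay
    # observable above the counting floor at their low-signal stages
    if n_trend:
        base_log2[trend_idx] = rng.normal(*cfg.trend_abundance, size=n_trend)
    k_frac = len(FRACTIONS)
    weights = np.empty((n, k_frac))
    conc = cfg.loading_jitter_concentration * k_frac
    for m in set(mode):
        sel = mode == m
        alpha = np.maximum(np.asarray(cfg.templates[m]) * conc, 1e-3)
        weights[sel] = rng.dirichlet(alpha, size=int(sel.sum()))

    # translatome coupling perturbations per (gene, stage)
    coupling = np.zeros((n, len(stages)))
    for j, s in enumerate(stages):
        coupling[:, j] = rng.normal(0.0, cfg.coupling_sd.get(s, 0.0), size=n)

    # UTR features coupled to the loading-derived true TE
    w_poly = weights[:, 7:10].mean(axis=1)
    te_rel = w_poly / (1.0 / k_frac)
    lam = np.clip(2.5 * te_rel ** (-cfg.te_cpe_coupling), 0.1, 12.0)
    n_cpe_planted = rng.poisson(lam)
    utr3_len = np.maximum(
        np.round(2.0 ** (9.6 - 0.5 * np.log2(te_rel) + rng.normal(0, 0.5, n))), 150
    ).astype(int)
    utr5_len = np.maximum(
        np.round(2.0 ** (7.13 + 0.15 * np.log2(te_rel) + rng.normal(0, 0.6, n))), 20
    ).astype(int)
    cds_len = np.round(2.0 ** (10.2 + rng.normal(0, 0.5, n))).astype(int)
    tx_len = utr5_len + cds_len + utr3_len
    seqs = [_random_utr(rng, int(l), int(k)) for l, k in zip(utr3_len, n_cpe_planted)]
    cpe_count = np.array([scan_cpe(s) for s in seqs])

    annotation = pd.DataFrame({
        "transcript_length": tx_len, "utr5_length": utr5_len,
        "utr3_length": utr3_len,
        "utr3_sequence": pd.array(seqs, dtype="string"),
    }, index=genes)
    annotation["length_mismatch"] = False

    # program multipliers: +/- half the total contrast on the log2 scale
    early = {"GV", "MII", "2C"}
    shift = cfg.program_log2fc / 2.0
    prog_shift = np.zeros((n, len(stages)))
    for j, s in enumerate(stages):
        sgn = 1.0 if s in early else -1.0
        prog_shift[program == "maternal", j] = sgn * shift
        prog_shift[program == "embryonic", j] = -sgn * shift

    trend_shift = np.zeros((n, len(stages)))
    s_idx = np.array([STAGE_INDEX[s] for s in stages], dtype=float)
    trend_shift += trend_slope[:, None] * (s_idx - s_idx.mean())[None, :]

    disc_trans_shift = np.zeros((n, len(stages)))
    disc_poly_shift = np.zeros((n, len(stages)))
    for i in np.flatnonzero(disc_class != ""):
        b = disc_transition[i].split("->")[1]
        onward = s_idx >= STAGE_INDEX[b]
        sgn = -1.0 if disc_class[i] == "gold" else 1.0
        disc_trans_shift[i, onward] = sgn * cfg.discordant_log2fc
        disc_poly_shift[i, onward] = -sgn * cfg.discordant_log2fc
    spec_shift = np.zeros((n, len(stages)))
    for i in np.flatnonzero(specific_stage != ""):
        j = stages.index(specific_stage[i])
        spec_shift[i, j] = cfg.stage_specific_log2fc

    sheet = make_sample_sheet(stages, cfg.n_fraction_replicates,
                              cfg.n_transcriptome_replicates)
    counts = np.zeros((n, len(sheet)), dtype=np.int64)
    lenw = tx_len.astype(float)
    for c, row in sheet.iterrows():
        j = stages.index(row["stage"])
        if row["sample_type"] == "transcriptome":
            mu = 2.0 ** (base_log2 + prog_shift[:, j] + disc_trans_shift[:, j]
                         + spec_shift[:, j])
            base_lib = cfg.transcriptome_lib_size
        else:
            f = int(row["fraction"]) - 1
            mu = (2.0 ** (base_log2 + prog_shift[:, j] + coupling[:, j]
                          + trend_shift[:, j] + disc_poly_shift[:, j]
                          + spec_shift[:, j])
                  * weights[:, f] * k_frac)
            base_lib = cfg.fraction_lib_size
        expected = mu * lenw
        expected = expected / expected.sum()
        lib = base_lib * np.exp(rng.normal(0.0, cfg.lib_size_log_sd))
        counts[:, c] = _nb_draw(rng, expected * lib, cfg.dispersion)

    cm = CountMatrix(pd.DataFrame(counts, index=genes,
                                  columns=list(sheet["sample_id"])), sheet)

    truth_genes = pd.DataFrame({
        "mode": mode, "program": program, "trend_slope": trend_slope,
        "discordant_class": disc_class, "discordant_transition": disc_transition,
        "specific_stage": specific_stage,
        "base_log2_abundance": base_log2, "true_te_rel": te_rel,
        "cpe_count": cpe_count, "utr3_length": utr3_len,
        "utr5_length": utr5_len,
    }, index=genes)
    for f in range(k_frac):
        truth_genes[f"w{f+1}"] = weights[:, f]
    truth_stage = pd.DataFrame(
        [{"gene_id": g, "stage": s,
          "coupling_log2": coupling[i, j],
          "true_te": te_rel[i] * 2.0 ** coupling[i, j]}
         for i, g in enumerate(genes) for j, s in enumerate(stages)])
    return SyntheticExperiment(counts=cm, annotation=annotation,
                               truth_genes=truth_genes, truth_stage=truth_stage,
                               config=cfg)


# ---------------------------------------------------------------------------
# rRNA profiles

# canonical relative quantities (18S, 28S) per fraction: free low, a 40S
# (18S-dominant) then a 60S (28S-dominant) fraction, the 80S monosome peak,
# an intermediate dip, and the rising polysome region
CANONICAL_RRNA = {
    1: (0.8, 0.7), 2: (0.9, 0.8), 3: (6.0, 2.0), 4: (2.0, 6.0),
    5: (8.0, 9.0), 6: (5.0, 6.0), 7: (5.5, 6.5), 8: (7.0, 9.0),
    9: (8.0, 10.5), 10: (9.0, 12.0),
}

CANONICAL_RRNA_ROLES = ("free", "free", "40S", "60S", "monosome",
                        "intermediate", "intermediate", "polysome",
                        "polysome", "polysome")


def generate_rrna_profiles(seed: int = 0, noise_sd: float = 0.1,
                           scale: float = 1.0) -> tuple[pd.DataFrame, tuple[str, ...]]:
    """Canonical 18S/28S fraction profile with multiplicative noise.

    Returns the profile table and the expected role labels.  ``scale``
    multiplies all raw quantities (role calls are scale-invariant).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for f in FRACTIONS:
        q18, q28 = CANONICAL_RRNA[f]
        rows.append({
            "fraction": f,
            "qty_18S": q18 * scale * np.exp(rng.normal(0, noise_sd)),
            "qty_28S": q28 * scale * np.exp(rng.normal(0, noise_sd)),
        })
    return pd.DataFrame(rows), CANONICAL_RRNA_ROLES


# ---------------------------------------------------------------------------
# hand-built worked example

_WE_STAGES = ("GV", "8C")

# transcriptome counts per stage (all transcript lengths 1000 nt, every
# sample column sums to 10000, so TPM = count x 100)
_WE_TRANSCRIPTOME = {
    "GV": {"g_m1": 20, "g_m2": 3000, "g_m3": 2500, "g_m4": 300, "g_mat": 800,
           "g_emb": 10, "g_b1": 50, "g_b2": 100, "g_b3": 200, "g_b4": 400,
           "g_b5": 600, "g_b6": 2020},
    "8C": {"g_m1": 20, "g_m2": 3000, "g_m3": 2500, "g_m4": 300, "g_mat": 5,
           "g_emb": 800, "g_b1": 50, "g_b2": 100, "g_b3": 200, "g_b4": 400,
           "g_b5": 600, "g_b6": 2025},
}

# fraction counts F1..F10 (per stage; g_b6 balances every column to 10000)
_WE_FRACTION_BASE = {
    "g_m1": [5, 5, 10, 20, 30, 45, 60, 80, 100, 120],
    "g_m2": [200, 200, 300, 400, 500, 600, 700, 800, 900, 1000],
    "g_m3": [450] * 10,
    "g_m4": [100, 100, 800, 700, 600, 300, 200, 100, 80, 60],
    # flat backgrounds at TE 1.2 (fraction counts = 1.2 x transcriptome)
    "g_b1": [60] * 10, "g_b2": [120] * 10, "g_b3": [240] * 10,
    "g_b4": [480] * 10, "g_b5": [720] * 10,
}

_WE_UTR = {
    # gene: (n CPEs to splice in, utr3 target length, utr5 length)
    "g_m1": (1, 150, 180), "g_m2": (3, 300, 140), "g_m3": (5, 400, 110),
    "g_m4": (4, 350, 120), "g_mat": (2, 240, 90), "g_emb": (0, 200, 160),
    "g_b1": (0, 180, 50), "g_b2": (1, 220, 100), "g_b3": (1, 260, 101),
    "g_b4": (2, 320, 130), "g_b5": (0, 150, 200), "g_b6": (1, 210, 150),
}

_WE_EXPECTED_MODE = {
    "g_m1": "1", "g_m2": "2", "g_m3": "3", "g_m4": "4",
    "g_mat": "none", "g_emb": "none", "g_b1": "none", "g_b2": "none",
    "g_b3": "none", "g_b4": "none", "g_b5": "none", "g_b6": "none",
}


def _we_sequence(n_motifs: int, length: int) -> str:
    """T-free background spliced with CPE motifs -> exact, countable CPEs.

    The first two motifs are placed adjacently overlapping-style
    (TTTTATTTTAT) when n >= 2, so the fixture also exercises the
    overlap-tolerant scan.
    """
    bg = ("ACGGCAGCGA" * (length // 10 + 2))[:length]
    if n_motifs == 0:
        return bg
    pieces = []
    if n_motifs >= 2:
        pieces.append("TTTTATTTTAT")  # two overlapping TTTTAT matches
        remaining = n_motifs - 2
    else:
        pieces.append("TTTTAT")
        remaining = 0
    seq = bg[:20] + pieces[0]
    pos = 20 + len(pieces[0])
    for k in range(remaining):
        seq += bg[pos:pos + 30] + "TTTTAT"
        pos += 30
    seq += bg[:max(length - len(seq), 0)]
    return seq[:length]


def worked_example() -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame]:
    """The hand-verifiable 12-gene, 2-stage miniature experiment.

    Returns (counts, annotation, expected) where ``expected`` lists the
    documented per-stage mode labels and TE values.  All transcript
    lengths are 1000 nt and every sample column sums to 10000 counts, so
    TPM = count x 100 and every downstream quantity can be checked by
    hand.
    """
    genes = list(_WE_EXPECTED_MODE)
    rows = []
    for stage in _WE_STAGES:
        for f in FRACTIONS:
            rows.append({"sample_id": f"{stage}_F{f}_r1", "stage": stage,
                         "sample_type": "fraction", "fraction": f, "replicate": 1})
        rows.append({"sample_id": f"{stage}_T_r1", "stage": stage,
                     "sample_type": "transcriptome", "fraction": pd.NA,
                     "replicate": 1})
    sheet = validate_sample_sheet(pd.DataFrame(rows))
    counts = pd.DataFrame(0, index=pd.Index(genes, name="gene_id"),
                          columns=list(sheet["sample_id"]), dtype=np.int64)
    for stage in _WE_STAGES:
        frac = dict(_WE_FRACTION_BASE)
        # program genes: TE 1.0 at their high stage, 0.8 at their low stage
        frac["g_mat"] = [800] * 10 if stage == "GV" else [4] * 10
        frac["g_emb"] = [4] * 10 if stage == "GV" else [800] * 10
        for fi, f in enumerate(FRACTIONS):
            col = f"{stage}_F{f}_r1"
            subtotal = sum(frac[g][fi] for g in frac)
            frac_col = dict(frac)
            for g, vals in frac_col.items():
                counts.loc[g, col] = vals[fi]
            counts.loc["g_b6", col] = 10000 - subtotal
        tcol = f"{stage}_T_r1"
        for g, v in _WE_TRANSCRIPTOME[stage].items():
            counts.loc[g, tcol] = v
    cm = CountMatrix(counts, sheet)
    annot = pd.DataFrame({
        "transcript_length": 1000,
        "utr5_length": [_WE_UTR[g][2] for g in genes],
        "utr3_length": [_WE_UTR[g][1] for g in genes],
        "utr3_sequence": pd.array([_we_sequence(_WE_UTR[g][0], _WE_UTR[g][1])
                                   for g in genes], dtype="string"),
    }, index=pd.Index(genes, name="gene_id"))
    annot["length_mismatch"] = False
    expected = pd.DataFrame(
        [{"gene_id": g, "stage": s, "mode": _WE_EXPECTED_MODE[g]}
         for s in _WE_STAGES for g in genes])
    return cm, annot, expected


def write_worked_example(outdir) -> None:
    """Write the worked-example fixture as TSV/FASTA files."""
    from pathlib import Path

    from . import io as pio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cm, annot, expected = worked_example()
    pio.write_counts(cm, outdir / "counts.tsv")
    pio.write_sample_sheet(cm.samples, outdir / "samples.tsv")
    pio.write_annotation(annot, outdir / "annotation.tsv",
                         fasta=outdir / "utr3.fasta")
    pio.write_table(expected, outdir / "expected_modes.tsv")
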