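"""Four-mode translational-selectivity classification.

For each developmental stage the classifier combines three per-gene
quantities computed from fraction-resolved TPM:

* a monotone-gradient statistic: Spearman's rank correlation between
  log2(TPM+1) and fraction index over F3-F10 (free fractions F1-F2
  excluded), replicates entering as separate points; p-values are exact
  permutation probabilities when the number of points is <= 10 and a
  t-approximation otherwise, BH-corrected within stage;
* translational efficiency TE = P/A, with A the mean transcriptome TPM,
  P the mean polysome TPM (F8-F10) and M the mean monosome TPM (F3-F5);
  the intermediate fractions F6-F7 enter neither summary;
* per-stage abundance and TE tertiles among expressed genes.

Modes (checked in this order; mutually exclusive):

1. monosome storage (mode 4): M >= 2P with a significant decreasing
   gradient;
2. selective translation of non-abundant mRNAs (mode 1): bottom abundance
   tertile, top TE tertile, significant increasing gradient;
3. active but modest translation of abundant mRNAs (mode 2): top abundance
   tertile, significant increasing gradient, TE below the top-tertile cut;
4. translational suppression (mode 3): abundance at or above the lower
   tertile cut, bottom TE tertile, no significant increasing gradient.

All cutoffs are quantile-based, making the assignment invariant to global
rescaling of the expression matrix.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .design import (GRADIENT_FRACTIONS, MONOSOME_FRACTIONS,
                     POLYSOME_FRACTIONS)
from .normalize import bh_adjust

EXACT_PERM_MAX_N = 10


# ---------------------------------------------------------------------------
# gradient statistic


def _rank_rho(xr: np.ndarray, yr: np.ndarray) -> float:
    """Pearson correlation of rank vectors (tie-corrected Spearman)."""
    xd = xr - xr.mean()
    yd = yr - yr.mean()
    sx = np.sqrt((xd ** 2).sum())
    sy = np.sqrt((yd ** 2).sum())
    if sx == 0 or sy == 0:
        return 0.0
    return float((xd * yd).sum() / (sx * sy))


@lru_cache(maxsize=64)
def _perm_null(x_key: tuple, y_key: tuple) -> np.ndarray:
    """Exhaustive null distribution of rho for permuted y ranks.

    Keyed on the fixed x ranks and the sorted multiset of y ranks, so the
    n! enumeration is shared across genes with the same tie pattern.
    """
    xr = np.asarray(x_key, dtype=float)
    yr = np.asarray(y_key, dtype=float)
    n = len(xr)
    xd = xr - xr.mean()
    sx = np.sqrt((xd ** 2).sum())
    yd_sorted = yr - yr.mean()
    sy = np.sqrt((yd_sorted ** 2).sum())
    if sx == 0 or sy == 0:
        return np.zeros(1)
    perms = np.fromiter(itertools.chain.from_iterable(
        itertools.permutations(range(n))), dtype=np.int64).reshape(-1, n)
    rho = (yd_sorted[perms] @ xd) / (sx * sy)
    return rho


def spearman_exact(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Tie-corrected Spearman rho with an exact two-sided permutation p.

    Enumerates all n! orderings of the y ranks against the fixed x ranks;
    p = P(|rho_perm| >= |rho_obs|).  Constant y (all ties) returns rho 0,
    p 1.
    """
    xr = stats.rankdata(x)
    yr = stats.rankdata(y)
    rho = _rank_rho(xr, yr)
    if np.allclose(y, y[0]) or np.allclose(x, x[0]):
        return 0.0, 1.0
    null = _perm_null(tuple(xr), tuple(np.sort(yr)))
    p = float(np.mean(np.abs(null) >= abs(rho) - 1e-12))
    return rho, p


def _spearman_batch(y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized tie-corrected Spearman rho + t-approximation p.

    y is genes x points; x the shared fraction-index vector.
    """
    n = y.shape[1]
    xr = stats.rankdata(x)
    yr = stats.rankdata(y, axis=1)
    xd = xr - xr.mean()
    yd = yr - yr.mean(axis=1, keepdims=True)
    sx = np.sqrt((xd ** 2).sum())
    sy = np.sqrt((yd ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (yd @ xd) / (sx * sy)
    rho = np.where(sy == 0, 0.0, np.clip(rho, -1.0, 1.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / np.maximum(1.0 - rho ** 2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(sy == 0, 1.0, np.minimum(p, 1.0))
    return rho, p


def fraction_gradient(tpm: pd.DataFrame, sheet: pd.DataFrame, stage: str,
                      exact_max_n: int = EXACT_PERM_MAX_N) -> pd.DataFrame:
    """Per-gene Spearman gradient over fractions F3-F10 for one stage.

    Replicates enter as separate points (x = fraction index).  Genes with
    no expression in any F3-F10 sample get an NA row (excluded from BH).
    Returns gene_id, stage, rho, p_value, fdr, n_points.
    """
    sel = sheet[(sheet["stage"] == stage) & (sheet["sample_type"] == "fraction")
                & sheet["fraction"].isin(GRADIENT_FRACTIONS)]
    present = set(sel["fraction"].dropna().astype(int))
    missing = set(GRADIENT_FRACTIONS) - present
    if missing:
        raise ValueError(f"stage {stage}: missing gradient fractions {sorted(missing)}")
    ids = list(sel["sample_id"])
    x = sel["fraction"].to_numpy(dtype=float)
    y = np.log2(tpm[ids].to_numpy(dtype=float) + 1.0)
    n_points = len(ids)
    unexpressed = (tpm[ids].to_numpy() <= 0).all(axis=1)
    if n_points <= exact_max_n:
        rho = np.empty(y.shape[0])
        p = np.empty(y.shape[0])
        for g in range(y.shape[0]):
            rho[g], p[g] = spearman_exact(x, y[g])
    else:
        rho, p = _spearman_batch(y, x)
    rho = np.where(unexpressed, np.nan, rho)
    p = np.where(unexpressed, np.nan, p)
    return pd.DataFrame({
        "gene_id": tpm.index,
        "stage": stage,
        "rho": rho,
        "p_value": p,
        "fdr": bh_adjust(p),
        "n_points": n_points,
    })


# ---------------------------------------------------------------------------
# translational efficiency


def translational_efficiency(tpm: pd.DataFrame, sheet: pd.DataFrame, stage: str,
                             floor: float = 1.0, eps: float = 0.25) -> pd.DataFrame:
    """A, P, M and TE = P/A for one stage.

    A = mean transcriptome TPM, P = mean TPM over F8-F10 samples, M = mean
    over F3-F5.  The denominator is floored at ``eps`` TPM so near-floor A
    does not explode the ratio; TE is NA when both A and P are below the
    expression floor.  Genes with A below the floor but polysome signal at
    or above it stay TE-eligible — these are the selective-translation
    candidates.
    """
    trans = sheet[(sheet["stage"] == stage) & (sheet["sample_type"] == "transcriptome")]
    if trans.empty:
        raise ValueError(f"no transcriptome samples for stage {stage}")
    poly = sheet[(sheet["stage"] == stage) & (sheet["sample_type"] == "fraction")
                 & sheet["fraction"].isin(POLYSOME_FRACTIONS)]
    mono = sheet[(sheet["stage"] == stage) & (sheet["sample_type"] == "fraction")
                 & sheet["fraction"].isin(MONOSOME_FRACTIONS)]
    if poly.empty or mono.empty:
        raise ValueError(f"missing fraction samples for stage {stage}")
    a = tpm[list(trans["sample_id"])].mean(axis=1)
    p = tpm[list(poly["sample_id"])].mean(axis=1)
    m = tpm[list(mono["sample_id"])].mean(axis=1)
    te = p / np.maximum(a, eps)
    te = te.where(~((a < floor) & (p < floor)))
    return pd.DataFrame({
        "gene_id": tpm.index, "stage": stage,
        "A": a.to_numpy(), "P": p.to_numpy(), "M": m.to_numpy(),
        "TE": te.to_numpy(),
    })


# ---------------------------------------------------------------------------
# mode assignment


@dataclass
class ModeConfig:
    """Tunable thresholds of the mode rule lattice (all scale-free)."""

    expression_floor: float = 1.0      # TPM; expressed = A or P at/above it
    te_eps: float = 0.25               # TPM floor of the TE denominator
    monosome_factor: float = 2.0       # M >= factor * P gates mode 4
    fdr_gate: float = 0.05             # gradient significance gate
    abundance_quantiles: tuple[float, float] = (1 / 3, 2 / 3)
    te_quantiles: tuple[float, float] = (1 / 3, 2 / 3)


def assign_modes(gradient: pd.DataFrame, te: pd.DataFrame,
                 config: ModeConfig | None = None) -> pd.DataFrame:
    """Assign each expressed gene of one stage to mode 1-4 or ``none``.

    ``gradient`` and ``te`` must cover the same (gene, stage) universe.
    Returns the ModeAssignment table with supporting quantities and a
    rule-trace string.
    """
    cfg = config or ModeConfig()
    if not (gradient["gene_id"].tolist() == te["gene_id"].tolist()
            and (gradient["stage"] == te["stage"]).all()):
        raise ValueError("gradient and TE tables must align on (gene, stage)")
    df = te.merge(gradient[["gene_id", "rho", "fdr"]], on="gene_id", how="left")
    a = df["A"].to_numpy(dtype=float)
    p = df["P"].to_numpy(dtype=float)
    m = df["M"].to_numpy(dtype=float)
    tev = df["TE"].to_numpy(dtype=float)
    rho = df["rho"].to_numpy(dtype=float)
    fdr = df["fdr"].to_numpy(dtype=float)
    expressed = (a >= cfg.expression_floor) | (p >= cfg.expression_floor)
    if not expressed.any():
        import warnings
        warnings.warn("no expressed genes to classify")
    qa_lo, qa_hi = (np.quantile(a[expressed], cfg.abundance_quantiles)
                    if expressed.any() else (np.nan, np.nan))
    te_pool = tev[expressed & np.isfinite(tev)]
    qt_lo, qt_hi = (np.quantile(te_pool, cfg.te_quantiles) if te_pool.size
                    else (np.nan, np.nan))
    sig = np.isfinite(fdr) & (fdr < cfg.fdr_gate)
    inc = sig & (rho > 0)
    dec = sig & (rho < 0)
    finite_te = np.isfinite(tev)
    mode = np.array(["none"] * len(df), dtype=object)
    trace = np.array([""] * len(df), dtype=object)

    m4 = expressed & (m >= cfg.monosome_factor * p) & dec
    mode[m4] = "4"
    trace[m4] = f"M>={cfg.monosome_factor}P;grad-"

    m1 = expressed & (mode == "none") & (a <= qa_lo) & finite_te & (tev >= qt_hi) & inc
    mode[m1] = "1"
    trace[m1] = "A<=q1/3;TE>=q2/3;grad+"

    m2 = expressed & (mode == "none") & (a >= qa_hi) & inc & finite_te & (tev < qt_hi)
    mode[m2] = "2"
    trace[m2] = "A>=q2/3;TE<q2/3;grad+"

    m3 = (expressed & (mode == "none") & (a >= qa_lo) & finite_te
          & (tev <= qt_lo) & ~inc)
    mode[m3] = "3"
    trace[m3] = "A>=q1/3;TE<=q1/3;no-grad+"

    trace[~expressed] = "unexpressed"
    out = df[["gene_id", "stage", "A", "P", "M", "TE", "rho", "fdr"]].copy()
    out["expressed"] = expressed
    out["mode"] = mode
    out["rule_trace"] = trace
    return out


def classify_stage(tpm: pd.DataFrame, sheet: pd.DataFrame, stage: str,
                   config: ModeConfig | None = None) -> pd.DataFrame:
    """Gradient + TE + mode assignment for one stage in one call."""
    cfg = config or ModeConfig()
    grad = fraction_gradient(tpm, sheet, stage)
    te = translational_efficiency(tpm, sheet, stage, floor=cfg.expression_floor,
                                  eps=cfg.te_eps)
    return assign_modes(grad, te, cfg)
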