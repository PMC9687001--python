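"""Gradient-fractionation quality control.

The 18S and 28S rRNAs mark the 40S and 60S ribosomal subunits.  A
successful sucrose gradient therefore shows: low combined rRNA in the free
fractions, an 18S-dominant fraction (40S subunits), a 28S-dominant fraction
(60S subunits), and both rRNAs high in the monosome peak and again in the
rising polysome region.  Role calls made here are QC evidence only — the
analysis partition (F1-F2 free, F3-F5 monosome, F6-F7 intermediate, F8-F10
polysome) is fixed by :mod:`polymodes.design` and never re-inferred.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .design import FRACTIONS, GRADIENT_FRACTIONS, fraction_role


def normalize_rrna(profile: pd.DataFrame) -> pd.DataFrame:
    """Normalize 18S/28S qRT-PCR quantities per fraction.

    Each fraction's quantities are divided by the mean of its 18S and 28S
    levels (``norm_18S``, ``norm_28S``); the two experiment-level vectors
    are additionally rescaled to sum 1 across fractions (``rel_18S``,
    ``rel_28S``) for cross-experiment comparability.  All-zero fractions
    yield NA with a warning.  Output is invariant to global rescaling of
    the raw quantities.
    """
    prof = profile.sort_values("fraction").reset_index(drop=True).copy()
    q18 = prof["qty_18S"].to_numpy(dtype=float)
    q28 = prof["qty_28S"].to_numpy(dtype=float)
    mean = (q18 + q28) / 2.0
    zero = mean == 0
    if zero.any():
        warnings.warn(f"all-zero rRNA fractions: {prof['fraction'][zero].tolist()}")
    with np.errstate(invalid="ignore", divide="ignore"):
        prof["norm_18S"] = np.where(zero, np.nan, q18 / mean)
        prof["norm_28S"] = np.where(zero, np.nan, q28 / mean)
    for raw, rel in (("qty_18S", "rel_18S"), ("qty_28S", "rel_28S")):
        total = prof[raw].sum()
        prof[rel] = prof[raw] / total if total > 0 else np.nan
    return prof


@dataclass
class RoleCallResult:
    calls: pd.DataFrame  # fraction, role_call, expected_role, mismatch
    warnings: list[str] = field(default_factory=list)


def call_fraction_roles(profile: pd.DataFrame, r_hi: float = 2.0,
                        r_lo: float = 0.5, low_frac: float = 0.25,
                        peak_drop: float = 0.8) -> RoleCallResult:
    """Rule-based fraction role calls from a normalized rRNA profile.

    Rules (on the sum-to-one ``rel_*`` columns): combined signal below
    ``low_frac`` of the maximum -> free; 18S/28S ratio > ``r_hi`` -> 40S;
    ratio < ``r_lo`` -> 60S; otherwise the both-high region is split into
    the monosome peak, an intermediate dip (combined below ``peak_drop`` of
    the peak) and the polysome rise (combined recovering above it toward
    F10).  A profile with dynamic range < 2 is called ambiguous throughout.
    Calls incompatible with the fixed analysis partition are returned as
    QC warnings, never applied to the partition.
    """
    prof = normalize_rrna(profile) if "rel_18S" not in profile.columns else profile
    prof = prof.sort_values("fraction").reset_index(drop=True)
    if sorted(prof["fraction"]) != list(FRACTIONS):
        raise ValueError("all 10 fractions are required for role calling")
    combined = (prof["rel_18S"] + prof["rel_28S"]).to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = prof["rel_18S"].to_numpy() / prof["rel_28S"].to_numpy()
    calls = np.array(["ambiguous"] * 10, dtype=object)
    msgs: list[str] = []
    cmax = np.nanmax(combined)
    cmin = np.nanmin(combined)
    if not np.isfinite(cmax) or cmin <= 0 or cmax / cmin < 2.0:
        msgs.extend(f"F{f}: ambiguous rRNA profile (flat or degenerate)"
                    for f in prof["fraction"])
    else:
        low = low_frac * cmax
        high_region: list[int] = []
        for i in range(10):
            if combined[i] < low:
                calls[i] = "free"
            elif ratio[i] > r_hi:
                calls[i] = "40S"
            elif ratio[i] < r_lo:
                calls[i] = "60S"
            else:
                high_region.append(i)
        if high_region:
            peak = max(high_region[:max(1, len(high_region) // 2)],
                       key=lambda i: combined[i])
            state = "monosome"
            for i in high_region:
                if i <= peak:
                    calls[i] = "monosome"
                    continue
                if state != "polysome" and combined[i] < peak_drop * combined[peak]:
                    state = "intermediate"
                elif state in ("monosome", "intermediate") \
                        and combined[i] >= peak_drop * combined[peak] \
                        and combined[i] > combined[i - 1]:
                    state = "polysome"
                calls[i] = state
        compatible = {
            "free": {"free"},
            "monosome": {"40S", "60S", "monosome"},
            "intermediate": {"monosome", "intermediate", "polysome"},
            "polysome": {"polysome"},
        }
        for i, f in enumerate(prof["fraction"]):
            expected = fraction_role(int(f))
            if calls[i] not in compatible[expected]:
                msgs.append(f"F{f}: rRNA call {calls[i]!r} incompatible with "
                            f"analysis partition role {expected!r}")
    out = pd.DataFrame({
        "fraction": prof["fraction"],
        "role_call": calls,
        "expected_role": [fraction_role(int(f)) for f in prof["fraction"]],
        "normalized_18S": prof["norm_18S"],
        "normalized_28S": prof["norm_28S"],
    })
    out["mismatch"] = [any(m.startswith(f"F{f}:") for m in msgs)
                       for f in prof["fraction"]]
    return RoleCallResult(calls=out, warnings=msgs)


# ---------------------------------------------------------------------------
# replicate correlation and PCA


def replicate_correlation(tpm: pd.DataFrame, sheet: pd.DataFrame,
                          floor: float = 1.0) -> pd.DataFrame:
    """Pearson r between biological replicates per (stage, fraction) unit.

    Computed on log2(TPM+1) over genes expressed (TPM >= ``floor``) in at
    least one replicate of the unit.  Transcriptome replicates are grouped
    per stage with fraction NA.
    """
    rows = []
    sheet = sheet.reset_index(drop=True)
    for (stage, stype, frac), grp in sheet.groupby(
            ["stage", "sample_type", "fraction"], dropna=False):
        if len(grp) < 2:
            continue
        sub = tpm[list(grp["sample_id"])]
        expressed = (sub >= floor).any(axis=1)
        logx = np.log2(sub.loc[expressed] + 1.0)
        ids = list(grp["sample_id"])
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                r = pearsonr(logx[ids[i]], logx[ids[j]])[0] if expressed.sum() > 2 else np.nan
                rows.append({"stage": stage, "sample_type": stype,
                             "fraction": frac, "sample_a": ids[i],
                             "sample_b": ids[j], "pearson_r": r,
                             "n_genes": int(expressed.sum())})
    return pd.DataFrame(rows)


@dataclass
class PCAResult:
    coordinates: pd.DataFrame      # samples x components
    explained_variance: np.ndarray  # fractions, non-increasing


def pca(tpm: pd.DataFrame, n_components: int = 5,
        standardize: bool = True) -> PCAResult:
    """Correlation PCA of samples on log2(TPM+1).

    Genes are centered and (by default) unit-scaled across samples before a
    singular value decomposition; zero-variance genes are dropped.  Sign
    convention: the largest-magnitude gene loading of each component is
    positive, making results deterministic.
    """
    if tpm.shape[1] < 2:
        raise ValueError("PCA requires at least two samples")
    logx = np.log2(tpm.to_numpy(dtype=float).T + 1.0)  # samples x genes
    center = logx - logx.mean(axis=0, keepdims=True)
    if standardize:
        sd = logx.std(axis=0, ddof=0)
        keep = sd > 1e-12
        center = center[:, keep] / sd[keep]
    n_components = min(n_components, min(center.shape))
    u, s, vt = np.linalg.svd(center, full_matrices=False)
    total_var = (s ** 2).sum()
    for k in range(n_components):
        j = int(np.argmax(np.abs(vt[k])))
        if vt[k, j] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    coords = u[:, :n_components] * s[:n_components]
    evr = (s[:n_components] ** 2) / total_var if total_var > 0 else np.zeros(n_components)
    cols = [f"PC{i+1}" for i in range(n_components)]
    return PCAResult(
        coordinates=pd.DataFrame(coords, index=tpm.columns, columns=cols),
        explained_variance=evr,
    )
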