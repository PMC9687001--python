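"""3'UTR cytoplasmic-polyadenylation-element scanning and UTR correlates.

CPEs are U-rich elements in mRNA 3'UTRs that control cytoplasmic
polyadenylation and translational activation of stored maternal
transcripts.  Scanning is exact-match, case-insensitive, sense strand
only, overlap-tolerant (a sliding window; a position matching two distinct
motifs contributes once per motif).  ``N`` never matches.

The motif set:
TTTTAT, TTTTAAT, TTTTACT, TTTTCAT, TTTTAAAT, TTTTAAGT.

Genes whose 5' or 3' UTR is 100 nt or shorter are excluded from UTR
feature correlations; CPE density is reported per kb of 3'UTR (any fixed
unit only rescales, never re-ranks, so Spearman correlations downstream do
not depend on the choice).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

CPE_MOTIFS = ("TTTTAT", "TTTTAAT", "TTTTACT", "TTTTCAT", "TTTTAAAT", "TTTTAAGT")

_DNA = set("ACGTN")

UTR_MIN_LENGTH = 100  # lengths <= this are excluded from UTR analyses


def scan_cpe(utr3_sequence: str) -> int:
    """Count exact CPE motif matches in a sense-strand 3'UTR sequence.

    Overlapping occurrences count; sequences must be over {A,C,G,T,N}.
    """
    seq = utr3_sequence.upper()
    bad = set(seq) - _DNA
    if bad:
        raise ValueError(f"non-DNA characters in sequence: {sorted(bad)}")
    total = 0
    for motif in CPE_MOTIFS:
        start = seq.find(motif)
        while start != -1:
            total += 1
            start = seq.find(motif, start + 1)
    return total


def cpe_density(count: int, utr3_length: int) -> float:
    """CPE motifs per kb of 3'UTR."""
    if utr3_length <= 0:
        raise ValueError("utr3_length must be positive")
    return count * 1000.0 / utr3_length


def utr_filter(annotation: pd.DataFrame) -> pd.Index:
    """Genes retained for UTR analyses: both UTRs strictly longer than 100 nt."""
    keep = (annotation["utr5_length"] > UTR_MIN_LENGTH) & \
           (annotation["utr3_length"] > UTR_MIN_LENGTH)
    return annotation.index[keep]


def utr_features(annotation: pd.DataFrame) -> pd.DataFrame:
    """Per-gene UTRFeatures table: CPE count/density and UTR lengths.

    Genes without a 3'UTR sequence get cpe_count 0 with ``has_sequence``
    False; downstream CPE correlations exclude them while length
    correlations keep them.
    """
    rows = []
    for gid, rec in annotation.iterrows():
        seq = rec.get("utr3_sequence")
        has_seq = isinstance(seq, str) and len(seq) > 0
        count = scan_cpe(seq) if has_seq else 0
        dens = (cpe_density(count, int(rec["utr3_length"]))
                if rec["utr3_length"] > 0 else np.nan)
        rows.append({"gene_id": gid, "cpe_count": count,
                     "cpe_density": dens if has_seq else np.nan,
                     "utr3_length": int(rec["utr3_length"]),
                     "utr5_length": int(rec["utr5_length"]),
                     "has_sequence": has_seq})
    return pd.DataFrame(rows).set_index("gene_id")


LENGTH_FEATURES = ("utr3_length", "utr5_length")
CPE_FEATURES = ("cpe_count", "cpe_density")


def te_feature_correlation(te: pd.DataFrame, features: pd.DataFrame,
                           annotation: pd.DataFrame | None = None,
                           min_genes: int = 10) -> pd.DataFrame:
    """Spearman correlation of TE with CPE and UTR-length features.

    ``te`` is a (possibly multi-stage) TEResult table; correlations are
    reported per stage and pooled (stage == 'all').  The UTR length filter
    (> 100 nt on both UTRs) is applied first; CPE features additionally
    require a sequence.
    """
    if annotation is not None:
        retained = utr_filter(annotation)
    else:
        retained = utr_filter(features)
    feats = features.loc[features.index.isin(retained)]
    rows = []
    groups = [(s, sub) for s, sub in te.groupby("stage")]
    if te["stage"].nunique() > 1:
        groups.append(("all", te))
    for stage, sub in groups:
        merged = sub.merge(feats, left_on="gene_id", right_index=True)
        merged = merged[np.isfinite(merged["TE"])]
        for feature in LENGTH_FEATURES + CPE_FEATURES:
            use = merged if feature in LENGTH_FEATURES else merged[merged["has_sequence"]]
            use = use[np.isfinite(use[feature].astype(float))]
            if len(use) < min_genes:
                rows.append({"feature": feature, "stage": stage,
                             "spearman_rho": np.nan, "p_value": np.nan,
                             "n_genes": len(use)})
                continue
            rho, p = stats.spearmanr(use["TE"], use[feature])
            rows.append({"feature": feature, "stage": stage,
                         "spearman_rho": rho, "p_value": p, "n_genes": len(use)})
    return pd.DataFrame(rows)
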