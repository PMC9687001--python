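"""Readers and writers for the pipeline's external artifacts.

Canonical formats are plain text: tab-separated tables (``#`` comments,
UTF-8, ``NA`` as the sole missing-value token), MatrixMarket sparse count
matrices with ``.rows``/``.cols`` sidecar id files, and FASTA for 3'UTR
sequences.  Count matrices are gene-level, genes in rows, one header column
per sample id.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .design import FRACTIONS, SAMPLE_TYPES, STAGES

NA_TOKEN = "NA"

SAMPLE_SHEET_COLUMNS = ["sample_id", "stage", "sample_type", "fraction", "replicate"]


class FormatError(ValueError):
    """Raised when an input file violates a format contract."""


# ---------------------------------------------------------------------------
# sample sheet


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample sheet and return it with normalized dtypes.

    Required columns: sample_id, stage, sample_type, fraction, replicate.
    ``fraction`` must be present (1-10) iff sample_type == 'fraction'.
    """
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise FormatError(f"sample sheet missing columns: {missing}")
    sheet = sheet[SAMPLE_SHEET_COLUMNS].copy()
    if sheet["sample_id"].duplicated().any():
        dups = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"duplicate sample ids: {dups}")
    bad_stage = set(sheet["stage"]) - set(STAGES)
    if bad_stage:
        raise FormatError(f"unknown stages: {sorted(bad_stage)}")
    bad_type = set(sheet["sample_type"]) - set(SAMPLE_TYPES)
    if bad_type:
        raise FormatError(f"unknown sample types: {sorted(bad_type)}")
    is_frac = sheet["sample_type"] == "fraction"
    frac = pd.to_numeric(sheet["fraction"], errors="coerce")
    if frac[is_frac].isna().any():
        raise FormatError("fraction index required for fraction samples")
    if frac[~is_frac].notna().any():
        raise FormatError("fraction index must be absent for transcriptome samples")
    if not frac[is_frac].isin(FRACTIONS).all():
        raise FormatError("fraction indices must be in 1-10")
    sheet["fraction"] = frac.astype("Int64")
    sheet["replicate"] = pd.to_numeric(sheet["replicate"]).astype(int)
    if (sheet["replicate"] < 1).any():
        raise FormatError("replicate must be a positive integer")
    return sheet.reset_index(drop=True)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", comment="#", na_values=[NA_TOKEN],
                        keep_default_na=False, dtype={"sample_id": str, "stage": str})
    return validate_sample_sheet(sheet)


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    validate_sample_sheet(sheet).to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN)


# ---------------------------------------------------------------------------
# count matrices


@dataclass
class CountMatrix:
    """Raw gene x sample counts with fraction/stage/replicate metadata.

    ``counts`` is a genes x samples integer DataFrame whose columns match
    ``samples['sample_id']`` in order.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.samples = validate_sample_sheet(self.samples)
        if list(self.counts.columns) != list(self.samples["sample_id"]):
            raise FormatError("count columns do not match sample sheet order")
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise FormatError(f"duplicate gene ids: {dups}")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise FormatError("counts must be integers")
            self.counts = self.counts.round().astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise FormatError("negative counts are not allowed")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    def subset_samples(self, mask: pd.Series | np.ndarray) -> "CountMatrix":
        sub = self.samples.loc[np.asarray(mask)].reset_index(drop=True)
        return CountMatrix(self.counts[list(sub["sample_id"])], sub)


def read_counts(path: str | Path, sheet: pd.DataFrame) -> CountMatrix:
    """Read a counts TSV (or MatrixMarket ``.mtx``) aligned to ``sheet``.

    The file's sample ids must be a superset of the sheet's; the returned
    matrix follows the sheet's sample order.  Errors name the offending
    sample or cell.
    """
    path = Path(path)
    sheet = validate_sample_sheet(sheet)
    if path.suffix == ".mtx":
        from scipy.io import mmread

        genes = Path(str(path) + ".rows").read_text().split()
        cols = Path(str(path) + ".cols").read_text().split()
        mat = mmread(path)
        mat = np.asarray(mat.todense()) if hasattr(mat, "todense") else np.asarray(mat)
        counts = pd.DataFrame(mat, index=genes, columns=cols)
    else:
        counts = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    missing = [s for s in sheet["sample_id"] if s not in counts.columns]
    if missing:
        raise FormatError(f"samples missing from counts file: {missing}")
    vals = counts.to_numpy()
    if not np.issubdtype(vals.dtype, np.number):
        bad = np.argwhere(~np.char.isnumeric(counts.astype(str).to_numpy()))
        r, c = bad[0] if len(bad) else (0, 0)
        raise FormatError(
            f"non-integer count at gene {counts.index[r]!r}, sample {counts.columns[c]!r}")
    if not np.allclose(vals, np.round(vals)):
        r, c = np.argwhere(~np.isclose(vals, np.round(vals)))[0]
        raise FormatError(
            f"non-integer count at gene {counts.index[r]!r}, sample {counts.columns[c]!r}")
    if (vals < 0).any():
        r, c = np.argwhere(vals < 0)[0]
        raise FormatError(
            f"negative count at gene {counts.index[r]!r}, sample {counts.columns[c]!r}")
    return CountMatrix(counts[list(sheet["sample_id"])].astype(np.int64), sheet)


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".mtx":
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix

        mmwrite(str(path), csr_matrix(cm.counts.to_numpy()))
        Path(str(path) + ".rows").write_text("\n".join(cm.genes) + "\n")
        Path(str(path) + ".cols").write_text("\n".join(cm.counts.columns) + "\n")
    else:
        cm.counts.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# transcript annotation


ANNOTATION_COLUMNS = ["gene_id", "transcript_length", "utr5_length", "utr3_length"]


def read_annotation(path: str | Path, fasta: str | Path | None = None) -> pd.DataFrame:
    """Read the per-gene canonical-transcript annotation table.

    Columns: gene_id, transcript_length, utr5_length, utr3_length.  When a
    3'UTR FASTA is given, sequences are joined by gene id; records whose
    sequence length disagrees with ``utr3_length`` get ``length_mismatch``
    set.  FASTA ids absent from the table produce a warning and are dropped.
    """
    tab = pd.read_csv(path, sep="\t", comment="#", na_values=[NA_TOKEN],
                      keep_default_na=False)
    missing = [c for c in ANNOTATION_COLUMNS if c not in tab.columns]
    if missing:
        raise FormatError(f"annotation missing columns: {missing}")
    if tab["gene_id"].duplicated().any():
        dups = tab.loc[tab["gene_id"].duplicated(), "gene_id"].tolist()
        raise FormatError(f"duplicate gene_id in annotation: {dups}")
    for col in ANNOTATION_COLUMNS[1:]:
        tab[col] = pd.to_numeric(tab[col]).astype(int)
        if (tab[col] < 0).any():
            raise FormatError(f"negative {col} in annotation")
    tab = tab.set_index("gene_id")
    if "utr3_sequence" not in tab.columns:
        tab["utr3_sequence"] = pd.Series(pd.NA, index=tab.index, dtype="string")
    tab["utr3_sequence"] = tab["utr3_sequence"].astype("string")
    if fasta is not None:
        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")}
        unknown = sorted(set(seqs) - set(tab.index))
        if unknown:
            warnings.warn(f"FASTA ids absent from annotation, ignored: {unknown}")
        for gid, seq in seqs.items():
            if gid in tab.index:
                tab.loc[gid, "utr3_sequence"] = seq
    tab["length_mismatch"] = [
        (isinstance(s, str) and len(s) != l)
        for s, l in zip(tab["utr3_sequence"].tolist(), tab["utr3_length"])
    ]
    return tab


def write_annotation(annot: pd.DataFrame, path: str | Path,
                     fasta: str | Path | None = None) -> None:
    out = annot.reset_index()[ANNOTATION_COLUMNS]
    out.to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN)
    if fasta is not None:
        with open(fasta, "w") as fh:
            for gid, seq in annot["utr3_sequence"].items():
                if isinstance(seq, str) and seq:
                    fh.write(f">{gid}\n")
                    for i in range(0, len(seq), 70):
                        fh.write(seq[i:i + 70] + "\n")


# ---------------------------------------------------------------------------
# rRNA profiles


def read_rrna(path: str | Path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t", comment="#", na_values=[NA_TOKEN],
                      keep_default_na=False)
    for col in ("fraction", "qty_18S", "qty_28S"):
        if col not in tab.columns:
            raise FormatError(f"rRNA profile missing column {col}")
    if sorted(tab["fraction"]) != list(FRACTIONS):
        raise FormatError("rRNA profile must have exactly one record per fraction 1-10")
    if (tab[["qty_18S", "qty_28S"]].to_numpy() < 0).any():
        raise FormatError("rRNA quantities must be non-negative")
    return tab.sort_values("fraction").reset_index(drop=True)


def write_rrna(profile: pd.DataFrame, path: str | Path) -> None:
    write_table(profile, path)


# ---------------------------------------------------------------------------
# generic result tables


def write_table(rows: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV: deterministic column order, floats at
    6 significant digits, NaN as ``NA``.  Empty tables keep their header."""
    rows.to_csv(path, sep="\t", index=False, na_rep=NA_TOKEN, float_format="%.6g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=[NA_TOKEN],
                       keep_default_na=False)
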