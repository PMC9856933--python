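"""Readers and writers for the plain-text exchange formats.

Expression and count matrices travel as TSV with genes as rows and a
header of sample ids; genomic intervals as BED (0-based half-open,
tab-separated, no header); segment tables as BED plus patient and
copy-number columns; variant tables as a VCF-like TSV with explicit
depth/allele-fraction columns; gene modules as GMT.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "read_matrix_tsv", "write_matrix_tsv",
    "read_segments_bed", "write_segments_bed",
    "read_bed4", "write_bed4",
    "read_variants_tsv", "write_variants_tsv",
    "read_annotation_tsv", "write_annotation_tsv",
    "write_gmt", "read_gmt",
]

_FLOAT_FMT = "%.6g"


def write_matrix_tsv(m: pd.DataFrame, path, index_label: str = "gene_id") -> None:
    m.to_csv(path, sep="\t", index_label=index_label, float_format=_FLOAT_FMT)


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_segments_bed(segs: pd.DataFrame, path) -> None:
    """BED-like: chrom, start, end, patient_id, copy_number (no header)."""
    segs[["chrom", "start", "end", "patient_id", "copy_number"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_segments_bed(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "patient_id", "copy_number"],
    )
    bad = df.index[(df.start >= df.end) | (df.start < 0)]
    if len(bad):
        raise ValueError(f"malformed interval at line {int(bad[0]) + 1} of {path}")
    return df


def write_bed4(df: pd.DataFrame, path, name_col: str) -> None:
    df[["chrom", "start", "end", name_col]].to_csv(path, sep="\t", header=False, index=False)


def read_bed4(path, name_col: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", name_col])
    bad = df.index[(df.start >= df.end) | (df.start < 0)]
    if len(bad):
        raise ValueError(f"malformed interval at line {int(bad[0]) + 1} of {path}")
    return df


_VARIANT_COLS = {
    "patient_id": "PATIENT", "chrom": "CHROM", "pos": "POS", "ref": "REF",
    "alt": "ALT", "gene": "GENE", "class": "CLASS", "t_depth": "T_DEPTH",
    "t_af": "T_AF", "n_depth": "N_DEPTH", "n_af": "N_AF", "pop_af": "POP_AF",
    "coding": "CODING", "synonymous": "SYNONYMOUS", "rna_depth": "RNA_DEPTH",
}


def write_variants_tsv(v: pd.DataFrame, path) -> None:
    out = v[[c for c in _VARIANT_COLS if c in v.columns]].rename(columns=_VARIANT_COLS)
    for col in ("CODING", "SYNONYMOUS"):
        if col in out.columns:
            out[col] = out[col].astype(int)
    out.to_csv(path, sep="\t", index=False)


def read_variants_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    inv = {v: k for k, v in _VARIANT_COLS.items()}
    df = df.rename(columns=inv)
    for col in ("coding", "synonymous"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df


def write_annotation_tsv(ann: pd.DataFrame, path) -> None:
    ann.to_csv(path, sep="\t", index_label="sample_id", float_format=_FLOAT_FMT)


def read_annotation_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_gmt(modules, path) -> None:
    """Gene modules as GMT: id, description, tab-separated gene list."""
    with open(path, "w") as fh:
        for m in modules:
            desc = f"size={m.size};flagged={int(m.flagged)}"
            fh.write("\t".join([m.module_id, desc, *m.genes]) + "\n")


def read_gmt(path) -> dict:
    out = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            out[parts[0]] = parts[2:]
    return out
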