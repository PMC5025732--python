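"""Readers and writers for the plain-text genomic formats the pipeline touches.

BED and bedGraph are consumed/emitted 0-based half-open as on disk; GTF/GFF
(1-based, closed) is converted to the internal convention on read.
"""

from __future__ import annotations

import logging

import gffutils
import numpy as np
import pandas as pd

from .intervals import ChromSizes, validate_reads

logger = logging.getLogger("chromdyn")

_BED_READ_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed_reads(path, sizes: ChromSizes,
                   default_strand: str | None = None,
                   deduplicate: bool = False) -> pd.DataFrame:
    """Load mapped reads from a BED3+ file into a read table.

    Records on chromosomes absent from ``sizes`` are dropped (count logged).
    A missing strand column is an error unless ``default_strand`` is given.
    With ``deduplicate``, reads identical in (chrom, start, end, strand)
    collapse to one copy (off by default: the protocols this consumes are
    commonly run without duplicate marking).
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#",
                         dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return pd.DataFrame({"chrom": pd.Series(dtype=str),
                             "start": pd.Series(dtype=np.int64),
                             "end": pd.Series(dtype=np.int64),
                             "strand": pd.Series(dtype=str)})
    if df.shape[1] < 3:
        raise ValueError(f"{path}: not a BED3+ file (fewer than 3 columns)")
    df = df.rename(columns=dict(enumerate(_BED_READ_COLS)))
    for col in ("start", "end"):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            lineno = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise ValueError(f"{path}: malformed {col} field at line {lineno}")
        df[col] = converted.astype(np.int64)
    if "strand" in df.columns:
        df["strand"] = df["strand"].str.strip()
    elif default_strand is not None:
        df["strand"] = default_strand
    else:
        raise ValueError(f"{path}: no strand column and no default strand")

    known = df["chrom"].isin(list(sizes))
    n_drop = int((~known).sum())
    if n_drop:
        logger.info("%s: dropped %d reads on unknown chromosomes", path, n_drop)
        df = df[known].reset_index(drop=True)
    reads = df[["chrom", "start", "end", "strand"]].copy()
    if deduplicate:
        n0 = len(reads)
        reads = reads.drop_duplicates().reset_index(drop=True)
        if len(reads) < n0:
            logger.info("%s: removed %d duplicate reads", path,
                        n0 - len(reads))
    validate_reads(reads, sizes)
    return reads


def write_bed_reads(reads: pd.DataFrame, path) -> None:
    out = reads[["chrom", "start", "end"]].copy()
    out["name"] = "."
    out["score"] = 0
    out["strand"] = reads["strand"].to_numpy()
    out.to_csv(path, sep="\t", header=False, index=False)


def read_gene_annotation(path) -> pd.DataFrame:
    """Load genes from GTF/GFF3 or BED12 into a table with one row per gene.

    Columns: gene_id, chrom, start, end, strand, tss (all 0-based half-open;
    tss is the first transcribed base). When a gene has several transcripts
    the longest one defines the record.
    """
    path = str(path)
    if path.endswith((".bed", ".bed12")):
        return _genes_from_bed12(path)
    return _genes_from_gff(path)


def _genes_from_gff(path) -> pd.DataFrame:
    db = gffutils.create_db(str(path), ":memory:", keep_order=True,
                            merge_strategy="create_unique",
                            disable_infer_genes=True,
                            disable_infer_transcripts=True)
    rows = []
    for feat in db.all_features():
        if feat.featuretype not in ("transcript", "mRNA", "gene"):
            continue
        gene_id = feat.attributes.get("gene_id", [feat.id])[0]
        if feat.strand not in ("+", "-"):
            raise ValueError(f"gene {gene_id} lacks a strand")
        rows.append((gene_id, feat.seqid, feat.start - 1, feat.end,
                     feat.strand, feat.featuretype))
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end",
                                     "strand", "featuretype"])
    # transcripts take precedence over the bare gene span when both exist
    has_tx = df["featuretype"].isin(("transcript", "mRNA"))
    tx_genes = set(df.loc[has_tx, "gene_id"])
    df = df[has_tx | ~df["gene_id"].isin(tx_genes)]
    return _longest_per_gene(df.drop(columns="featuretype"))


def _genes_from_bed12(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 6:
        raise ValueError(f"{path}: BED gene annotation needs >= 6 columns")
    df = df.iloc[:, :6]
    df.columns = ["chrom", "start", "end", "gene_id", "score", "strand"]
    if (~df["strand"].isin(("+", "-"))).any():
        raise ValueError(f"{path}: gene without strand")
    return _longest_per_gene(
        df[["gene_id", "chrom", "start", "end", "strand"]])


def _longest_per_gene(df: pd.DataFrame) -> pd.DataFrame:
    df = df.assign(_len=df["end"] - df["start"])
    df = (df.sort_values(["_len", "start"], ascending=[False, True])
            .drop_duplicates("gene_id")
            .drop(columns="_len"))
    tss = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
    out = df.assign(tss=tss).sort_values(["chrom", "start"])
    return out.reset_index(drop=True)


def write_genes_gtf(genes: pd.DataFrame, path, source: str = "chromdyn") -> None:
    """Write one gene + one transcript feature per record (1-based GTF)."""
    with open(path, "w") as fh:
        for row in genes.itertuples():
            attrs = (f'gene_id "{row.gene_id}"; '
                     f'transcript_id "{row.gene_id}.t1";')
            for ftype in ("gene", "transcript"):
                fh.write(f"{row.chrom}\t{source}\t{ftype}\t{row.start + 1}\t"
                         f"{row.end}\t.\t{row.strand}\t.\t{attrs}\n")


def write_track(values: dict[str, np.ndarray], bin_bp: int, path,
                sizes: ChromSizes | None = None) -> None:
    """Write a binned signal as bedGraph, run-length merging equal bins.

    Zero-valued bins are omitted, so an all-zero track writes no lines.
    """
    with open(path, "w") as fh:
        for chrom in values:
            v = np.asarray(values[chrom], dtype=float)
            if v.size == 0:
                continue
            change = np.flatnonzero(v[1:] != v[:-1]) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [v.size]))
            chrom_len = sizes[chrom] if sizes is not None else v.size * bin_bp
            for s, e in zip(starts, ends):
                val = v[s]
                if val == 0:
                    continue
                bp_end = min(int(e) * bin_bp, chrom_len)
                fh.write(f"{chrom}\t{int(s) * bin_bp}\t{bp_end}\t{val:.17g}\n")


def read_track(path, sizes: ChromSizes, bin_bp: int) -> dict[str, np.ndarray]:
    """Read a bedGraph produced by :func:`write_track` back into binned arrays."""
    values = {c: np.zeros(-(-sizes[c] // bin_bp)) for c in sizes}
    try:
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "value"])
    except pd.errors.EmptyDataError:
        return values
    for row in df.itertuples():
        if row.chrom not in values:
            raise KeyError(f"unknown chromosome {row.chrom!r} in {path}")
        b0 = int(row.start) // bin_bp
        b1 = -(-int(row.end) // bin_bp)
        values[row.chrom][b0:b1] = row.value
    return values


def write_bed6(df: pd.DataFrame, path) -> None:
    """Write a table with chrom/start/end/name/score/strand columns as BED6."""
    out = df[["chrom", "start", "end", "name", "score", "strand"]]
    out.to_csv(path, sep="\t", header=False, index=False)


def read_expression_table(path) -> pd.DataFrame:
    """Read a gene-level expression TSV: gene_id, rpkm_1, rpkm_2[, q_value]."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "rpkm_1", "rpkm_2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: expression table missing {sorted(missing)}")
    if "q_value" not in df.columns:
        df["q_value"] = 1.0
    return df
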