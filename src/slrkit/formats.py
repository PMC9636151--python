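"""Readers and writers for the standard formats the pipeline touches.

Coordinate conventions
----------------------
Internally every interval is 0-based, half-open (``[start, end)``), the BED
convention.  Conversion to and from 1-based inclusive coordinates happens
only at the VCF/GFF3 boundary.  "kb" values in reports are integer kb by
truncation toward zero.

All text I/O transparently supports gzip (files ending in ``.gz``).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

log = logging.getLogger("slrkit")

VALID_CONTEXTS = ("CG", "CHG", "CHH")

#: Column order of the allele-depth table shared by simdata, bsa and the TSV
#: reader/writer.  ``pos`` is 1-based at I/O (VCF convention).
POOL_CALL_COLUMNS = [
    "chrom", "pos", "ref", "alt",
    "ad_ref_f", "ad_alt_f", "ad_ref_m", "ad_alt_m",
]


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


@dataclass(frozen=True, order=True)
class GenomeInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def length_kb(self) -> int:
        """Length in integer kb, truncated toward zero."""
        return self.length // 1000

    def overlaps(self, other: "GenomeInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomeInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene as a translation-start/translation-end span with a strand.

    ``start``/``end`` delimit the gene body (translation start to translation
    termination) as a 0-based half-open interval regardless of strand; for a
    minus-strand gene the translation start site is at ``end - 1``.
    """

    id: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.id}: strand must be '+' or '-'")
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"gene {self.id}: invalid span {self.start}-{self.end}")

    @property
    def body(self) -> GenomeInterval:
        return GenomeInterval(self.chrom, self.start, self.end)


# ---------------------------------------------------------------------------
# Pooled allele-depth calls (VCF / TSV)
# ---------------------------------------------------------------------------

def _empty_pool_calls() -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype="int64") for c in POOL_CALL_COLUMNS})
    for c in ("chrom", "ref", "alt"):
        df[c] = df[c].astype(str)
    return df


def _finish_pool_calls(df: pd.DataFrame, n_skipped: int) -> pd.DataFrame:
    for c in ("ad_ref_f", "ad_alt_f", "ad_ref_m", "ad_alt_m", "pos"):
        bad = df[c] < 0
        if bad.any():
            raise ValueError(f"negative values in column {c}")
    df = df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
    df.attrs["n_skipped"] = n_skipped
    return df


def read_pool_calls(path, format: str | None = None) -> pd.DataFrame:
    """Read per-site allele depths for the two sex pools.

    Parameters
    ----------
    path:
        VCF (two samples, FEMALE then MALE, with an AD field) or a TSV with
        columns ``chrom pos ref alt ad_ref_f ad_alt_f ad_ref_m ad_alt_m``.
    format:
        ``"vcf"`` or ``"tsv"``; inferred from the file name when omitted.

    Returns a DataFrame in :data:`POOL_CALL_COLUMNS` order, sorted by
    (chrom, pos), with the number of skipped (non-biallelic-SNV) records in
    ``df.attrs["n_skipped"]``.
    """
    path = Path(path)
    if format is None:
        name = path.name.removesuffix(".gz")
        format = "vcf" if name.endswith(".vcf") else "tsv"
    if format == "vcf":
        return _read_pool_calls_vcf(path)
    if format == "tsv":
        return _read_pool_calls_tsv(path)
    raise ValueError(f"unknown pool-call format {format!r}")


def _read_pool_calls_tsv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.EmptyDataError:
        return _finish_pool_calls(_empty_pool_calls(), 0)
    missing = set(POOL_CALL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df = df[POOL_CALL_COLUMNS].copy()
    snv = df["ref"].str.len().eq(1) & df["alt"].str.len().eq(1) \
        & ~df["alt"].str.contains(",")
    n_skipped = int((~snv).sum())
    if n_skipped:
        log.info("read_pool_calls: skipped %d non-biallelic-SNV rows", n_skipped)
    df = df[snv].copy()
    df["chrom"] = df["chrom"].astype(str)
    return _finish_pool_calls(df, n_skipped)


def _read_pool_calls_vcf(path) -> pd.DataFrame:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    if len(vcf.samples) != 2:
        raise ValueError(
            f"{path}: expected 2 pool samples (female, male), got {vcf.samples}"
        )
    rows = []
    n_skipped = 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_skipped += 1
            continue
        ad = v.format("AD")
        if ad is None:
            raise ValueError(f"{path}: record {v.CHROM}:{v.POS} lacks an AD field")
        rows.append((
            v.CHROM, v.POS, v.REF, v.ALT[0],
            int(ad[0][0]), int(ad[0][1]), int(ad[1][0]), int(ad[1][1]),
        ))
    vcf.close()
    if n_skipped:
        log.info("read_pool_calls: skipped %d non-biallelic-SNV records", n_skipped)
    if not rows:
        return _finish_pool_calls(_empty_pool_calls(), n_skipped)
    df = pd.DataFrame(rows, columns=POOL_CALL_COLUMNS)
    return _finish_pool_calls(df, n_skipped)


def write_pool_calls_tsv(calls: pd.DataFrame, path) -> None:
    calls[POOL_CALL_COLUMNS].to_csv(path, sep="\t", index=False)


def write_pool_calls_vcf(calls: pd.DataFrame, path,
                         contig_lengths: dict[str, int] | None = None) -> None:
    """Write pool calls as VCF v4.2 with one AD-typed sample per pool."""
    with _open_text(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=slrkit\n")
        if contig_lengths:
            for chrom, length in contig_lengths.items():
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
        else:
            for chrom in dict.fromkeys(calls["chrom"].astype(str)):
                fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                 'Description="Allelic depths (ref,alt)">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT"
                 "\tFEMALE\tMALE\n")
        for row in calls.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t.\t"
                f"AD\t{row.ad_ref_f},{row.ad_alt_f}\t{row.ad_ref_m},{row.ad_alt_m}\n"
            )


# ---------------------------------------------------------------------------
# Per-cytosine methylation reports
# ---------------------------------------------------------------------------

CYTOSINE_COLUMNS = ["chrom", "pos", "strand", "n_methylated", "n_unmethylated",
                    "context"]


def read_cytosine_report(path) -> pd.DataFrame:
    """Read a per-cytosine methylation count table.

    Columns: chrom, pos (1-based), strand, n_methylated, n_unmethylated,
    context (CG/CHG/CHH).  An empty file yields an empty table.
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.EmptyDataError:
        df = pd.DataFrame({c: pd.Series(dtype="int64")
                           for c in CYTOSINE_COLUMNS})
        for c in ("chrom", "strand", "context"):
            df[c] = df[c].astype(str)
        return df
    missing = set(CYTOSINE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df = df[CYTOSINE_COLUMNS].copy()
    bad = ~df["context"].isin(VALID_CONTEXTS)
    if bad.any():
        tokens = sorted(df.loc[bad, "context"].unique())
        raise ValueError(f"{path}: unknown methylation context token(s) {tokens}")
    if ((df["n_methylated"] < 0) | (df["n_unmethylated"] < 0)).any():
        raise ValueError(f"{path}: negative methylation counts")
    df["chrom"] = df["chrom"].astype(str)
    return df.reset_index(drop=True)


def write_cytosine_report(records: pd.DataFrame, path) -> None:
    records[CYTOSINE_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED intervals and window tables
# ---------------------------------------------------------------------------

def write_bed(intervals: Sequence[GenomeInterval], path,
              names: Sequence[str] | None = None) -> None:
    """Write intervals as 0-based half-open BED; unsorted input is sorted."""
    ivs = list(intervals)
    idx = sorted(range(len(ivs)), key=lambda i: (ivs[i].chrom, ivs[i].start))
    if idx != list(range(len(ivs))):
        log.info("write_bed: input unsorted; sorting on write")
    with _open_text(path, "wt") as fh:
        for i in idx:
            iv = ivs[i]
            line = f"{iv.chrom}\t{iv.start}\t{iv.end}"
            if names is not None:
                line += f"\t{names[i]}"
            fh.write(line + "\n")


def read_bed(path) -> list[GenomeInterval]:
    out = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            chrom, start, end, *_ = line.split("\t")
            out.append(GenomeInterval(chrom, int(start), int(end)))
    return out


WINDOW_COLUMNS = ["chrom", "start", "end", "n_sites", "mean_delta",
                  "env_low", "env_high"]


def write_windows(windows: pd.DataFrame, path) -> None:
    """Write the windowed scan table (header always present)."""
    cols = [c for c in WINDOW_COLUMNS if c in windows.columns]
    windows[cols].to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_windows(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["chrom"] = df["chrom"].astype(str)
    return df


# ---------------------------------------------------------------------------
# FASTA and GFF3
# ---------------------------------------------------------------------------

def write_fasta(records: dict[str, str] | Iterable[tuple[str, str]], path,
                width: int = 80) -> None:
    items = records.items() if isinstance(records, dict) else records
    with _open_text(path, "wt") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper()
                for rec in SeqIO.parse(fh, "fasta")}


def write_gff3(genes: Sequence[GeneModel], path) -> None:
    """Write gene models as GFF3 gene features (1-based inclusive)."""
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            fh.write(
                f"{g.chrom}\tslrkit\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.id}\n"
            )


def read_gff3(path) -> list[GeneModel]:
    """Read gene features from GFF3 into :class:`GeneModel` records."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True,
                            merge_strategy="create_unique")
    out = []
    for feat in db.features_of_type("gene"):
        out.append(GeneModel(
            id=feat.id, chrom=feat.seqid, strand=feat.strand,
            start=feat.start - 1, end=feat.end,
        ))
    return sorted(out, key=lambda g: (g.chrom, g.start))


# ---------------------------------------------------------------------------
# Misc small tables
# ---------------------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
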