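"""Readers and writers for the genomic file formats the pipeline touches.

All in-memory coordinates are 0-based half-open (BED-native). VCF positions
are 1-based on disk and converted at the I/O boundary only: ``VariantRecord.pos``
keeps the VCF convention, and ``VariantRecord.pos0`` gives the 0-based point
coordinate for interval lookups.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd
import pysam
from pyfaidx import Fasta


class FormatError(ValueError):
    """A file did not conform to the expected format."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    score: Optional[float] = None
    strand: Optional[str] = None
    summit_offset: Optional[int] = None  # narrowPeak column 10, -1 if absent

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class AlignedRead:
    """One mapped single-end read, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("read end must exceed start")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


@dataclass(frozen=True)
class GeneModel:
    """A gene with strand-aware TSS/TES (both 0-based positions).

    For a ``+`` strand gene tss <= tes; for ``-`` strand tss >= tes.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tes: int
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")
        if self.strand == "+" and self.tss > self.tes:
            raise ValueError("tss must not exceed tes on + strand")
        if self.strand == "-" and self.tss < self.tes:
            raise ValueError("tss must not precede tes on - strand")

    @property
    def body(self) -> GenomicInterval:
        lo, hi = min(self.tss, self.tes), max(self.tss, self.tes)
        return GenomicInterval(self.chrom, lo, hi + 1)


@dataclass
class VariantRecord:
    """One VCF site. ``pos`` is 1-based per the VCF convention."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    quality: Optional[float]
    depth: Optional[int]
    sample_id: str = ""
    variant_id: Optional[str] = None
    missing_fields: list = field(default_factory=list)

    @property
    def pos0(self) -> int:
        """0-based point coordinate for interval arithmetic."""
        return self.pos - 1


# ---------------------------------------------------------------------------
# interval I/O


def read_intervals(path: str, dialect: str = "bed") -> list[GenomicInterval]:
    """Read a BED or narrowPeak file into intervals.

    narrowPeak column 10 (summit offset from start) is preserved when present.
    """
    if dialect not in ("bed", "narrowPeak"):
        raise ValueError(f"unknown dialect {dialect!r}")
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: expected >=3 tab-separated columns"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                score = float(fields[4])
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-." else None
            summit = None
            if dialect == "narrowPeak" and len(fields) >= 10:
                # signalValue (column 7) is the quantitative score
                if fields[6] not in (".", ""):
                    score = float(fields[6])
                summit = int(fields[9])
                if summit < 0:
                    summit = None
            out.append(
                GenomicInterval(fields[0], start, end, name, score, strand, summit)
            )
    return out


def write_intervals(
    intervals: Iterable[GenomicInterval], path: str, dialect: str = "bed"
) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if dialect == "narrowPeak":
                fields += [
                    iv.name or ".",
                    "0",
                    iv.strand or ".",
                    f"{iv.score:.6g}" if iv.score is not None else "0",
                    "-1",
                    "-1",
                    str(iv.summit_offset if iv.summit_offset is not None else -1),
                ]
            else:
                if iv.name is not None or iv.score is not None or iv.strand:
                    fields.append(iv.name or ".")
                if iv.score is not None or iv.strand:
                    fields.append(f"{iv.score:.6g}" if iv.score is not None else "0")
                if iv.strand:
                    fields.append(iv.strand)
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# read I/O


def read_reads(path: str, fmt: Optional[str] = None) -> tuple[list[AlignedRead], int]:
    """Read aligned single-end reads from BED or BAM/SAM.

    Returns ``(reads, n_mapped)`` where ``n_mapped`` is the count of mapped
    records read — the denominator for RPM normalization. Unmapped records
    are skipped and do not increment the counter.
    """
    if fmt is None:
        ext = os.path.splitext(path)[1].lower()
        fmt = {"bed": "bed", ".bed": "bed", ".bam": "bam", ".sam": "bam"}.get(ext)
        if fmt is None:
            raise ValueError(f"cannot infer read format from {path!r}")
    if fmt == "bed":
        reads = [
            AlignedRead(iv.chrom, iv.start, iv.end, iv.strand or "+")
            for iv in read_intervals(path, "bed")
        ]
        return reads, len(reads)
    if fmt == "bam":
        reads = []
        with pysam.AlignmentFile(path, check_sq=False) as bam:
            for rec in bam.fetch(until_eof=True):
                if rec.is_unmapped or rec.reference_start is None:
                    continue
                reads.append(
                    AlignedRead(
                        rec.reference_name,
                        rec.reference_start,
                        rec.reference_end or rec.reference_start + rec.query_length,
                        "-" if rec.is_reverse else "+",
                    )
                )
        return reads, len(reads)
    raise ValueError(f"unknown read format {fmt!r}")


def write_reads(reads: Iterable[AlignedRead], path: str) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tr{i}\t0\t{r.strand}\n")


# ---------------------------------------------------------------------------
# sequence access


def fetch_sequence(genome, interval: GenomicInterval) -> str:
    """Fetch the uppercase sequence of an interval, clipped to the chromosome.

    ``genome`` is a ``pyfaidx.Fasta`` handle (or a plain dict of sequences,
    which is convenient in tests).
    """
    if isinstance(genome, (dict,)):
        if interval.chrom not in genome:
            raise KeyError(f"chromosome {interval.chrom!r} not in genome")
        seq = str(genome[interval.chrom])
    else:
        if interval.chrom not in genome:
            raise KeyError(f"chromosome {interval.chrom!r} not in genome")
        seq = str(genome[interval.chrom][:])
    start = max(0, interval.start)
    end = min(len(seq), interval.end)
    if start >= end:
        return ""
    return seq[start:end].upper()


def open_genome(path: str) -> Fasta:
    return Fasta(path)


# ---------------------------------------------------------------------------
# variant I/O


def read_variants(path: str, sample_id: str = "") -> list[VariantRecord]:
    """Read a VCF into records, keeping positions 1-based.

    DP is taken from INFO/DP, falling back to the sum of per-sample FORMAT/DP.
    Records missing QUAL or DP are flagged in ``missing_fields`` rather than
    dropped. A VCF carrying DP nowhere at all raises.
    """
    records: list[VariantRecord] = []
    any_dp = False
    with pysam.VariantFile(path) as vcf:
        has_dp_header = "DP" in vcf.header.info or any(
            "DP" in vcf.header.formats for _ in (0,)
        )
        for rec in vcf:
            missing = []
            qual = rec.qual
            if qual is None:
                missing.append("quality")
            depth = rec.info.get("DP")
            if depth is None:
                fmt_dp = [
                    s.get("DP") for s in rec.samples.values() if s.get("DP") is not None
                ]
                depth = sum(fmt_dp) if fmt_dp else None
            if depth is None:
                missing.append("depth")
            else:
                any_dp = True
            alt = rec.alts[0] if rec.alts else "."
            records.append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref_allele=rec.ref,
                    alt_allele=alt,
                    quality=qual,
                    depth=int(depth) if depth is not None else None,
                    sample_id=sample_id,
                    variant_id=rec.id,
                    missing_fields=missing,
                )
            )
        if records and not any_dp and not has_dp_header:
            raise FormatError(
                f"{path}: no DP found in INFO or FORMAT of any record; "
                "re-call variants with depth annotation enabled"
            )
    return records


def write_variants(records: Sequence[VariantRecord], path: str, contigs=None) -> None:
    """Write records as a minimal VCF 4.2 with INFO/DP."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">\n')
        if contigs:
            for name, length in contigs:
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in records:
            qual = "." if r.quality is None else f"{r.quality:g}"
            info = "." if r.depth is None else f"DP={r.depth}"
            vid = r.variant_id or "."
            fh.write(
                f"{r.chrom}\t{r.pos}\t{vid}\t{r.ref_allele}\t{r.alt_allele}"
                f"\t{qual}\tPASS\t{info}\n"
            )


# ---------------------------------------------------------------------------
# tables


GENE_TABLE_COLUMNS = ["gene_id", "chrom", "strand", "start", "end", "biotype"]


def read_gene_table(path: str) -> list[GeneModel]:
    """Read a 6-column gene annotation TSV (gene_id, chrom, strand, start,
    end, biotype; start/end 0-based half-open) and derive TSS/TES by strand."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(GENE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    genes = []
    for row in df.itertuples(index=False):
        if row.strand == "+":
            tss, tes = int(row.start), int(row.end) - 1
        else:
            tss, tes = int(row.end) - 1, int(row.start)
        genes.append(
            GeneModel(str(row.gene_id), str(row.chrom), row.strand, tss, tes,
                      str(row.biotype))
        )
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise FormatError(f"{path}: duplicate gene_id values")
    return genes


def write_gene_table(genes: Sequence[GeneModel], path: str) -> None:
    rows = []
    for g in genes:
        lo, hi = min(g.tss, g.tes), max(g.tss, g.tes)
        rows.append((g.gene_id, g.chrom, g.strand, lo, hi + 1, g.biotype))
    pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_table(path: str, required: Optional[Sequence[str]] = None) -> pd.DataFrame:
    """Read a headered TSV (GWAS catalogue, LD table, qPCR table, id lists)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if required:
        missing = set(required) - set(df.columns)
        if missing:
            raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_id_list(path: str) -> set[str]:
    """Read a one-column list of variant ids (dbSNP-build emulation).

    Ids are ``chrom:pos`` (1-based) or rsIDs; a header line named ``id`` is
    tolerated.
    """
    ids = set()
    with open(path) as fh:
        for line in fh:
            tok = line.strip()
            if tok and tok.lower() != "id":
                ids.add(tok)
    return ids


def write_fasta(sequences: dict[str, str], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
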