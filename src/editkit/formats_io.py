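"""Readers and writers for the external formats the pipeline touches.

Coordinate conventions
----------------------
Internally every interval is half-open, 0-based.  Anything user-facing
(site tables, VCF, GTF) is 1-based, matching the habits of those formats.
``AlignedRead.pos`` keeps the 1-based SAM value; the per-base reference
coordinates stored on each read are 0-based.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")
DEFAULT_BARCODE_TAG = "CB"


class FormatError(ValueError):
    """Raised for malformed or unusable input files."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignedRead:
    """One mapped primary alignment with per-base reference placement.

    ``bases`` holds ``(ref_pos0, base, qual)`` triples for every aligned
    query base (insertions and clips are dropped, deletions/skips leave
    gaps), with strictly increasing 0-based reference coordinates.
    """

    query_name: str
    chrom: str
    pos: int                     # 1-based leftmost, as in SAM
    mapq: int
    strand: str                  # '+' or '-'
    bases: tuple                 # ((ref_pos0, base, qual), ...)
    barcode: Optional[str] = None


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int                   # 0-based
    end: int                     # half-open
    strand: str = "."
    label: str = ""

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval {self.chrom}:{self.start}-{self.end}")

    def __len__(self):
        return self.end - self.start

    def contains(self, pos0: int) -> bool:
        return self.start <= pos0 < self.end


REPEAT_FAMILIES = ("SINE", "LINE", "LTR", "DNA", "Simple_repeat", "Other")


@dataclass(frozen=True)
class RepeatInterval:
    interval: GenomicInterval
    family: str
    subfamily: str

    def __post_init__(self):
        if self.family not in REPEAT_FAMILIES:
            raise ValueError(f"unknown repeat family {self.family!r}")


@dataclass(frozen=True)
class SnpSite:
    chrom: str
    pos: int                     # 1-based
    ref: str
    alt: str

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError(f"SNP ref == alt at {self.chrom}:{self.pos}")


@dataclass
class GeneModel:
    """Stranded transcript structure used for region and recoding calls."""

    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    exons: list = field(default_factory=list)   # [GenomicInterval]
    cds: list = field(default_factory=list)     # [(GenomicInterval, frame)]
    utr5: list = field(default_factory=list)
    utr3: list = field(default_factory=list)
    codable: bool = True

    @property
    def span(self) -> tuple:
        parts = self.exons + [iv for iv, _ in self.cds] + self.utr5 + self.utr3
        return (min(iv.start for iv in parts), max(iv.end for iv in parts))

    def cds_length(self) -> int:
        return sum(len(iv) for iv, _ in self.cds)


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

def parse_alignments(
    path,
    barcode_tag: Optional[str] = DEFAULT_BARCODE_TAG,
    dedup_clonal: bool = True,
) -> Iterator[AlignedRead]:
    """Stream mapped primary records from a SAM file as :class:`AlignedRead`.

    Unmapped, secondary and supplementary records are skipped.  Per-base
    reference coordinates are reconstructed from the CIGAR (M/=/X consume
    both query and reference, I/S consume query only, D/N reference only).

    With ``dedup_clonal`` (default), only the first read is kept per
    (chrom, leftmost pos, strand, CIGAR) key — a simple stand-in for PCR
    duplicate removal; pass ``False`` for pre-deduplicated input.
    """
    path = str(path)
    seen: set = set()
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            strand = "-" if rec.is_reverse else "+"
            if dedup_clonal:
                key = (rec.reference_name, rec.reference_start, strand,
                       rec.cigarstring)
                if key in seen:
                    continue
                seen.add(key)
            try:
                pairs = rec.get_aligned_pairs(matches_only=True)
            except (ValueError, SystemError) as exc:  # pragma: no cover
                raise FormatError(
                    f"malformed CIGAR for record {rec.query_name!r} in {path}"
                ) from exc
            seq = rec.query_sequence or ""
            quals = rec.query_qualities
            if quals is None:
                quals = [0] * len(seq)
            bases = tuple(
                (rpos, seq[qpos], quals[qpos]) for qpos, rpos in pairs
            )
            barcode = None
            if barcode_tag and rec.has_tag(barcode_tag):
                barcode = str(rec.get_tag(barcode_tag))
            yield AlignedRead(
                query_name=rec.query_name,
                chrom=rec.reference_name,
                pos=rec.reference_start + 1,
                mapq=rec.mapping_quality,
                strand=strand,
                bases=bases,
                barcode=barcode,
            )


def write_sam(path, reads: Iterable[dict], reference_lengths: dict) -> None:
    """Write ungapped alignment records to a SAM file.

    Each read dict needs: name, chrom, pos0, seq, quals (list[int]),
    mapq; optional barcode.  Records are emitted in input order.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": int(n)} for c, n in reference_lengths.items()],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rd in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = rd["name"]
            a.query_sequence = rd["seq"]
            a.flag = 0
            a.reference_name = rd["chrom"]
            a.reference_start = rd["pos0"]
            a.mapping_quality = rd["mapq"]
            a.cigarstring = f"{len(rd['seq'])}M"
            a.query_qualities = rd["quals"]
            if rd.get("barcode"):
                a.set_tag("CB", rd["barcode"], value_type="Z")
            out.write(a)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict:
    """Load a FASTA file into a dict of upper-case sequence strings."""
    genome = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        genome[rec.id] = str(rec.seq).upper()
    if not genome:
        raise FormatError(f"no sequences in {path}")
    return genome


def write_fasta(path, genome: dict, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

def _gtf_attributes(col9: str) -> dict:
    attrs = {}
    for chunk in col9.strip().rstrip(";").split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, val = chunk.partition(" ")
        attrs[key] = val.strip().strip('"')
    return attrs


def parse_gene_models(path) -> list:
    """Parse a GTF subset (exon/CDS/five_prime_utr/three_prime_utr rows).

    GTF is 1-based inclusive; intervals are converted to half-open
    0-based.  Frame comes from column 8.  A gene whose total CDS length
    is not divisible by 3 is flagged non-codable with a warning.
    """
    genes: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _src, feature, start, end, _score, strand, frame, col9 = \
                fields[:9]
            if feature not in ("exon", "CDS", "five_prime_utr",
                               "three_prime_utr"):
                continue
            attrs = _gtf_attributes(col9)
            gid = attrs.get("gene_id")
            if gid is None:
                raise FormatError(f"{path}:{lineno}: missing gene_id")
            gene = genes.get(gid)
            if gene is None:
                gene = genes[gid] = GeneModel(
                    gene_id=gid,
                    gene_name=attrs.get("gene_name", gid),
                    chrom=chrom,
                    strand=strand,
                )
            iv = GenomicInterval(chrom, int(start) - 1, int(end),
                                 strand=strand, label=feature)
            if feature == "exon":
                gene.exons.append(iv)
            elif feature == "CDS":
                fr = 0 if frame == "." else int(frame)
                gene.cds.append((iv, fr))
            elif feature == "five_prime_utr":
                gene.utr5.append(iv)
            else:
                gene.utr3.append(iv)
    out = []
    for gene in genes.values():
        gene.exons.sort(key=lambda iv: iv.start)
        gene.cds.sort(key=lambda t: t[0].start)
        gene.utr5.sort(key=lambda iv: iv.start)
        gene.utr3.sort(key=lambda iv: iv.start)
        if gene.cds and gene.cds_length() % 3 != 0:
            warnings.warn(
                f"gene {gene.gene_id}: CDS length {gene.cds_length()} "
                "not divisible by 3; coding annotation disabled"
            )
            gene.codable = False
        elif not gene.cds:
            gene.codable = False
        out.append(gene)
    out.sort(key=lambda g: (g.chrom, g.span[0], g.gene_id))
    return out


def write_gtf(path, genes: Sequence[GeneModel]) -> None:
    def row(gene, feature, iv, frame="."):
        return "\t".join([
            gene.chrom, "editkit", feature, str(iv.start + 1), str(iv.end),
            ".", gene.strand, str(frame),
            f'gene_id "{gene.gene_id}"; gene_name "{gene.gene_name}";',
        ])

    with open(path, "w") as fh:
        for gene in genes:
            for iv in gene.exons:
                fh.write(row(gene, "exon", iv) + "\n")
            for iv, fr in gene.cds:
                fh.write(row(gene, "CDS", iv, fr) + "\n")
            for iv in gene.utr5:
                fh.write(row(gene, "five_prime_utr", iv) + "\n")
            for iv in gene.utr3:
                fh.write(row(gene, "three_prime_utr", iv) + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def parse_snps(path) -> set:
    """Read a sites-only VCF into a set of :class:`SnpSite`.

    Multi-allelic rows are expanded to one SnpSite per ALT allele; rows
    with a missing ALT are skipped with a warning.
    """
    snps: set = set()
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if not rec.alts:
                warnings.warn(f"{path}: record at {rec.chrom}:{rec.pos} "
                              "has no ALT; skipped")
                continue
            for alt in rec.alts:
                if alt in (None, ".", "*"):
                    continue
                snps.add(SnpSite(rec.chrom, rec.pos, rec.ref.upper(),
                                 str(alt).upper()))
    return snps


def write_vcf(path, snps: Iterable[SnpSite], reference_lengths: dict) -> None:
    rows = sorted(snps, key=lambda s: (s.chrom, s.pos, s.alt))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in reference_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in rows:
            fh.write(f"{s.chrom}\t{s.pos}\t.\t{s.ref}\t{s.alt}\t.\t.\t.\n")


# ---------------------------------------------------------------------------
# repeats (BED6 + family/subfamily columns)
# ---------------------------------------------------------------------------

def parse_repeats(path) -> list:
    repeats = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8:
                raise FormatError(
                    f"{path}:{lineno}: expected BED6+2 (family, subfamily)")
            chrom, start, end, name, _score, strand, family, sub = fields[:8]
            repeats.append(RepeatInterval(
                GenomicInterval(chrom, int(start), int(end),
                                strand=strand, label=name),
                family=family, subfamily=sub))
    return repeats


def write_repeats(path, repeats: Sequence[RepeatInterval]) -> None:
    with open(path, "w") as fh:
        for rp in repeats:
            iv = rp.interval
            fh.write("\t".join([
                iv.chrom, str(iv.start), str(iv.end),
                iv.label or f"{rp.family}/{rp.subfamily}", "0",
                iv.strand if iv.strand in "+-" else "+",
                rp.family, rp.subfamily,
            ]) + "\n")


# ---------------------------------------------------------------------------
# site tables
# ---------------------------------------------------------------------------

SITE_TABLE_FIXED = ["chrom", "pos", "strand", "region", "gene_id",
                    "recoding", "repeat_family", "repeat_subfamily",
                    "pattern"]


def write_site_table(df: pd.DataFrame, path) -> None:
    """Write an annotated site table as TSV (1-based positions).

    ``df`` must contain the :data:`SITE_TABLE_FIXED` columns; any extra
    columns (per-sample levels etc.) are carried through unchanged.
    """
    missing = [c for c in SITE_TABLE_FIXED if c not in df.columns]
    if missing:
        raise FormatError(f"site table missing columns: {missing}")
    ordered = SITE_TABLE_FIXED + [c for c in df.columns
                                  if c not in SITE_TABLE_FIXED]
    df[ordered].to_csv(path, sep="\t", index=False, float_format="%.6g",
                       na_rep="NA")


def read_site_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"],
                       keep_default_na=True,
                       dtype={"chrom": str, "pos": int, "strand": str})
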