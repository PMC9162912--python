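"""Site annotation: genomic region, recoding consequence, repeat context,
flanking sequence composition, and editing-level comparison by repeat class.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from scipy import stats

from .formats_io import GeneModel, RepeatInterval, revcomp

REGION_PRECEDENCE = ("exonic_cds", "utr3", "utr5", "ncRNA", "intronic",
                     "intergenic")

CODON_TABLE = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_TABLE[_stop] = "*"


@dataclass(frozen=True)
class RegionCall:
    category: str
    gene_id: Optional[str] = None

    def __post_init__(self):
        if self.category not in REGION_PRECEDENCE:
            raise ValueError(f"unknown region category {self.category!r}")


@dataclass(frozen=True)
class RecodingCall:
    kind: str                    # synonymous | nonsynonymous | not_coding
    codon_ref: Optional[str] = None
    codon_alt: Optional[str] = None
    aa_ref: Optional[str] = None
    aa_alt: Optional[str] = None
    label: Optional[str] = None  # e.g. "Q/R"


NOT_CODING = RecodingCall(kind="not_coding")


@dataclass
class ContextMatrix:
    """Base composition of the 11-mer (+-5 bp) around sites, edited strand."""

    counts: np.ndarray           # 11 x 4 (A,C,G,T)
    n_sites: int
    n_skipped: int               # sites too close to a contig end

    POSITIONS = tuple(range(-5, 6))
    BASES = ("A", "C", "G", "T")

    @property
    def frequencies(self) -> np.ndarray:
        totals = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(totals > 0, self.counts / totals, 0.0)


# ---------------------------------------------------------------------------
# region assignment
# ---------------------------------------------------------------------------

def _gene_category(pos0: int, gene: GeneModel) -> Optional[str]:
    if any(iv.contains(pos0) for iv, _ in gene.cds):
        return "exonic_cds"
    if any(iv.contains(pos0) for iv in gene.utr3):
        return "utr3"
    if any(iv.contains(pos0) for iv in gene.utr5):
        return "utr5"
    if not gene.cds and any(iv.contains(pos0) for iv in gene.exons):
        return "ncRNA"
    lo, hi = gene.span
    if lo <= pos0 < hi:
        return "intronic"
    return None


def assign_region(chrom: str, pos: int,
                  genes: Sequence[GeneModel]) -> RegionCall:
    """Highest-precedence region overlap for a 1-based site position.

    Precedence: exonic_cds > utr3 > utr5 > ncRNA > intronic > intergenic;
    ties within a category break by lexicographic gene_id, so input order
    never matters.
    """
    pos0 = pos - 1
    hits: List[Tuple[int, str, str]] = []
    for gene in genes:
        if gene.chrom != chrom:
            continue
        cat = _gene_category(pos0, gene)
        if cat is not None:
            hits.append((REGION_PRECEDENCE.index(cat), gene.gene_id, cat))
    if not hits:
        return RegionCall(category="intergenic")
    rank, gene_id, cat = min(hits)
    return RegionCall(category=cat, gene_id=gene_id)


# ---------------------------------------------------------------------------
# recoding
# ---------------------------------------------------------------------------

def _coding_sequence(gene: GeneModel, reference: dict) -> Tuple[str, list]:
    """CDS on the coding strand plus the genomic position of each base."""
    seq_parts = []
    pos_parts = []
    for iv, _fr in gene.cds:
        seq_parts.append(reference[gene.chrom][iv.start:iv.end])
        pos_parts.append(range(iv.start, iv.end))
    seq = "".join(seq_parts)
    positions = [p for part in pos_parts for p in part]
    if gene.strand == "-":
        seq = revcomp(seq)
        positions = positions[::-1]
    return seq.upper(), positions


def classify_recoding(chrom: str, pos: int, strand: str, gene: GeneModel,
                      reference: dict) -> RecodingCall:
    """Consequence of the A->G edit within a coding gene.

    The codon is reconstructed on the coding strand across CDS junctions
    (frame from the first CDS interval); minus-strand genes see the
    genomic T>C site as an mRNA A>G.  Standard codon table.
    """
    if not gene.codable or gene.chrom != chrom:
        return NOT_CODING
    if strand != gene.strand:
        # the edit is on the opposite strand of the transcript
        return NOT_CODING
    cds_seq, positions = _coding_sequence(gene, reference)
    pos0 = pos - 1
    try:
        offset = positions.index(pos0)
    except ValueError:
        return NOT_CODING
    # frame of the first transcribed CDS interval shifts the codon grid
    first = gene.cds[0] if gene.strand == "+" else gene.cds[-1]
    frame = first[1]
    offset_in_frame = offset - frame
    if offset_in_frame < 0:
        return NOT_CODING
    if cds_seq[offset] != "A":
        warnings.warn(
            f"site {chrom}:{pos} is not A on the coding strand of "
            f"{gene.gene_id}; frame inconsistency?")
        return NOT_CODING
    codon_start = offset - (offset_in_frame % 3)
    codon_ref = cds_seq[codon_start:codon_start + 3]
    if len(codon_ref) < 3:
        warnings.warn(f"truncated codon for {gene.gene_id} at {chrom}:{pos}")
        return NOT_CODING
    within = offset - codon_start
    codon_alt = codon_ref[:within] + "G" + codon_ref[within + 1:]
    aa_ref = CODON_TABLE[codon_ref]
    aa_alt = CODON_TABLE[codon_alt]
    kind = "synonymous" if aa_ref == aa_alt else "nonsynonymous"
    return RecodingCall(kind=kind, codon_ref=codon_ref, codon_alt=codon_alt,
                        aa_ref=aa_ref, aa_alt=aa_alt,
                        label=f"{aa_ref}/{aa_alt}")


# ---------------------------------------------------------------------------
# repeats
# ---------------------------------------------------------------------------

def overlap_repeats(chrom: str, pos: int,
                    repeats: Sequence[RepeatInterval]
                    ) -> Optional[RepeatInterval]:
    """Innermost (shortest) repeat overlapping a 1-based position."""
    pos0 = pos - 1
    best = None
    for rp in repeats:
        iv = rp.interval
        if iv.chrom == chrom and iv.contains(pos0):
            if best is None or len(iv) < len(best.interval):
                best = rp
    return best


# ---------------------------------------------------------------------------
# sequence context
# ---------------------------------------------------------------------------

def context_matrix(sites: Sequence[Tuple[str, int, str]],
                   reference: dict, flank: int = 5) -> ContextMatrix:
    """Base counts at -flank..+flank around sites on the edited strand.

    Minus-strand sites are reverse-complemented so position 0 is always
    the edited A.  Sites within ``flank`` of a contig end are skipped
    (and counted), never padded.
    """
    width = 2 * flank + 1
    counts = np.zeros((width, 4), dtype=int)
    base_idx = {b: i for i, b in enumerate(ContextMatrix.BASES)}
    used = skipped = 0
    for chrom, pos, strand in sites:
        seq = reference[chrom]
        pos0 = pos - 1
        if pos0 - flank < 0 or pos0 + flank + 1 > len(seq):
            skipped += 1
            continue
        kmer = seq[pos0 - flank:pos0 + flank + 1].upper()
        if strand == "-":
            kmer = revcomp(kmer)
        used += 1
        for i, base in enumerate(kmer):
            if base in base_idx:
                counts[i, base_idx[base]] += 1
    return ContextMatrix(counts=counts, n_sites=used, n_skipped=skipped)


# ---------------------------------------------------------------------------
# rank-sum comparison of editing levels by repeat class
# ---------------------------------------------------------------------------

def _exact_ranksum_p(x_ranks, all_ranks) -> float:
    """Two-sided exact p for the rank-sum of ``x`` under permutation.

    Dynamic programme over the permutation distribution of the sum of n1
    midranks drawn from the pooled midranks (handles ties exactly).
    Ranks are scaled by 2 so midranks become integers.
    """
    n1 = len(x_ranks)
    scaled = [int(round(2 * r)) for r in all_ranks]
    w_obs = int(round(2 * sum(x_ranks)))
    # dp[j] = {sum: count} over subsets of size j
    dp = [dict() for _ in range(n1 + 1)]
    dp[0][0] = 1
    for r in scaled:
        for j in range(min(n1, len(scaled)) - 1, -1, -1):
            if not dp[j]:
                continue
            tgt = dp[j + 1]
            for s, c in dp[j].items():
                tgt[s + r] = tgt.get(s + r, 0) + c
    dist = dp[n1]
    total = sum(dist.values())
    p_ge = sum(c for s, c in dist.items() if s >= w_obs) / total
    p_le = sum(c for s, c in dist.items() if s <= w_obs) / total
    return min(1.0, 2.0 * min(p_ge, p_le))


def rank_sum_test(x: Sequence[float], y: Sequence[float],
                  exact_max: int = 12) -> Tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U for ``x``).

    Exact permutation null (tie-aware) when both groups have at most
    ``exact_max`` observations; otherwise the normal approximation with
    tie correction and continuity correction.
    """
    x = list(map(float, x))
    y = list(map(float, y))
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("rank_sum_test requires non-empty groups")
    pooled = np.asarray(x + y)
    ranks = stats.rankdata(pooled)
    w1 = float(ranks[:n1].sum())
    u = w1 - n1 * (n1 + 1) / 2.0
    if n1 <= exact_max and n2 <= exact_max:
        p = _exact_ranksum_p(ranks[:n1], ranks)
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic")
        p = float(res.pvalue)
    return u, p


def compare_levels_by_repeat(levels_by_class: Dict[str, Sequence[float]]
                             ) -> Dict[str, dict]:
    """Compare B1 editing levels with other-repeat and non-repeat classes.

    ``levels_by_class`` maps 'B1', 'other_repeat', 'non_repeat' to mean
    per-site editing levels.  Empty classes skip their comparison with a
    flag rather than erroring.
    """
    out: Dict[str, dict] = {}
    b1 = list(levels_by_class.get("B1", []))
    for other in ("other_repeat", "non_repeat"):
        vals = list(levels_by_class.get(other, []))
        name = f"B1_vs_{other}"
        if not b1 or not vals:
            out[name] = {"skipped": True, "reason": "empty class"}
            continue
        u, p = rank_sum_test(b1, vals)
        out[name] = {"skipped": False, "U": u, "p_value": p,
                     "n_B1": len(b1), "n_other": len(vals)}
    return out


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def annotate_site(chrom: str, pos: int, strand: str,
                  genes: Sequence[GeneModel],
                  repeats: Sequence[RepeatInterval],
                  reference: dict) -> dict:
    """Full annotation record for one site."""
    region = assign_region(chrom, pos, genes)
    recoding = NOT_CODING
    if region.category == "exonic_cds" and region.gene_id is not None:
        gene = next(g for g in genes if g.gene_id == region.gene_id)
        recoding = classify_recoding(chrom, pos, strand, gene, reference)
    repeat = overlap_repeats(chrom, pos, repeats)
    return {
        "region": region.category,
        "gene_id": region.gene_id,
        "recoding_kind": recoding.kind,
        "recoding": recoding.label,
        "repeat_family": repeat.family if repeat else None,
        "repeat_subfamily": repeat.subfamily if repeat else None,
    }


def region_fractions(annotations: Sequence[dict]) -> Dict[str, float]:
    """Fraction of sites per region category (sums to 1)."""
    n = len(annotations)
    if n == 0:
        return {}
    out = {}
    for cat in REGION_PRECEDENCE:
        out[cat] = sum(a["region"] == cat for a in annotations) / n
    return out
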