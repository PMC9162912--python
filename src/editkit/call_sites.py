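"""High-confidence A-to-I site calling from aligned reads.

The cascade: per-base/read quality filtering during pileup, candidate
selection (coverage, mismatch rate, third-allele guard), known-SNP
exclusion, and a cross-sample recurrence filter.  Two statistics are
kept distinct throughout: the mismatch rate m = n_edit / N (N = all
quality-passing reads at the site) used for candidate filtering, and
the editing level beta = n_edit / (n_edit + n_ref) used for
quantification.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np

from .formats_io import AlignedRead, SnpSite

log = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")

# site key: (chrom, pos 1-based, strand)
SiteKey = Tuple[str, int, str]


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the calling cascade; all ``>=`` bounds inclusive."""

    min_base_quality: int = 25
    min_mapq: int = 20
    min_coverage: int = 15
    min_mismatch_rate: float = 0.02
    recurrence_fraction: float = 0.5       # strict: must exceed
    max_third_allele_fraction: float = 0.01
    both_strands: bool = True              # False: plus-strand A>G only

    def __post_init__(self):
        if not (0.0 < self.recurrence_fraction < 1.0):
            raise ValueError("recurrence_fraction must be in (0,1)")
        for name in ("min_base_quality", "min_mapq", "min_coverage",
                     "min_mismatch_rate", "max_third_allele_fraction"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class SiteEvidence:
    """Per-sample read support at one site (strand-adjusted counts)."""

    sample_id: str
    coverage: int        # N: quality-passing reads at the position
    n_ref: int           # reads supporting the unedited base
    n_edit: int          # reads supporting the edited base
    n_other: int

    def __post_init__(self):
        if self.n_ref + self.n_edit + self.n_other != self.coverage:
            raise ValueError("evidence counts do not sum to coverage")

    @property
    def editing_level(self) -> Optional[float]:
        return editing_level(self)

    @property
    def mismatch_rate(self) -> float:
        return self.n_edit / self.coverage if self.coverage else 0.0


CANDIDATE = "candidate"
SNP_EXCLUDED = "snp_excluded"
HIGH_CONFIDENCE = "high_confidence"


@dataclass
class EditingSite:
    chrom: str
    pos: int             # 1-based
    strand: str          # '+': genomic A>G, '-': genomic T>C
    status: str = CANDIDATE
    evidence: Dict[str, SiteEvidence] = field(default_factory=dict)

    @property
    def key(self) -> SiteKey:
        return (self.chrom, self.pos, self.strand)


@dataclass
class EditingMatrix:
    """Sites x ordered samples matrix of editing levels with missingness."""

    site_keys: List[SiteKey]
    samples: List[str]
    values: np.ndarray      # float, NaN where missing
    mask: np.ndarray        # bool, True where missing

    def __post_init__(self):
        assert self.values.shape == (len(self.site_keys), len(self.samples))
        assert self.mask.shape == self.values.shape


@dataclass
class CallResult:
    sites: List[EditingSite]            # high_confidence + snp_excluded
    samples: List[str]
    attrition: Dict[str, int]

    @property
    def high_confidence(self) -> List[EditingSite]:
        return [s for s in self.sites if s.status == HIGH_CONFIDENCE]


# ---------------------------------------------------------------------------
# pileup
# ---------------------------------------------------------------------------

def pileup_counts(reads: Iterable[AlignedRead], reference: dict,
                  config: FilterConfig) -> Dict[Tuple[str, int], Dict[str, int]]:
    """Quality-filtered base counts per (chrom, pos0).

    Reads below ``min_mapq`` are wholly excluded; individual bases below
    ``min_base_quality`` are excluded; N bases are ignored.
    """
    counts: Dict[Tuple[str, int], Dict[str, int]] = defaultdict(
        lambda: dict.fromkeys(BASES, 0))
    minq = config.min_base_quality
    for read in reads:
        if read.mapq < config.min_mapq:
            continue
        if read.chrom not in reference:
            raise KeyError(
                f"chromosome {read.chrom!r} absent from reference")
        for pos0, base, qual in read.bases:
            if qual < minq or base == "N":
                continue
            counts[(read.chrom, pos0)][base] += 1
    return dict(counts)


def _site_counts(counts: Dict[str, int], ref_base: str):
    """Strand-adjusted (strand, n_ref, n_edit, n_other) or None."""
    if ref_base == "A":
        return ("+", counts["A"], counts["G"], counts["C"] + counts["T"])
    if ref_base == "T":
        return ("-", counts["T"], counts["C"], counts["A"] + counts["G"])
    return None


def candidate_sites(counts, reference: dict, config: FilterConfig,
                    sample_id: str) -> Dict[SiteKey, SiteEvidence]:
    """Apply coverage / mismatch-rate / third-allele filters to a pileup.

    A position is a candidate iff the reference base is A with G
    mismatches (strand '+'), or T with C mismatches (strand '-',
    counts complemented), coverage N >= min_coverage, mismatch rate
    m >= min_mismatch_rate, and n_other / N <= max_third_allele_fraction.
    """
    out: Dict[SiteKey, SiteEvidence] = {}
    for (chrom, pos0), base_counts in counts.items():
        ref_base = reference[chrom][pos0].upper()
        adj = _site_counts(base_counts, ref_base)
        if adj is None:
            continue
        strand, n_ref, n_edit, n_other = adj
        if n_edit == 0:
            continue
        if strand == "-" and not config.both_strands:
            continue
        n = n_ref + n_edit + n_other
        if n < config.min_coverage:
            continue
        if n_edit / n < config.min_mismatch_rate:
            continue
        if n_other / n > config.max_third_allele_fraction:
            continue
        out[(chrom, pos0 + 1, strand)] = SiteEvidence(
            sample_id=sample_id, coverage=n, n_ref=n_ref,
            n_edit=n_edit, n_other=n_other)
    return out


# ---------------------------------------------------------------------------
# SNP exclusion
# ---------------------------------------------------------------------------

def site_matches_snp(key: SiteKey, snps: set) -> bool:
    """True if a known SNP explains the site's mismatch on its strand."""
    chrom, pos, strand = key
    if strand == "+":
        return SnpSite(chrom, pos, "A", "G") in snps
    return SnpSite(chrom, pos, "T", "C") in snps


def exclude_snps(sites: List[EditingSite], snps: set) -> List[EditingSite]:
    """Mark sites whose mismatch coincides with a known SNP.

    Excluded sites are retained with status ``snp_excluded`` so that the
    attrition can be reported.
    """
    for site in sites:
        if site_matches_snp(site.key, snps):
            site.status = SNP_EXCLUDED
    return sites


# ---------------------------------------------------------------------------
# recurrence across samples
# ---------------------------------------------------------------------------

def _evidence_from_pileup(counts, key: SiteKey, sample_id: str):
    chrom, pos, strand = key
    base_counts = counts.get((chrom, pos - 1))
    if base_counts is None:
        return None
    ref_base = "A" if strand == "+" else "T"
    adj = _site_counts(base_counts, ref_base)
    strand_, n_ref, n_edit, n_other = adj
    n = n_ref + n_edit + n_other
    if n == 0:
        return None
    return SiteEvidence(sample_id=sample_id, coverage=n, n_ref=n_ref,
                        n_edit=n_edit, n_other=n_other)


def recurrence_filter(
    per_sample_candidates: Dict[str, Dict[SiteKey, SiteEvidence]],
    per_sample_pileups: Dict[str, dict],
    snps: set,
    config: FilterConfig,
    sample_order: Optional[List[str]] = None,
) -> CallResult:
    """Keep sites that are surviving candidates in > recurrence_fraction
    of all samples; merge evidence across every sample with coverage.

    SNP-matched sites are reported with status ``snp_excluded``; they
    never count toward recurrence.
    """
    if not per_sample_candidates:
        raise ValueError("recurrence_filter requires at least one sample")
    samples = sample_order or sorted(per_sample_candidates)
    n_samples = len(samples)

    support: Dict[SiteKey, int] = defaultdict(int)
    for sample in samples:
        for key in per_sample_candidates[sample]:
            support[key] += 1

    snp_keys = {k for k in support if site_matches_snp(k, snps)}
    passing = {
        k for k, cnt in support.items()
        if k not in snp_keys and cnt / n_samples > config.recurrence_fraction
    }

    sites: List[EditingSite] = []
    for key in sorted(snp_keys | passing):
        status = SNP_EXCLUDED if key in snp_keys else HIGH_CONFIDENCE
        evidence = {}
        for sample in samples:
            ev = _evidence_from_pileup(per_sample_pileups[sample], key, sample)
            if ev is not None:
                evidence[sample] = ev
        sites.append(EditingSite(chrom=key[0], pos=key[1], strand=key[2],
                                 status=status, evidence=evidence))

    attrition = {
        "candidate_keys": len(support),
        "snp_excluded": len(snp_keys),
        "recurrence_failed": len(support) - len(snp_keys) - len(passing),
        "high_confidence": len(passing),
    }
    return CallResult(sites=sites, samples=samples, attrition=attrition)


# ---------------------------------------------------------------------------
# quantification
# ---------------------------------------------------------------------------

def editing_level(evidence: SiteEvidence) -> Optional[float]:
    """Editing level G/(G+A); ``None`` (missing) when G+A = 0."""
    denom = evidence.n_edit + evidence.n_ref
    if denom == 0:
        return None
    return evidence.n_edit / denom


def overall_editing_level(sites: List[EditingSite],
                          sample: str) -> Optional[float]:
    """Sample-wide editing: sum(n_edit) / sum(N) over covered sites."""
    n_edit = 0
    n_total = 0
    for site in sites:
        ev = site.evidence.get(sample)
        if ev is None:
            continue
        n_edit += ev.n_edit
        n_total += ev.coverage
    if n_total == 0:
        return None
    return n_edit / n_total


def build_matrix(sites: List[EditingSite],
                 sample_order: List[str]) -> EditingMatrix:
    """Editing-level matrix, rows = sites, columns = ordered samples."""
    keys = [s.key for s in sites]
    values = np.full((len(sites), len(sample_order)), np.nan)
    for i, site in enumerate(sites):
        for j, sample in enumerate(sample_order):
            ev = site.evidence.get(sample)
            if ev is None:
                continue
            lvl = editing_level(ev)
            if lvl is not None:
                values[i, j] = lvl
    mask = np.isnan(values)
    return EditingMatrix(site_keys=keys, samples=list(sample_order),
                        values=values, mask=mask)


# ---------------------------------------------------------------------------
# one-call driver
# ---------------------------------------------------------------------------

def call_from_pileups(per_sample_pileups: Dict[str, dict], reference: dict,
                      snps: set, config: FilterConfig,
                      sample_order: Optional[List[str]] = None) -> CallResult:
    """Run candidate selection + SNP exclusion + recurrence on pileups."""
    samples = sample_order or sorted(per_sample_pileups)
    per_sample_candidates = {
        s: candidate_sites(per_sample_pileups[s], reference, config, s)
        for s in samples
    }
    result = recurrence_filter(per_sample_candidates, per_sample_pileups,
                               snps, config, sample_order=samples)
    log.info("cascade attrition: %s", result.attrition)
    return result
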