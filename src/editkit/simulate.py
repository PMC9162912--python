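"""Synthetic study generator.

Produces a complete, seeded corpus: random reference with gene and repeat
annotation, planted editing sites following three temporal trajectories
(high / medium / low), heterozygous germline SNP confounders, bulk reads
for each ordered stage, barcoded single-cell reads with per-cell-type
site ownership, expression tables, and a serialized ground truth.

Everything is deterministic given the config seed; identical configs
yield byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import annotate as _annotate
from .call_sites import EditingMatrix
from .formats_io import (GeneModel, GenomicInterval, RepeatInterval, SnpSite,
                         write_fasta, write_gtf, write_repeats, write_sam,
                         write_vcf)

DEFAULT_STAGES = ("E14.5", "E17.5", "P0", "P3", "P7", "P10", "P14", "P21")
PATTERNS = ("high", "medium", "low")


class SizingError(ValueError):
    """Requested features exceed genome capacity."""


# ---------------------------------------------------------------------------
# config / truth types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    seed: int
    genome_length: int = 60_000
    chrom: str = "chrS"
    n_genes: int = 12
    n_ncrna: int = 2
    n_sites: Dict[str, int] = field(
        default_factory=lambda: {"high": 20, "medium": 20, "low": 20})
    frac_cds_nonsyn: float = 0.25      # of high-pattern sites
    frac_utr3: float = 0.25
    frac_b1: float = 0.25
    n_snps: int = 20
    n_null_sites: int = 40
    mean_coverage: float = 50.0
    read_length: int = 80
    error_rate: float = 0.001
    qual_high: int = 37
    qual_low: int = 10
    low_qual_fraction: float = 0.03
    mapq_high: int = 60
    mapq_low: int = 10
    low_mapq_fraction: float = 0.03
    nb_dispersion: Optional[float] = None   # None -> Poisson coverage
    stages: Tuple[str, ...] = DEFAULT_STAGES
    cell_types: Tuple[str, ...] = ("TypeA", "TypeB", "TypeC")
    cells_per_type: int = 30
    cell_coverage: float = 40.0
    n_background_genes: int = 40
    adar_slope: Tuple[float, float] = (30.0, 60.0)
    adar_intercept: Tuple[float, float] = (5.0, 10.0)
    adar_sigma: float = 0.5

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not (0.0 <= self.error_rate <= 0.05):
            raise ValueError("error_rate must be in [0, 0.05]")
        for name in ("genome_length", "n_genes", "n_snps", "n_null_sites",
                     "cells_per_type", "n_background_genes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(v < 0 for v in self.n_sites.values()):
            raise ValueError("site counts must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown simulation keys: {sorted(unknown)}")
        for key in ("stages", "cell_types", "adar_slope", "adar_intercept"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass(frozen=True)
class TrajectorySpec:
    pattern: str
    levels: Tuple[float, ...]

    def __post_init__(self):
        lv = np.asarray(self.levels)
        if self.pattern == "high":
            ok = np.all(np.diff(lv) >= 0) and lv[-1] >= 0.5
        elif self.pattern == "medium":
            ok = np.all(np.diff(lv) >= 0) and 0.2 <= lv[-1] < 0.5
        elif self.pattern == "low":
            ok = np.all(lv < 0.15) and (lv.max() - lv.min()) < 0.05
        else:
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if not ok:
            raise ValueError(
                f"levels {self.levels} violate {self.pattern} invariants")


@dataclass(frozen=True)
class PlantedSite:
    chrom: str
    pos: int                     # 1-based
    strand: str
    trajectory: TrajectorySpec
    compartment: str             # cds | utr3 | b1 | intergenic
    gene_id: Optional[str] = None
    repeat_subfamily: Optional[str] = None
    recoding_label: Optional[str] = None

    @property
    def key(self):
        return (self.chrom, self.pos, self.strand)


@dataclass
class SimulationTruth:
    sites: List[PlantedSite]
    snps: List[SnpSite]
    null_positions: List[Tuple[str, int, str]]
    stages: Tuple[str, ...]
    ownership: Dict[str, List[Tuple[str, int, str]]]   # cell type -> keys
    barcodes: Dict[str, List[str]]

    def level(self, site_index: int, stage: str) -> float:
        return self.sites[site_index].trajectory.levels[
            self.stages.index(stage)]

    def to_json(self, path) -> None:
        def key_str(k):
            return f"{k[0]}:{k[1]}:{k[2]}"

        doc = {
            "stages": list(self.stages),
            "sites": [
                {
                    "chrom": s.chrom, "pos": s.pos, "strand": s.strand,
                    "pattern": s.trajectory.pattern,
                    "levels": list(s.trajectory.levels),
                    "compartment": s.compartment,
                    "gene_id": s.gene_id,
                    "repeat_subfamily": s.repeat_subfamily,
                    "recoding_label": s.recoding_label,
                }
                for s in self.sites
            ],
            "snps": [
                {"chrom": s.chrom, "pos": s.pos, "ref": s.ref, "alt": s.alt}
                for s in self.snps
            ],
            "null_positions": [key_str(k) for k in self.null_positions],
            "ownership": {ct: [key_str(k) for k in keys]
                          for ct, keys in self.ownership.items()},
            "barcodes": self.barcodes,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SimulationTruth":
        def parse_key(s):
            chrom, pos, strand = s.rsplit(":", 2)
            return (chrom, int(pos), strand)

        with open(path) as fh:
            doc = json.load(fh)
        sites = [
            PlantedSite(
                chrom=d["chrom"], pos=d["pos"], strand=d["strand"],
                trajectory=TrajectorySpec(d["pattern"], tuple(d["levels"])),
                compartment=d["compartment"], gene_id=d["gene_id"],
                repeat_subfamily=d["repeat_subfamily"],
                recoding_label=d["recoding_label"])
            for d in doc["sites"]
        ]
        snps = [SnpSite(d["chrom"], d["pos"], d["ref"], d["alt"])
                for d in doc["snps"]]
        return cls(
            sites=sites, snps=snps,
            null_positions=[parse_key(s) for s in doc["null_positions"]],
            stages=tuple(doc["stages"]),
            ownership={ct: [parse_key(s) for s in keys]
                       for ct, keys in doc["ownership"].items()},
            barcodes=doc["barcodes"],
        )


def _rng(config: SimConfig, *tags: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, *tags])


# ---------------------------------------------------------------------------
# reference
# ---------------------------------------------------------------------------

_REPEAT_CYCLE = [("SINE", "B1"), ("SINE", "B1"), ("SINE", "B2"),
                 ("LINE", "L1"), ("SINE", "B1"), ("SINE", "B4"),
                 ("LTR", "ERVK")]


def simulate_reference(config: SimConfig):
    """Random genome with non-overlapping genes and labelled repeats.

    Genes alternate strand; the last ``n_ncrna`` of them carry exons but
    no CDS.  Repeats are placed in the intergenic gaps (SINE/B1 enriched)
    and inside some 3'UTRs.
    """
    if config.genome_length < 10_000:
        raise SizingError("genome_length must be >= 10 kb")
    rng = _rng(config, 1)
    genome = {config.chrom: "".join(
        rng.choice(list("ACGT"), size=config.genome_length))}

    genes: List[GeneModel] = []
    repeats: List[RepeatInterval] = []
    gap = 500
    cursor = 400
    utr5_len, utr3_len = 40, 220
    rep_i = 0
    for gi in range(config.n_genes):
        n_codons = int(rng.integers(50, 100))
        cds_len = 3 * n_codons
        is_nc = gi >= config.n_genes - config.n_ncrna
        glen = utr5_len + cds_len + utr3_len
        if cursor + glen + gap > config.genome_length - 400:
            raise SizingError(
                f"{config.n_genes} genes do not fit in "
                f"{config.genome_length} bp")
        strand = "+" if gi % 2 == 0 else "-"
        gid = f"G{gi + 1:03d}"
        gene = GeneModel(gene_id=gid, gene_name=gid, chrom=config.chrom,
                         strand=strand)
        exon = GenomicInterval(config.chrom, cursor, cursor + glen,
                               strand=strand, label="exon")
        gene.exons.append(exon)
        if not is_nc:
            if strand == "+":
                u5 = (cursor, cursor + utr5_len)
                cds = (u5[1], u5[1] + cds_len)
                u3 = (cds[1], cds[1] + utr3_len)
            else:
                u3 = (cursor, cursor + utr3_len)
                cds = (u3[1], u3[1] + cds_len)
                u5 = (cds[1], cds[1] + utr5_len)
            gene.utr5.append(GenomicInterval(config.chrom, *u5,
                                             strand=strand, label="utr5"))
            gene.cds.append((GenomicInterval(config.chrom, *cds,
                                             strand=strand, label="CDS"), 0))
            gene.utr3.append(GenomicInterval(config.chrom, *u3,
                                             strand=strand, label="utr3"))
            # a B1 embedded in every other 3'UTR
            if gi % 2 == 0:
                r0 = u3[0] + 40
                repeats.append(RepeatInterval(
                    GenomicInterval(config.chrom, r0, r0 + 120,
                                    strand="+", label="B1"),
                    family="SINE", subfamily="B1"))
        else:
            gene.codable = False
        genes.append(gene)
        # two intergenic repeats in the following gap: a B1 plus one
        # cycled through the other families
        r0 = cursor + glen + 60
        repeats.append(RepeatInterval(
            GenomicInterval(config.chrom, r0, r0 + 200, strand="+",
                            label="B1"),
            family="SINE", subfamily="B1"))
        fam, sub = _REPEAT_CYCLE[rep_i % len(_REPEAT_CYCLE)]
        rep_i += 1
        r1 = r0 + 240
        repeats.append(RepeatInterval(
            GenomicInterval(config.chrom, r1, r1 + 150, strand="+",
                            label=sub),
            family=fam, subfamily=sub))
        cursor += glen + gap
    return genome, genes, repeats


# ---------------------------------------------------------------------------
# planting
# ---------------------------------------------------------------------------

def _trajectory(pattern: str, n_stages: int,
                rng: np.random.Generator) -> TrajectorySpec:
    s = np.arange(n_stages)
    mid = (n_stages - 1) / 2.0
    if pattern == "high":
        lo, hi = 0.10, 0.55 + 0.25 * rng.random()
        lv = lo + (hi - lo) / (1.0 + np.exp(-1.1 * (s - mid)))
        lv[-1] = hi
    elif pattern == "medium":
        lo, hi = 0.04, 0.22 + 0.15 * rng.random()
        lv = lo + (hi - lo) / (1.0 + np.exp(-1.1 * (s - mid)))
        lv[-1] = hi
    else:
        base = 0.05 + 0.05 * rng.random()
        lv = base + rng.uniform(-0.01, 0.01, size=n_stages)
    lv = np.clip(np.round(lv, 4), 0.0, 1.0)
    if pattern in ("high", "medium"):
        lv = np.maximum.accumulate(lv)
    return TrajectorySpec(pattern=pattern, levels=tuple(float(v) for v in lv))


def _strand_base(genome: dict, chrom: str, pos0: int, strand: str) -> str:
    base = genome[chrom][pos0]
    if strand == "-":
        base = {"A": "T", "C": "G", "G": "C", "T": "A"}.get(base, "N")
    return base


def plant_sites(config: SimConfig, genome: dict,
                genes: Sequence[GeneModel],
                repeats: Sequence[RepeatInterval],
                recoding_label: Optional[str] = None) -> SimulationTruth:
    """Choose planted sites, SNPs and never-edited null positions.

    High-pattern sites take the CDS-nonsynonymous quota (verified against
    the codon table); fractions of each pattern go to 3'UTRs and B1
    repeats, the rest intergenic.  All planted positions (including SNPs
    and nulls) are strand-adjusted A's and are spaced more than one read
    length apart so reads never straddle two of them.
    """
    rng = _rng(config, 2)
    chrom = config.chrom
    spacing = config.read_length + 5
    margin = 300
    taken: List[int] = []

    def free(pos0: int) -> bool:
        if not (margin <= pos0 < config.genome_length - margin):
            return False
        return all(abs(pos0 - t) >= spacing for t in taken)

    gene_spans = [g.span for g in genes]

    def in_gene(pos0: int) -> bool:
        return any(lo <= pos0 < hi for lo, hi in gene_spans)

    def in_repeat(pos0: int) -> bool:
        return any(r.interval.contains(pos0) for r in repeats)

    # --- candidate pools -------------------------------------------------
    cds_pool = []      # (pos0, strand, gene_id, label)
    for gene in genes:
        if not gene.codable:
            continue
        cds_seq, positions = _annotate._coding_sequence(gene, genome)
        for ci in range(0, len(cds_seq) - 2, 3):
            codon = cds_seq[ci:ci + 3]
            for within in range(3):
                if codon[within] != "A":
                    continue
                alt = codon[:within] + "G" + codon[within + 1:]
                aa_ref = _annotate.CODON_TABLE[codon]
                aa_alt = _annotate.CODON_TABLE[alt]
                if aa_ref == aa_alt or "*" in (aa_ref, aa_alt):
                    continue
                label = f"{aa_ref}/{aa_alt}"
                if recoding_label and label != recoding_label:
                    continue
                cds_pool.append((positions[ci + within], gene.strand,
                                 gene.gene_id, label))

    utr3_pool = []     # (pos0, strand, gene_id)
    for gene in genes:
        for iv in gene.utr3:
            for pos0 in range(iv.start, iv.end):
                if in_repeat(pos0):
                    continue
                if _strand_base(genome, chrom, pos0, gene.strand) == "A":
                    utr3_pool.append((pos0, gene.strand, gene.gene_id))

    b1_pool = []       # (pos0,) intergenic B1 A positions, plus strand
    for rp in repeats:
        if rp.subfamily != "B1":
            continue
        for pos0 in range(rp.interval.start, rp.interval.end):
            if in_gene(pos0):
                continue
            if genome[chrom][pos0] == "A":
                b1_pool.append(pos0)

    inter_pool = [
        pos0 for pos0 in range(margin, config.genome_length - margin, 3)
        if genome[chrom][pos0] == "A" and not in_gene(pos0)
        and not in_repeat(pos0)
    ]

    for pool in (cds_pool, utr3_pool, b1_pool, inter_pool):
        rng.shuffle(pool)

    def draw(pool, compartment: str):
        while pool:
            item = pool.pop()
            pos0 = item if isinstance(item, (int, np.integer)) else item[0]
            if free(pos0):
                taken.append(int(pos0))
                return item
        raise SizingError(
            f"not enough A positions in compartment {compartment!r}")

    sites: List[PlantedSite] = []
    n_stages = len(config.stages)
    for pattern in PATTERNS:
        n = config.n_sites.get(pattern, 0)
        n_cds = round(config.frac_cds_nonsyn * n) if pattern == "high" else 0
        n_u3 = round(config.frac_utr3 * n)
        n_b1 = round(config.frac_b1 * n)
        n_int = n - n_cds - n_u3 - n_b1
        for _ in range(n_cds):
            pos0, strand, gid, label = draw(cds_pool, "cds")
            sites.append(PlantedSite(
                chrom=chrom, pos=pos0 + 1, strand=strand,
                trajectory=_trajectory(pattern, n_stages, rng),
                compartment="cds", gene_id=gid, recoding_label=label))
        for _ in range(n_u3):
            pos0, strand, gid = draw(utr3_pool, "utr3")
            sites.append(PlantedSite(
                chrom=chrom, pos=pos0 + 1, strand=strand,
                trajectory=_trajectory(pattern, n_stages, rng),
                compartment="utr3", gene_id=gid))
        for _ in range(n_b1):
            pos0 = draw(b1_pool, "b1")
            sites.append(PlantedSite(
                chrom=chrom, pos=pos0 + 1, strand="+",
                trajectory=_trajectory(pattern, n_stages, rng),
                compartment="b1", repeat_subfamily="B1"))
        for _ in range(n_int):
            pos0 = draw(inter_pool, "intergenic")
            sites.append(PlantedSite(
                chrom=chrom, pos=pos0 + 1, strand="+",
                trajectory=_trajectory(pattern, n_stages, rng),
                compartment="intergenic"))

    snps = []
    for _ in range(config.n_snps):
        pos0 = draw(inter_pool, "intergenic (SNPs)")
        snps.append(SnpSite(chrom, pos0 + 1, "A", "G"))

    nulls = []
    for _ in range(config.n_null_sites):
        pos0 = draw(inter_pool, "intergenic (null sites)")
        nulls.append((chrom, pos0 + 1, "+"))

    # sanity: planted sites are A on their strand and disjoint from SNPs
    for s in sites:
        assert _strand_base(genome, chrom, s.pos - 1, s.strand) == "A"
    assert not ({s.key for s in sites}
                & {(p.chrom, p.pos, "+") for p in snps})

    sites.sort(key=lambda s: s.pos)
    ownership = _assign_ownership(sites, config.cell_types)
    barcodes = _make_barcodes(config, rng)
    return SimulationTruth(sites=sites, snps=snps, null_positions=nulls,
                           stages=config.stages, ownership=ownership,
                           barcodes=barcodes)


def _assign_ownership(sites: Sequence[PlantedSite],
                      cell_types: Sequence[str]) -> Dict[str, list]:
    """CDS (recoding) sites all go to the first cell type; the rest are
    dealt round-robin, so the first type owns the largest subset."""
    owner: Dict[str, list] = {ct: [] for ct in cell_types}
    others = []
    for s in sites:
        if s.compartment == "cds":
            owner[cell_types[0]].append(s.key)
        else:
            others.append(s.key)
    for i, key in enumerate(others):
        owner[cell_types[i % len(cell_types)]].append(key)
    return owner


def _make_barcodes(config: SimConfig,
                   rng: np.random.Generator) -> Dict[str, List[str]]:
    out: Dict[str, List[str]] = {}
    seen = set()
    for ct in config.cell_types:
        bcs = []
        while len(bcs) < config.cells_per_type:
            bc = "".join(rng.choice(list("ACGT"), size=16))
            if bc not in seen:
                seen.add(bc)
                bcs.append(bc)
        out[ct] = bcs
    return out


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def _coverage(config: SimConfig, mean: float,
              rng: np.random.Generator) -> int:
    if config.nb_dispersion is None:
        return int(rng.poisson(mean))
    r = config.nb_dispersion
    p = r / (r + mean)
    return int(rng.negative_binomial(r, p))


def _emit_reads(genome: dict, config: SimConfig, rng: np.random.Generator,
                chrom: str, pos0: int, n_reads: int, edit_prob: float,
                edited_base: str, name_prefix: str,
                barcode: Optional[callable] = None) -> List[dict]:
    glen = len(genome[chrom])
    L = config.read_length
    reads = []
    lo = max(0, pos0 - L + 1)
    hi = min(pos0, glen - L)
    for i in range(n_reads):
        start = int(rng.integers(lo, hi + 1))
        seq = list(genome[chrom][start:start + L])
        if rng.random() < edit_prob:
            seq[pos0 - start] = edited_base
        if config.error_rate > 0:
            err = np.nonzero(rng.random(L) < config.error_rate)[0]
            for j in err:
                alts = [b for b in "ACGT" if b != seq[j]]
                seq[j] = alts[int(rng.integers(3))]
        quals = np.where(rng.random(L) < config.low_qual_fraction,
                         config.qual_low, config.qual_high)
        mapq = (config.mapq_low
                if rng.random() < config.low_mapq_fraction
                else config.mapq_high)
        rd = {
            "name": f"{name_prefix}_{pos0}_{i}",
            "chrom": chrom,
            "pos0": start,
            "seq": "".join(seq),
            "quals": [int(q) for q in quals],
            "mapq": int(mapq),
        }
        if barcode is not None:
            rd["barcode"] = barcode()
        reads.append(rd)
    return reads


def simulate_reads(genome: dict, truth: SimulationTruth, config: SimConfig,
                   stage: str) -> List[dict]:
    """Bulk reads for one stage (list of dicts for ``write_sam``)."""
    if stage not in truth.stages:
        raise ValueError(f"unknown stage {stage!r}")
    s_idx = truth.stages.index(stage)
    rng = _rng(config, 3, s_idx)
    reads: List[dict] = []
    for site in truth.sites:
        beta = site.trajectory.levels[s_idx]
        edited = "G" if site.strand == "+" else "C"
        n = _coverage(config, config.mean_coverage, rng)
        reads += _emit_reads(genome, config, rng, site.chrom, site.pos - 1,
                             n, beta, edited, f"s{s_idx}")
    for snp in truth.snps:
        n = _coverage(config, config.mean_coverage, rng)
        reads += _emit_reads(genome, config, rng, snp.chrom, snp.pos - 1,
                             n, 0.5, snp.alt, f"s{s_idx}snp")
    for chrom, pos, _strand in truth.null_positions:
        n = _coverage(config, config.mean_coverage, rng)
        reads += _emit_reads(genome, config, rng, chrom, pos - 1,
                             n, 0.0, "G", f"s{s_idx}null")
    return reads


def simulate_barcoded_reads(genome: dict, truth: SimulationTruth,
                            config: SimConfig, stage: str
                            ) -> Tuple[List[dict], pd.DataFrame]:
    """Barcoded reads for one stage plus the barcode -> cell-type map.

    Each cell type covers every planted site but edits only its owned
    subset (beta = 0 elsewhere).
    """
    if stage not in truth.stages:
        raise ValueError(f"unknown stage {stage!r}")
    s_idx = truth.stages.index(stage)
    reads: List[dict] = []
    for t_idx, ct in enumerate(config.cell_types):
        rng = _rng(config, 4, s_idx, t_idx)
        owned = set(map(tuple, truth.ownership.get(ct, [])))
        bcs = truth.barcodes[ct]

        def pick_bc():
            return bcs[int(rng.integers(len(bcs)))]

        for site in truth.sites:
            beta = (site.trajectory.levels[s_idx]
                    if site.key in owned else 0.0)
            edited = "G" if site.strand == "+" else "C"
            n = _coverage(config, config.cell_coverage, rng)
            reads += _emit_reads(genome, config, rng, site.chrom,
                                 site.pos - 1, n, beta, edited,
                                 f"sc{s_idx}t{t_idx}", barcode=pick_bc)
    rows = [(bc, ct) for ct in config.cell_types
            for bc in truth.barcodes[ct]]
    bc_map = pd.DataFrame(rows, columns=["barcode", "cell_type"])
    return reads, bc_map


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def simulate_expression(truth: SimulationTruth, config: SimConfig
                        ) -> pd.DataFrame:
    """Per-stage FPKM for Adar1/Adar2 (tracking mean planted editing)
    plus uncorrelated background genes.  Genes x stages."""
    rng = _rng(config, 5)
    mean_beta = np.array([
        np.mean([s.trajectory.levels[i] for s in truth.sites])
        for i in range(len(truth.stages))
    ])
    rows = {}
    for gene, a, b in zip(("Adar1", "Adar2"), config.adar_slope,
                          config.adar_intercept):
        noise = rng.normal(0.0, config.adar_sigma, size=mean_beta.size)
        rows[gene] = a * mean_beta + b + noise
    for i in range(config.n_background_genes):
        rows[f"Bg{i + 1:03d}"] = rng.normal(8.0, 1.0, size=mean_beta.size)
    return pd.DataFrame(rows, index=list(truth.stages)).T


def simulate_cell_expression(truth: SimulationTruth, config: SimConfig,
                             genes: Sequence[GeneModel]) -> pd.DataFrame:
    """Log-scale expression matrix, cells x genes.

    Cells of the first cell type over-express the host genes of the
    planted recoding (CDS) sites by +1, so that a module score on that
    gene set separates the owner type.
    """
    rng = _rng(config, 6)
    gene_names = [g.gene_id for g in genes] + [
        f"Bg{i + 1:03d}" for i in range(config.n_background_genes)]
    cells = [bc for ct in config.cell_types for bc in truth.barcodes[ct]]
    cell_type = {bc: ct for ct in config.cell_types
                 for bc in truth.barcodes[ct]}
    expr = rng.normal(1.0, 0.2, size=(len(cells), len(gene_names)))
    df = pd.DataFrame(expr, index=cells, columns=gene_names)
    nonsyn_genes = sorted({s.gene_id for s in truth.sites
                           if s.compartment == "cds" and s.gene_id})
    owner = config.cell_types[0]
    for g in nonsyn_genes:
        boost = [1.0 if cell_type[bc] == owner else 0.0 for bc in cells]
        df[g] = df[g] + boost
    return df


# ---------------------------------------------------------------------------
# trajectory matrices for clustering experiments
# ---------------------------------------------------------------------------

def synthetic_trajectory_matrix(n_per_pattern: int = 100, n_stages: int = 8,
                                coverage: int = 50, seed: int = 0
                                ) -> Tuple[EditingMatrix, List[str]]:
    """Editing matrix of three well-separated trajectories + binomial noise.

    The pattern means are >= 0.2 apart at every stage; observed levels
    are Binomial(coverage, beta)/coverage.  Returns the matrix and the
    true per-site pattern labels.
    """
    rng = np.random.default_rng(seed)
    s = np.arange(n_stages) / max(n_stages - 1, 1)
    means = {
        "high": 0.60 + 0.30 * s,
        "medium": 0.30 + 0.10 * s,
        "low": np.full(n_stages, 0.05),
    }
    rows, labels = [], []
    for pattern in PATTERNS:
        for _ in range(n_per_pattern):
            beta = means[pattern]
            obs = rng.binomial(coverage, beta) / coverage
            rows.append(obs)
            labels.append(pattern)
    values = np.asarray(rows, dtype=float)
    keys = [("sim", i + 1, "+") for i in range(values.shape[0])]
    mask = np.zeros_like(values, dtype=bool)
    return (EditingMatrix(site_keys=keys, samples=[f"s{i}" for i in
                                                   range(n_stages)],
                          values=values, mask=mask), labels)


# ---------------------------------------------------------------------------
# corpus driver
# ---------------------------------------------------------------------------

def simulate_corpus(config: SimConfig, outdir,
                    sc_stage: Optional[str] = None) -> Dict[str, object]:
    """Generate and write the full synthetic study under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, genes, repeats = simulate_reference(config)
    truth = plant_sites(config, genome, genes, repeats)

    write_fasta(outdir / "reference.fa", genome)
    write_gtf(outdir / "genes.gtf", genes)
    write_repeats(outdir / "repeats.bed", repeats)
    ref_lengths = {c: len(s) for c, s in genome.items()}
    write_vcf(outdir / "snps.vcf", truth.snps, ref_lengths)
    truth.to_json(outdir / "truth.json")

    bulk_dir = outdir / "bulk"
    bulk_dir.mkdir(exist_ok=True)
    sam_paths = {}
    for stage in config.stages:
        path = bulk_dir / f"{stage}.sam"
        write_sam(path, simulate_reads(genome, truth, config, stage),
                  ref_lengths)
        sam_paths[stage] = path

    sc_stage = sc_stage or config.stages[-1]
    sc_reads, bc_map = simulate_barcoded_reads(genome, truth, config,
                                               sc_stage)
    write_sam(outdir / "cells.sam", sc_reads, ref_lengths)
    bc_map.to_csv(outdir / "barcode_map.tsv", sep="\t", index=False)

    expr = simulate_expression(truth, config)
    expr.to_csv(outdir / "expression.tsv", sep="\t", float_format="%.6g",
                index_label="gene")
    cell_expr = simulate_cell_expression(truth, config, genes)
    cell_expr.to_csv(outdir / "cell_expression.tsv", sep="\t",
                     float_format="%.6g", index_label="cell")

    return {
        "genome": genome, "genes": genes, "repeats": repeats,
        "truth": truth, "sam_paths": sam_paths,
        "reference": outdir / "reference.fa",
        "gtf": outdir / "genes.gtf",
        "repeats_bed": outdir / "repeats.bed",
        "vcf": outdir / "snps.vcf",
        "cells_sam": outdir / "cells.sam",
        "barcode_map": outdir / "barcode_map.tsv",
        "expression": outdir / "expression.tsv",
        "cell_expression": outdir / "cell_expression.tsv",
        "truth_json": outdir / "truth.json",
        "sc_stage": sc_stage,
    }
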