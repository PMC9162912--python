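import filecmp
import math

import numpy as np
import pytest
from scipy import stats

from conftest import SMALL_STAGES, small_config
from editkit.formats_io import read_fasta
from editkit.simulate import (SimConfig, SimulationTruth, SizingError,
                              TrajectorySpec, _emit_reads, _trajectory,
                              plant_sites, simulate_barcoded_reads,
                              simulate_corpus, simulate_expression,
                              simulate_reads, simulate_reference,
                              synthetic_trajectory_matrix)

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


# ---------------------------------------------------------------------------
# config & trajectories
# ---------------------------------------------------------------------------

def test_config_validation():
    with pytest.raises(ValueError):
        SimConfig(seed=1, error_rate=0.2)
    with pytest.raises(ValueError):
        SimConfig(seed=1, n_snps=-1)


def test_trajectory_invariants_sampled():
    rng = np.random.default_rng(0)
    for _ in range(50):
        for pattern in ("high", "medium", "low"):
            tr = _trajectory(pattern, 8, rng)  # validates in __post_init__
            lv = np.array(tr.levels)
            if pattern == "high":
                assert lv[-1] >= 0.5 and np.all(np.diff(lv) >= 0)
            elif pattern == "medium":
                assert 0.2 <= lv[-1] < 0.5 and np.all(np.diff(lv) >= 0)
            else:
                assert lv.max() < 0.15 and lv.max() - lv.min() < 0.05


def test_trajectory_spec_rejects_violations():
    with pytest.raises(ValueError):
        TrajectorySpec("high", (0.1, 0.2, 0.3))        # never reaches 0.5
    with pytest.raises(ValueError):
        TrajectorySpec("medium", (0.3, 0.2, 0.25))     # not monotone
    with pytest.raises(ValueError):
        TrajectorySpec("low", (0.01, 0.2))             # above 0.15


# ---------------------------------------------------------------------------
# reference
# ---------------------------------------------------------------------------

def test_reference_gene_invariants():
    config = small_config(genome_length=50_000, n_genes=5, n_ncrna=0)
    genome, genes, repeats = simulate_reference(config)
    assert len(genome[config.chrom]) == 50_000
    assert len(genes) == 5
    spans = []
    for gene in genes:
        lo, hi = gene.span
        assert 0 <= lo < hi <= 50_000
        assert gene.cds_length() % 3 == 0
        spans.append((lo, hi))
    spans.sort()
    for (a, b), (c, d) in zip(spans, spans[1:]):
        assert b <= c, "genes overlap"
    subfams = {r.subfamily for r in repeats}
    assert "B1" in subfams and len(subfams) > 1


def test_reference_no_genes():
    config = small_config(n_genes=0, n_ncrna=0)
    genome, genes, repeats = simulate_reference(config)
    assert genes == [] and repeats == []
    assert set(genome[config.chrom]) <= set("ACGT")


def test_reference_sizing_error():
    with pytest.raises(SizingError):
        simulate_reference(small_config(genome_length=10_000, n_genes=40))


def test_reference_too_small():
    with pytest.raises(SizingError):
        simulate_reference(small_config(genome_length=5_000))


# ---------------------------------------------------------------------------
# planting
# ---------------------------------------------------------------------------

def test_planted_sites_are_A_on_strand(small_corpus):
    genome = read_fasta(small_corpus["reference"])
    truth = small_corpus["truth"]
    for site in truth.sites:
        base = genome[site.chrom][site.pos - 1]
        if site.strand == "-":
            base = COMP[base]
        assert base == "A"


def test_sites_and_snps_disjoint(small_corpus):
    truth = small_corpus["truth"]
    site_pos = {(s.chrom, s.pos) for s in truth.sites}
    snp_pos = {(s.chrom, s.pos) for s in truth.snps}
    assert not site_pos & snp_pos
    assert len(truth.snps) == small_corpus["config"].n_snps


def test_b1_sites_overlap_b1_repeats(small_corpus):
    truth = small_corpus["truth"]
    repeats = small_corpus["repeats"]
    b1_sites = [s for s in truth.sites if s.compartment == "b1"]
    assert b1_sites
    for site in b1_sites:
        assert any(r.subfamily == "B1" and r.interval.contains(site.pos - 1)
                   for r in repeats)


def test_requested_recoding_label():
    config = small_config(seed=3, n_sites={"high": 4, "medium": 0, "low": 0},
                          frac_cds_nonsyn=0.25, frac_utr3=0.25, frac_b1=0.25)
    genome, genes, repeats = simulate_reference(config)
    truth = plant_sites(config, genome, genes, repeats,
                        recoding_label="Q/R")
    (cds_site,) = [s for s in truth.sites if s.compartment == "cds"]
    assert cds_site.recoding_label == "Q/R"
    # Q/R comes from CAG codon edited at position 2 -> CGG
    gene = next(g for g in genes if g.gene_id == cds_site.gene_id)
    seq = genome[cds_site.chrom]
    iv, _ = gene.cds[0]
    if gene.strand == "+":
        cds_seq = seq[iv.start:iv.end]
        off = (cds_site.pos - 1) - iv.start
    else:
        cds_seq = "".join(COMP[b] for b in reversed(seq[iv.start:iv.end]))
        off = iv.end - cds_site.pos
    codon = cds_seq[off - off % 3:off - off % 3 + 3]
    assert codon == "CAG" and off % 3 == 1


def test_truth_round_trip(tmp_path, small_corpus):
    truth = small_corpus["truth"]
    truth.to_json(tmp_path / "t.json")
    back = SimulationTruth.from_json(tmp_path / "t.json")
    assert back.stages == truth.stages
    assert back.sites == truth.sites
    assert back.snps == truth.snps
    assert back.ownership == truth.ownership
    assert back.barcodes == truth.barcodes


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def test_determinism_byte_identical(tmp_path):
    config = small_config(seed=11)
    a = simulate_corpus(config, tmp_path / "a")
    b = simulate_corpus(config, tmp_path / "b")
    for name in ("reference.fa", "genes.gtf", "repeats.bed", "snps.vcf",
                 "truth.json", "cells.sam", "barcode_map.tsv",
                 "expression.tsv", "cell_expression.tsv"):
        assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name,
                           shallow=False), name
    for stage in config.stages:
        assert filecmp.cmp(tmp_path / "a" / "bulk" / f"{stage}.sam",
                           tmp_path / "b" / "bulk" / f"{stage}.sam",
                           shallow=False)


def _site_base_fractions(reads, pos0):
    from collections import Counter
    c = Counter()
    for rd in reads:
        start = rd["pos0"]
        if start <= pos0 < start + len(rd["seq"]):
            c[rd["seq"][pos0 - start]] += 1
    return c


def test_beta_zero_and_one_extremes():
    config = small_config(seed=5, error_rate=0.0)
    genome, genes, repeats = simulate_reference(config)
    rng = np.random.default_rng(0)
    pos0 = genome[config.chrom].index("A", 6000)
    reads0 = _emit_reads(genome, config, rng, config.chrom, pos0, 100, 0.0,
                         "G", "t")
    assert _site_base_fractions(reads0, pos0)["G"] == 0
    reads1 = _emit_reads(genome, config, rng, config.chrom, pos0, 100, 1.0,
                         "G", "t")
    counts = _site_base_fractions(reads1, pos0)
    assert counts["G"] == 100 and sum(counts.values()) == 100


def test_binomial_bound_on_g_fraction():
    # beta = 0.3, coverage 200, eps = 0: within 3 binomial sigma
    config = small_config(seed=5, error_rate=0.0)
    genome, *_ = simulate_reference(config)
    pos0 = genome[config.chrom].index("A", 6000)
    ok = 0
    n_seeds = 30
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        reads = _emit_reads(genome, config, rng, config.chrom, pos0, 200,
                            0.3, "G", "t")
        frac = _site_base_fractions(reads, pos0)["G"] / 200
        if abs(frac - 0.3) <= 3 * math.sqrt(0.3 * 0.7 / 200):
            ok += 1
    assert ok >= 0.99 * n_seeds - 1


def test_convergence_at_high_coverage():
    # spec invariant: eps=0, coverage 2000 -> |G/(G+A) - beta| <= 0.02
    config = small_config(seed=5, error_rate=0.0)
    genome, *_ = simulate_reference(config)
    rng = np.random.default_rng(42)
    beta = 0.37
    pos0 = genome[config.chrom].index("A", 6000)
    reads = _emit_reads(genome, config, rng, config.chrom, pos0, 2000,
                        beta, "G", "t")
    c = _site_base_fractions(reads, pos0)
    assert abs(c["G"] / (c["G"] + c["A"]) - beta) <= 0.02


def test_unknown_stage_rejected(small_corpus):
    genome = read_fasta(small_corpus["reference"])
    with pytest.raises(ValueError, match="unknown stage"):
        simulate_reads(genome, small_corpus["truth"],
                       small_corpus["config"], "P99")


# ---------------------------------------------------------------------------
# barcoded reads
# ---------------------------------------------------------------------------

def test_barcoded_ownership_and_conservation():
    config = small_config(seed=9, error_rate=0.0)
    genome, genes, repeats = simulate_reference(config)
    truth = plant_sites(config, genome, genes, repeats)
    reads, bc_map = simulate_barcoded_reads(genome, truth, config,
                                            config.stages[-1])
    bc2type = dict(zip(bc_map["barcode"], bc_map["cell_type"]))
    # every emitted barcode is covered by the map
    assert {rd["barcode"] for rd in reads} <= set(bc2type)
    # G reads at a site come only from the owner type (eps = 0)
    owner_of = {}
    for ct, keys in truth.ownership.items():
        for key in keys:
            owner_of[tuple(key)] = ct
    for site in truth.sites:
        if site.strand != "+":
            continue
        pos0 = site.pos - 1
        for rd in reads:
            start = rd["pos0"]
            if start <= pos0 < start + len(rd["seq"]):
                if rd["seq"][pos0 - start] == "G":
                    assert bc2type[rd["barcode"]] == owner_of[site.key]
    # conservation: per-type counts sum to the total
    per_type = {ct: 0 for ct in config.cell_types}
    for rd in reads:
        per_type[bc2type[rd["barcode"]]] += 1
    assert sum(per_type.values()) == len(reads)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def test_expression_sigma_zero_perfect_correlation(small_corpus):
    config = small_config(seed=7, adar_sigma=0.0)
    truth = small_corpus["truth"]
    expr = simulate_expression(truth, config)
    mean_beta = [np.mean([s.trajectory.levels[i] for s in truth.sites])
                 for i in range(len(truth.stages))]
    for gene in ("Adar1", "Adar2"):
        r = stats.pearsonr(expr.loc[gene], mean_beta).statistic
        assert r == pytest.approx(1.0)


def test_expression_zero_slope_uncorrelated(small_corpus):
    config = small_config(seed=7, adar_slope=(0.0, 0.0), adar_sigma=1.0)
    truth = small_corpus["truth"]
    rs = []
    for seed in range(40):
        cfg = small_config(seed=seed, adar_slope=(0.0, 0.0), adar_sigma=1.0)
        expr = simulate_expression(truth, cfg)
        mean_beta = [np.mean([s.trajectory.levels[i] for s in truth.sites])
                     for i in range(len(truth.stages))]
        rs.append(stats.pearsonr(expr.loc["Adar2"], mean_beta).statistic)
    assert abs(np.mean(rs)) < 0.2


def test_expression_slope_recovery(small_corpus):
    # OLS slope of FPKM on mean beta approximates the configured slope
    truth = small_corpus["truth"]
    mean_beta = np.array([
        np.mean([s.trajectory.levels[i] for s in truth.sites])
        for i in range(len(truth.stages))])
    slopes = []
    for seed in range(60):
        cfg = small_config(seed=seed, adar_slope=(30.0, 60.0),
                          adar_sigma=0.5)
        expr = simulate_expression(truth, cfg)
        fit = stats.linregress(mean_beta, expr.loc["Adar2"])
        slopes.append(fit.slope)
    assert abs(np.mean(slopes) - 60.0) <= 0.2 * 60.0


# ---------------------------------------------------------------------------
# trajectory matrices
# ---------------------------------------------------------------------------

def test_synthetic_trajectory_matrix_gaps():
    matrix, labels = synthetic_trajectory_matrix(n_per_pattern=10, seed=0)
    assert matrix.values.shape == (30, 8)
    assert labels.count("high") == 10
    # pattern means stay >= 0.2 apart at every stage
    vals = matrix.values
    hi = vals[:10].mean(axis=0)
    med = vals[10:20].mean(axis=0)
    lo = vals[20:].mean(axis=0)
    assert np.all(hi - med >= 0.15) and np.all(med - lo >= 0.15)
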