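import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from editkit import call_sites as cs
from editkit.formats_io import parse_alignments, parse_snps, read_fasta
from editkit.simulate import SimConfig, SimulationTruth, simulate_corpus

SMALL_STAGES = ("E14.5", "P0", "P7", "P21")


def small_config(seed=1, **overrides) -> SimConfig:
    """A scaled-down simulation for fast per-corpus tests."""
    kw = dict(
        seed=seed,
        genome_length=12_000,
        n_genes=3,
        n_ncrna=1,
        n_sites={"high": 3, "medium": 3, "low": 3},
        n_snps=2,
        n_null_sites=3,
        mean_coverage=25.0,
        stages=SMALL_STAGES,
        cells_per_type=5,
        cell_coverage=25.0,
        n_background_genes=30,
    )
    kw.update(overrides)
    return SimConfig(**kw)


@pytest.fixture(scope="session")
def default_corpus(tmp_path_factory):
    """The full default corpus (8 stages, 60 sites, 20 SNPs, coverage 50)."""
    outdir = tmp_path_factory.mktemp("corpus_default")
    config = SimConfig(seed=1)
    artifacts = simulate_corpus(config, outdir)
    artifacts["config"] = config
    artifacts["outdir"] = outdir
    return artifacts


@pytest.fixture(scope="session")
def default_call(default_corpus):
    """Cascade result on the default corpus with default thresholds."""
    config = cs.FilterConfig()
    reference = default_corpus["genome"]
    truth = default_corpus["truth"]
    snps = parse_snps(default_corpus["vcf"])
    pileups = {
        stage: cs.pileup_counts(
            parse_alignments(default_corpus["sam_paths"][stage]),
            reference, config)
        for stage in truth.stages
    }
    result = cs.call_from_pileups(pileups, reference, snps, config,
                                  sample_order=list(truth.stages))
    return {"result": result, "pileups": pileups, "config": config,
            "snps": snps}


@pytest.fixture(scope="session")
def small_corpus(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("corpus_small")
    config = small_config(seed=7)
    artifacts = simulate_corpus(config, outdir)
    artifacts["config"] = config
    artifacts["outdir"] = outdir
    return artifacts
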