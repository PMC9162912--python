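"""Barcode-split pseudobulk editing quantification and gene-set scoring.

Reads carrying cell barcodes are partitioned by cell type, piled up at a
background list of high-confidence sites with the same quality filters as
bulk, and quantified with the single-cell convention: level = edited reads
/ all quality-passing reads at the site (note: not G/(G+A) as in bulk).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .call_sites import FilterConfig, SiteKey, _site_counts, pileup_counts
from .formats_io import AlignedRead


@dataclass
class CellTypeGroup:
    cell_type: str
    barcodes: frozenset
    read_count: int


@dataclass(frozen=True)
class PseudobulkEvidence:
    cell_type: str
    site: SiteKey
    coverage: int
    n_edit: int

    @property
    def level(self) -> float:
        return self.n_edit / self.coverage

    def __post_init__(self):
        if not (0 <= self.n_edit <= self.coverage):
            raise ValueError("edited reads exceed coverage")


@dataclass
class ModuleScoreResult:
    scores: pd.Series            # cell id -> score
    n_bins: int
    n_ctrl: int
    seed: int


# ---------------------------------------------------------------------------
# barcode splitting
# ---------------------------------------------------------------------------

def read_barcode_map(path) -> Dict[str, str]:
    """TSV (barcode, cell_type) -> dict; duplicate barcodes across cell
    types are an error."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"barcode", "cell_type"} <= set(df.columns):
        raise ValueError("barcode map needs columns: barcode, cell_type")
    mapping: Dict[str, str] = {}
    for bc, ct in zip(df["barcode"], df["cell_type"]):
        if bc in mapping and mapping[bc] != ct:
            raise ValueError(f"barcode {bc!r} maps to multiple cell types")
        mapping[bc] = ct
    return mapping


def split_by_celltype(reads: Iterable[AlignedRead],
                      barcode_map: Dict[str, str]
                      ) -> Tuple[List[CellTypeGroup],
                                 Dict[str, List[AlignedRead]],
                                 List[AlignedRead]]:
    """Partition barcoded reads into per-cell-type streams.

    Every barcoded read lands in exactly one group or the unassigned
    bin, so group counts plus unassigned equals the number of barcoded
    reads.  Reads without a barcode go to the unassigned bin too.
    """
    streams: Dict[str, List[AlignedRead]] = {
        ct: [] for ct in dict.fromkeys(barcode_map.values())
    }
    unassigned: List[AlignedRead] = []
    for read in reads:
        ct = barcode_map.get(read.barcode) if read.barcode else None
        if ct is None:
            unassigned.append(read)
        else:
            streams[ct].append(read)
    by_type: Dict[str, set] = {ct: set() for ct in streams}
    for bc, ct in barcode_map.items():
        by_type[ct].add(bc)
    groups = [
        CellTypeGroup(cell_type=ct, barcodes=frozenset(by_type[ct]),
                      read_count=len(streams[ct]))
        for ct in streams
    ]
    return groups, streams, unassigned


# ---------------------------------------------------------------------------
# pseudobulk editing at background sites
# ---------------------------------------------------------------------------

def pseudobulk_editing(reads: Iterable[AlignedRead],
                       background: Sequence[SiteKey],
                       reference: dict,
                       config: FilterConfig,
                       cell_type: str) -> List[PseudobulkEvidence]:
    """Editing per background site for one cell type's read stream.

    Same mapq / base-quality filters as bulk; the level denominator is
    all quality-passing reads at the site.  Uncovered sites are absent
    from the output.
    """
    counts = pileup_counts(reads, reference, config)
    out: List[PseudobulkEvidence] = []
    for key in background:
        chrom, pos, strand = key
        base_counts = counts.get((chrom, pos - 1))
        if base_counts is None:
            continue
        ref_base = "A" if strand == "+" else "T"
        _s, n_ref, n_edit, n_other = _site_counts(base_counts, ref_base)
        n = n_ref + n_edit + n_other
        if n == 0:
            continue
        out.append(PseudobulkEvidence(cell_type=cell_type, site=key,
                                      coverage=n, n_edit=n_edit))
    return out


def site_ratio(evidence: Sequence[PseudobulkEvidence],
               background: Sequence[SiteKey],
               min_cov: int = 5, min_edit: int = 2) -> float:
    """Fraction of background sites detected in a cell type.

    Detected = coverage >= min_cov and edited reads >= min_edit.
    """
    if not background:
        raise ValueError("empty background site list")
    if min_cov < 0 or min_edit < 0:
        raise ValueError("thresholds must be >= 0")
    bg = set(background)
    detected = {
        ev.site for ev in evidence
        if ev.site in bg and ev.coverage >= min_cov and ev.n_edit >= min_edit
    }
    return len(detected) / len(bg)


# ---------------------------------------------------------------------------
# gene-set module score
# ---------------------------------------------------------------------------

def module_score(expression: pd.DataFrame, gene_set: Sequence[str],
                 n_bins: int = 24, n_ctrl: int = 100,
                 seed: int = 0) -> ModuleScoreResult:
    """Expression-matched gene-set score per cell.

    ``expression`` is cells x genes on a log scale.  Genes are ranked by
    mean expression over cells and cut into ``n_bins`` equal-frequency
    bins; each set gene draws ``n_ctrl`` control genes from its bin (set
    genes excluded; with replacement when the bin is smaller).  The score
    is the per-cell mean over set genes minus the mean over the pooled
    controls.
    """
    gene_set = list(dict.fromkeys(gene_set))
    if not gene_set:
        raise ValueError("empty gene set")
    for g in gene_set:
        if g not in expression.columns:
            raise KeyError(f"gene {g!r} absent from expression matrix")
    if expression.shape[1] < n_bins:
        raise ValueError(
            f"{expression.shape[1]} genes < n_bins={n_bins}")
    rng = np.random.default_rng(seed)
    means = expression.mean(axis=0)
    ranks = means.rank(method="first")
    bins = pd.qcut(ranks, n_bins, labels=False)
    set_genes = set(gene_set)
    ctrl_genes: List[str] = []
    for g in gene_set:
        pool = [c for c in expression.columns
                if bins[c] == bins[g] and c not in set_genes]
        # if set genes monopolise the bin, widen to neighbouring bins
        width = 0
        while not pool and width < n_bins:
            width += 1
            pool = [c for c in expression.columns
                    if abs(bins[c] - bins[g]) <= width
                    and c not in set_genes]
        if not pool:
            raise ValueError(f"no control genes available for {g!r}")
        replace = len(pool) < n_ctrl
        chosen = rng.choice(np.array(pool, dtype=object), size=n_ctrl,
                            replace=replace)
        ctrl_genes.extend(chosen.tolist())
    set_mean = expression[gene_set].mean(axis=1)
    ctrl_mean = expression[ctrl_genes].mean(axis=1)
    return ModuleScoreResult(scores=set_mean - ctrl_mean, n_bins=n_bins,
                             n_ctrl=n_ctrl, seed=seed)
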