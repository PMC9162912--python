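"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive and shares no code with the
package: SAM records are split by hand and the CIGAR is walked
explicitly, the calling cascade enumerates reads per position, the
rank-sum null is a full itertools enumeration, and the codon table is
hard-coded from the standard 64-codon layout.
"""

from __future__ import annotations

import re
from itertools import combinations

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def hand_parse_sam(path):
    """Parse SAM text by hand; returns dicts with 0-based base placements."""
    reads = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("@") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            flag = int(f[1])
            if flag & 0x4 or flag & 0x100 or flag & 0x800:
                continue
            chrom, pos, mapq, cigar = f[2], int(f[3]), int(f[4]), f[5]
            seq, qual = f[9], f[10]
            barcode = None
            for tag in f[11:]:
                if tag.startswith("CB:Z:"):
                    barcode = tag[5:]
            bases = []
            q = 0
            r = pos - 1
            for num, op in _CIGAR_RE.findall(cigar):
                n = int(num)
                if op in "M=X":
                    for i in range(n):
                        bases.append((r + i, seq[q + i],
                                      ord(qual[q + i]) - 33))
                    q += n
                    r += n
                elif op in "IS":
                    q += n
                elif op in "DN":
                    r += n
            reads.append({
                "name": f[0], "chrom": chrom, "pos": pos, "mapq": mapq,
                "strand": "-" if flag & 0x10 else "+", "cigar": cigar,
                "bases": bases, "barcode": barcode,
            })
    return reads


def brute_force_cascade(sam_paths, reference, snps, *, min_base_quality=25,
                        min_mapq=20, min_coverage=15, min_mismatch_rate=0.02,
                        recurrence_fraction=0.5,
                        max_third_allele_fraction=0.01, dedup=True):
    """Naive reimplementation of the full calling cascade.

    ``sam_paths``: {sample: path}; ``snps``: set of (chrom, pos1, ref, alt).
    Returns (final_sites, evidence) where final_sites is a set of
    (chrom, pos1, strand) keys and evidence maps key -> {sample:
    (coverage, n_ref, n_edit, n_other)} over samples with any coverage.
    """
    pileups = {}
    candidates = {}
    for sample, path in sam_paths.items():
        reads = hand_parse_sam(path)
        if dedup:
            seen = set()
            kept = []
            for rd in reads:
                key = (rd["chrom"], rd["pos"], rd["strand"], rd["cigar"])
                if key in seen:
                    continue
                seen.add(key)
                kept.append(rd)
            reads = kept
        counts = {}
        for rd in reads:
            if rd["mapq"] < min_mapq:
                continue
            for r, b, q in rd["bases"]:
                if q < min_base_quality or b == "N":
                    continue
                site = counts.setdefault((rd["chrom"], r),
                                         {"A": 0, "C": 0, "G": 0, "T": 0})
                site[b] += 1
        pileups[sample] = counts
        cands = {}
        for (chrom, r), c in counts.items():
            ref_base = reference[chrom][r].upper()
            if ref_base == "A" and c["G"] > 0:
                strand = "+"
                n_ref, n_edit, n_oth = c["A"], c["G"], c["C"] + c["T"]
            elif ref_base == "T" and c["C"] > 0:
                strand = "-"
                n_ref, n_edit, n_oth = c["T"], c["C"], c["A"] + c["G"]
            else:
                continue
            n = n_ref + n_edit + n_oth
            if n < min_coverage:
                continue
            if n_edit / n < min_mismatch_rate:
                continue
            if n_oth / n > max_third_allele_fraction:
                continue
            cands[(chrom, r + 1, strand)] = (n, n_ref, n_edit, n_oth)
        candidates[sample] = cands

    support = {}
    for sample in sam_paths:
        for key in candidates[sample]:
            support[key] = support.get(key, 0) + 1
    n_samples = len(sam_paths)
    final = set()
    for key, cnt in support.items():
        chrom, pos, strand = key
        is_snp = ((chrom, pos, "A", "G") in snps if strand == "+"
                  else (chrom, pos, "T", "C") in snps)
        if is_snp:
            continue
        if cnt / n_samples > recurrence_fraction:
            final.add(key)

    evidence = {}
    for key in final:
        chrom, pos, strand = key
        per_sample = {}
        for sample in sam_paths:
            c = pileups[sample].get((chrom, pos - 1))
            if c is None:
                continue
            if strand == "+":
                n_ref, n_edit, n_oth = c["A"], c["G"], c["C"] + c["T"]
            else:
                n_ref, n_edit, n_oth = c["T"], c["C"], c["A"] + c["G"]
            n = n_ref + n_edit + n_oth
            if n == 0:
                continue
            per_sample[sample] = (n, n_ref, n_edit, n_oth)
        evidence[key] = per_sample
    return final, evidence


def midranks(values):
    """Midranks (ties averaged), computed by hand."""
    n = len(values)
    order = sorted(range(n), key=lambda i: values[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def enum_ranksum(x, y):
    """Two-sided exact rank-sum p via full permutation enumeration.

    Returns (U for x, two-sided p).  Feasible for C(n1+n2, n1) up to a
    few hundred thousand.
    """
    x, y = list(x), list(y)
    n1 = len(x)
    pooled = x + y
    ranks = midranks(pooled)
    w_obs = sum(ranks[:n1])
    total = ge = le = 0
    for comb in combinations(range(len(pooled)), n1):
        w = sum(ranks[i] for i in comb)
        total += 1
        if w >= w_obs - 1e-9:
            ge += 1
        if w <= w_obs + 1e-9:
            le += 1
    p = min(1.0, 2.0 * min(ge / total, le / total))
    u = w_obs - n1 * (n1 + 1) / 2.0
    return u, p


# standard codon table, spelled out independently (TCAG order)
_AA = ("FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG")
_NT = "TCAG"
CODON_AA = {
    a + b + c: _AA[16 * i + 4 * j + k]
    for i, a in enumerate(_NT)
    for j, b in enumerate(_NT)
    for k, c in enumerate(_NT)
}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(seq):
    return "".join(_COMP[b] for b in reversed(seq))
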