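"""Temporal co-editing pattern discovery and ADAR-expression regression."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .call_sites import EditingMatrix

PATTERN_LABELS_3 = ("high", "medium", "low")


@dataclass
class PatternAssignment:
    site_keys: List[tuple]
    cluster_ids: np.ndarray           # per site
    labels: Dict[int, str]            # cluster id -> label
    centroids: np.ndarray             # k x n_stages
    sse: float
    sse_by_k: Optional[Dict[int, float]] = None

    def label_of(self, i: int) -> str:
        return self.labels[int(self.cluster_ids[i])]

    @property
    def site_labels(self) -> List[str]:
        return [self.labels[int(c)] for c in self.cluster_ids]


@dataclass
class RegressionResult:
    gene: str
    slope: Optional[float]
    intercept: Optional[float]
    pearson_r: Optional[float]
    p_value: Optional[float]
    q_value: Optional[float] = None
    flagged: bool = False


# ---------------------------------------------------------------------------
# imputation
# ---------------------------------------------------------------------------

def impute_matrix(matrix: EditingMatrix) -> np.ndarray:
    """Replace missing entries with the site's observed mean.

    Observed values are untouched.  A site with no observed value is an
    error (it cannot be clustered meaningfully).
    """
    values = matrix.values.copy()
    for i in range(values.shape[0]):
        row = values[i]
        observed = row[~np.isnan(row)]
        if observed.size == 0:
            raise ValueError(
                f"site {matrix.site_keys[i]} has no observed editing level")
        row[np.isnan(row)] = observed.mean()
    return values


# ---------------------------------------------------------------------------
# k-means patterns
# ---------------------------------------------------------------------------

def _fit_kmeans(data: np.ndarray, k: int, n_init: int, seed: int,
                warm_centers: Optional[np.ndarray] = None) -> KMeans:
    best = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(data)
    if warm_centers is not None:
        # warm start: previous centroids plus the worst-fit point; adding a
        # centroid at a data point cannot raise the optimum, so SSE(k) is
        # guaranteed <= SSE(k-1)
        d2 = ((data[:, None, :] - warm_centers[None]) ** 2).sum(-1).min(1)
        init = np.vstack([warm_centers, data[int(np.argmax(d2))]])
        warm = KMeans(n_clusters=k, init=init, n_init=1,
                      random_state=seed).fit(data)
        if warm.inertia_ < best.inertia_:
            best = warm
    return best


def _order_labels(centroids: np.ndarray, k: int) -> Dict[int, str]:
    """Label clusters by descending centroid grand mean."""
    means = centroids.mean(axis=1)
    order = np.argsort(-means, kind="stable")
    if k == 3:
        names = PATTERN_LABELS_3
    else:
        names = tuple(f"c{i + 1}" for i in range(k))
    return {int(cid): names[rank] for rank, cid in enumerate(order)}


def kmeans_patterns(matrix: EditingMatrix, k: int = 3, n_init: int = 10,
                    seed: int = 0,
                    standardize: bool = False) -> PatternAssignment:
    """Cluster site trajectories with k-means (Lloyd, Euclidean, restarts).

    Clusters are labelled by descending centroid grand mean; for k = 3
    the labels are high / medium / low.  Missing entries are mean-imputed
    for clustering only.
    """
    data = impute_matrix(matrix)
    if data.shape[0] < k:
        raise ValueError(f"{data.shape[0]} sites < k={k}")
    fit_data = data
    if standardize:
        mu = data.mean(axis=1, keepdims=True)
        sd = data.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        fit_data = (data - mu) / sd
    km = _fit_kmeans(fit_data, k, n_init, seed)
    # centroids reported on the raw level scale
    centroids = np.vstack([
        data[km.labels_ == c].mean(axis=0) for c in range(k)
    ])
    labels = _order_labels(centroids, k)
    return PatternAssignment(
        site_keys=list(matrix.site_keys),
        cluster_ids=km.labels_.copy(),
        labels=labels,
        centroids=centroids,
        sse=float(km.inertia_),
    )


def elbow_curve(matrix: EditingMatrix, k_max: int = 8, n_init: int = 10,
                seed: int = 0) -> Dict:
    """SSE as a function of k plus an advisory elbow suggestion.

    The curve is non-increasing by construction (each k is warm-started
    from the previous optimum).  The suggested k maximises the second
    difference of log(SSE) — i.e. the largest relative kink in the
    curve, robust to the dominant k=1 term; advisory only, the pipeline
    default remains k = 3.
    """
    if k_max < 3:
        raise ValueError("k_max must be >= 3")
    data = impute_matrix(matrix)
    n = data.shape[0]
    if k_max > n:
        warnings.warn(f"k_max {k_max} > {n} rows; truncating")
        k_max = n
    sse: Dict[int, float] = {}
    prev_centers = None
    for k in range(1, k_max + 1):
        km = _fit_kmeans(data, k, n_init, seed, warm_centers=prev_centers)
        sse[k] = float(km.inertia_)
        prev_centers = km.cluster_centers_
    ks = sorted(sse)
    suggested = None
    if len(ks) >= 3:
        eps = 1e-12
        log_sse = {k: np.log(sse[k] + eps) for k in ks}
        second_diff = {
            k: log_sse[k - 1] - 2 * log_sse[k] + log_sse[k + 1]
            for k in ks[1:-1]
        }
        suggested = max(second_diff, key=lambda k: (second_diff[k], -k))
    return {"sse_by_k": sse, "suggested_k": suggested}


# ---------------------------------------------------------------------------
# ADAR regression
# ---------------------------------------------------------------------------

def adar_regression(overall_levels: Sequence[float],
                    expression: pd.DataFrame,
                    genes: Sequence[str] = ("Adar1", "Adar2")
                    ) -> List[RegressionResult]:
    """OLS of overall editing level on per-stage gene expression.

    ``expression`` is genes x stages (FPKM), columns in stage order
    matching ``overall_levels``.  The two-sided t-test p-value on the
    slope is Benjamini-Hochberg adjusted across the requested genes.
    """
    y = np.asarray(overall_levels, dtype=float)
    if y.size < 3:
        raise ValueError("need >= 3 stages for regression")
    results: List[RegressionResult] = []
    for gene in genes:
        if gene not in expression.index:
            raise KeyError(f"gene {gene!r} absent from expression table")
        x = expression.loc[gene].to_numpy(dtype=float)
        if x.size != y.size:
            raise ValueError("expression stages do not match editing stages")
        if np.allclose(x, x[0]):
            results.append(RegressionResult(
                gene=gene, slope=None, intercept=None, pearson_r=None,
                p_value=None, flagged=True))
            continue
        fit = stats.linregress(x, y)
        results.append(RegressionResult(
            gene=gene, slope=float(fit.slope),
            intercept=float(fit.intercept), pearson_r=float(fit.rvalue),
            p_value=float(fit.pvalue)))
    testable = [r for r in results if r.p_value is not None]
    if testable:
        _, q, _, _ = multipletests([r.p_value for r in testable],
                                   method="fdr_bh")
        for r, qv in zip(testable, q):
            r.q_value = float(qv)
    return results


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH-adjusted q-values (convenience wrapper)."""
    _, q, _, _ = multipletests(list(p_values), method="fdr_bh")
    return q


# ---------------------------------------------------------------------------
# pattern composition
# ---------------------------------------------------------------------------

def pattern_composition(assignment: PatternAssignment,
                        annotations: Sequence[dict],
                        what: str = "region") -> pd.DataFrame:
    """Per-pattern fraction table of an annotation attribute.

    ``what`` selects the attribute: 'region', 'recoding_kind', or
    'repeat' (repeat vs non-repeat).  Each row sums to 1; empty patterns
    are flagged as all-zero rows.
    """
    if len(annotations) != len(assignment.site_keys):
        raise ValueError("annotations do not match assignment sites")

    def attr(a: dict) -> str:
        if what == "repeat":
            return "repeat" if a.get("repeat_family") else "non_repeat"
        return str(a.get(what))

    labels = assignment.site_labels
    cats = sorted({attr(a) for a in annotations})
    patterns = sorted(set(assignment.labels.values()))
    rows = {}
    for pat in patterns:
        sub = [attr(a) for a, lab in zip(annotations, labels) if lab == pat]
        n = len(sub)
        if n == 0:
            warnings.warn(f"pattern {pat!r} is empty")
            rows[pat] = {c: 0.0 for c in cats}
        else:
            rows[pat] = {c: sub.count(c) / n for c in cats}
    return pd.DataFrame.from_dict(rows, orient="index")[cats]
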