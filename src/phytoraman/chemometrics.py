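"""Statistical layer: PCA of preprocessed spectra and Kruskal-Wallis day test.

PCA is a mean-centred singular value decomposition (no variable scaling —
SNV already standardises each spectrum).  Phase structure of the culture
shows up as separated day-groups in score space; the non-parametric
Kruskal-Wallis test on the first component score, with culture days as
groups, quantifies that separation, and a Dunn-type pairwise mean-rank
comparison locates the day boundaries where the physiology shifts.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm, rankdata

from .spectra import SpectraSet

__all__ = ["PCAResult", "pca", "KWResult", "kruskal_wallis", "pairwise_rank_comparison"]


@dataclass
class PCAResult:
    """Scores, loadings and explained-variance fractions of a PCA.

    ``scores`` is n_spectra x k, ``loadings`` k x n_points (orthonormal
    rows), ``explained_fraction`` the first k values of sigma_i^2 / sum
    sigma^2 over *all* components.  Signs follow the convention that each
    loading's largest-magnitude element is positive.
    """

    scores: np.ndarray
    loadings: np.ndarray
    explained_fraction: np.ndarray
    center: np.ndarray
    singular_values: np.ndarray
    meta: pd.DataFrame = field(repr=False)

    def scores_table(self) -> pd.DataFrame:
        out = self.meta.copy()
        for j in range(self.scores.shape[1]):
            out[f"PC{j + 1}"] = self.scores[:, j]
        return out


def pca(spectra: SpectraSet, k: int = 3) -> PCAResult:
    """Mean-centred PCA via singular value decomposition."""
    n, p = spectra.matrix.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 spectra")
    max_k = min(n - 1, p)
    if not 1 <= k <= max_k:
        raise ValueError(f"k must lie in [1, {max_k}] for {n} spectra x {p} points")
    center = spectra.matrix.mean(axis=0)
    centered = spectra.matrix - center
    u, sigma, vt = np.linalg.svd(centered, full_matrices=False)
    total = float(np.sum(sigma**2))
    explained = sigma**2 / total
    scores = u * sigma
    # sign convention: largest-magnitude loading element positive
    for j in range(vt.shape[0]):
        if vt[j, np.argmax(np.abs(vt[j]))] < 0:
            vt[j] = -vt[j]
            scores[:, j] = -scores[:, j]
    return PCAResult(
        scores=scores[:, :k],
        loadings=vt[:k],
        explained_fraction=explained[:k],
        center=center,
        singular_values=sigma[:k],
        meta=spectra.meta.copy(),
    )


@dataclass
class KWResult:
    """Tie-corrected Kruskal-Wallis statistic with per-group rank summaries."""

    H: float
    p_value: float
    group_stats: pd.DataFrame
    n_total: int
    tie_term: float  # sum of t^3 - t over tie groups

    def summary(self) -> str:
        lines = [
            f"Kruskal-Wallis: H = {self.H:.4f}, "
            f"df = {len(self.group_stats) - 1}, p = {self.p_value:.3g}",
            self.group_stats.to_string(index=False),
        ]
        return "\n".join(lines)


def kruskal_wallis(values, groups) -> KWResult:
    """Kruskal-Wallis one-way rank test with midrank ties.

    H = [12/(N(N+1)) * sum_j R_j^2/n_j - 3(N+1)] / (1 - sum(t^3 - t)/(N^3 - N))

    where R_j is the rank sum of group j and t runs over tie-group sizes;
    the p-value uses the chi-square approximation with (groups - 1) degrees
    of freedom.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape or values.ndim != 1:
        raise ValueError("values and groups must be equal-length 1-D sequences")
    labels = pd.unique(groups)
    if labels.size < 2:
        raise ValueError("Kruskal-Wallis needs at least 2 groups")
    if np.all(values == values[0]):
        raise ValueError("all values identical; ranks are degenerate")
    n_total = values.size
    ranks = rankdata(values)  # midranks for ties
    _, counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(counts.astype(float) ** 3 - counts))
    correction = 1.0 - tie_term / (n_total**3 - n_total)

    records = []
    h_sum = 0.0
    for lab in sorted(labels.tolist()):
        r = ranks[groups == lab]
        if r.size == 0:
            raise ValueError(f"group {lab!r} is empty")
        h_sum += r.sum() ** 2 / r.size
        records.append(
            {
                "group": lab,
                "n": int(r.size),
                "mean_rank": float(r.mean()),
                "median_rank": float(np.median(r)),
            }
        )
    h = (12.0 / (n_total * (n_total + 1)) * h_sum - 3.0 * (n_total + 1)) / correction
    p = float(chi2.sf(h, labels.size - 1))
    return KWResult(
        H=float(h),
        p_value=p,
        group_stats=pd.DataFrame.from_records(records),
        n_total=n_total,
        tie_term=tie_term,
    )


def pairwise_rank_comparison(
    kw: KWResult, alpha: float = 0.05, pairs: str = "adjacent"
) -> pd.DataFrame:
    """Dunn-type pairwise mean-rank comparison with Bonferroni control.

    z_ij = |Rbar_i - Rbar_j| / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j))

    with T the tie term of the omnibus test.  ``pairs`` selects which group
    pairs are compared: ``"adjacent"`` (consecutive groups in sorted order,
    the day-boundary scan) or ``"all"``; Bonferroni multiplies raw two-sided
    normal p-values by the number of pairs actually compared.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    gs = kw.group_stats
    n_total = kw.n_total
    variance_scale = n_total * (n_total + 1) / 12.0 - kw.tie_term / (12.0 * (n_total - 1))
    if pairs == "adjacent":
        index_pairs = [(i, i + 1) for i in range(len(gs) - 1)]
    elif pairs == "all":
        index_pairs = list(combinations(range(len(gs)), 2))
    else:
        raise ValueError(f"pairs must be 'adjacent' or 'all', got {pairs!r}")
    m = len(index_pairs)
    records = []
    for i, j in index_pairs:
        gi, gj = gs.iloc[i], gs.iloc[j]
        se = np.sqrt(variance_scale * (1.0 / gi["n"] + 1.0 / gj["n"]))
        diff = gi["mean_rank"] - gj["mean_rank"]
        z = abs(diff) / se if se > 0 else np.inf
        p_raw = float(2.0 * norm.sf(z))
        p_adj = min(1.0, p_raw * m)
        records.append(
            {
                "group_1": gi["group"],
                "group_2": gj["group"],
                "rank_difference": float(diff),
                "z": float(z),
                "p_raw": p_raw,
                "p_adjusted": p_adj,
                "significant": p_adj < alpha,
            }
        )
    out = pd.DataFrame.from_records(records)
    out.attrs["alpha"] = alpha
    out.attrs["pairs"] = pairs
    return out
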