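"""Statistical kernels: rank tests, NB likelihood-ratio DE, FDR, enrichment.

The differential-expression surface has two paths matching the two
sequencing modalities: a negative-binomial likelihood-ratio test with a
pooled method-of-moments dispersion for bulk designs (few replicates,
model-based), and the Wilcoxon rank-sum test on log-CPM for cell-level data
(many observations, distribution-free).  Both feed Benjamini-Hochberg
step-up FDR control.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.special
import scipy.stats

from .io_formats import CountMatrix
from .preprocess import filter_low_expressed, log_cpm, tmm_factors

__all__ = [
    "DETable",
    "wilcoxon_rank_sum",
    "nb_lrt_test",
    "estimate_dispersion",
    "bh_fdr",
    "hypergeom_test",
    "spearman_corr",
    "de_table",
]


@dataclass
class DETable:
    """Per-gene effect sizes and (adjusted) p-values.

    ``log2fc`` is disease minus control on log2-CPM means; ``direction`` is
    its sign (0 only for an exactly null effect).
    """

    table: pd.DataFrame  # index: gene; columns: log2fc, p, q, direction
    test: str

    def __post_init__(self) -> None:
        t = self.table
        required = {"log2fc", "p", "q", "direction"}
        if not required.issubset(t.columns):
            raise ValueError(f"DE table missing columns {required - set(t.columns)}")
        if len(t) and (t["q"] + 1e-12 < t["p"]).any():
            raise ValueError("BH q-values cannot be smaller than p-values")
        expect = np.sign(t["log2fc"]).astype(int)
        if len(t) and not (t["direction"] == expect).all():
            raise ValueError("direction must equal sign(log2fc)")

    def __len__(self) -> int:
        return len(self.table)

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["q"] < alpha]


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U for x: #{x_i > y_j} + 0.5 * #{x_i == y_j}."""
    allv = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(allv)  # mid-ranks for ties
    r_x = ranks[: x.size].sum()
    return float(r_x - x.size * (x.size + 1) / 2.0)


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    mode: Literal["exact", "approx", "auto"] = "auto",
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    The exact path enumerates the permutation distribution of U over all
    C(n, n_x) group assignments of the pooled values (mid-ranks for ties) and
    reports 2*min(lower tail, upper tail) clipped at 1.  The normal
    approximation uses the tie-corrected variance and a 0.5 continuity
    correction.  ``auto`` takes the exact path when n_x + n_y <= 14 and the
    pooled sample has no ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("wilcoxon_rank_sum requires non-empty samples")
    n_x, n_y = x.size, y.size
    n = n_x + n_y
    u = _u_statistic(x, y)
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < n
    if mode == "auto":
        mode = "exact" if (n <= 14 and not has_ties) else "approx"
    if mode == "exact":
        ranks = scipy.stats.rankdata(pooled)
        base = n_x * (n_x + 1) / 2.0
        us = np.array(
            [ranks[list(c)].sum() - base for c in combinations(range(n), n_x)]
        )
        m = us.size
        lower = np.count_nonzero(us <= u + 1e-9) / m
        upper = np.count_nonzero(us >= u - 1e-9) / m
        p = min(1.0, 2.0 * min(lower, upper))
    elif mode == "approx":
        mu = n_x * n_y / 2.0
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts))
        var = n_x * n_y / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var <= 0:
            return u, 1.0
        diff = u - mu
        z = (diff - 0.5 * np.sign(diff)) / math.sqrt(var)
        p = min(1.0, 2.0 * scipy.stats.norm.sf(abs(z)))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return u, max(p, np.finfo(float).tiny)


# ---------------------------------------------------------------------------
# negative-binomial LRT


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> float:
    """NB2 log-likelihood; mu may contain zeros (only valid when y == 0)."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    out = np.zeros_like(mu)
    pos = mu > 0
    if pos.any():
        r = 1.0 / phi
        m = mu[pos]
        yy = y[pos]
        out[pos] = (
            scipy.special.gammaln(yy + r)
            - scipy.special.gammaln(r)
            - scipy.special.gammaln(yy + 1)
            + r * np.log(r / (r + m))
            + yy * np.log(m / (r + m))
        )
    if np.any((~pos) & (y > 0)):
        return -np.inf
    return float(out.sum())


def _nb_fit_mean(y: np.ndarray, offsets: np.ndarray, phi: float) -> np.ndarray:
    """MLE of the NB mean with a log link and fixed offsets: mu_i = e^(b + o_i).

    Newton-Raphson on the score sum_i (y_i - mu_i) / (1 + phi mu_i); returns
    the fitted per-observation means.  An all-zero response gives mu = 0.
    """
    y = np.asarray(y, dtype=float)
    s = float(y.sum())
    e = np.exp(offsets)
    if s == 0:
        return np.zeros_like(e)
    beta = math.log(s / e.sum())
    for _ in range(100):
        mu = np.exp(beta) * e
        denom = 1.0 + phi * mu
        score = float(np.sum((y - mu) / denom))
        info = float(np.sum(mu / denom))
        if info <= 0:
            break
        step = score / info
        beta += step
        if abs(step) < 1e-12:
            break
    return np.exp(beta) * e


def nb_lrt_test(
    counts_x: Sequence[int],
    counts_y: Sequence[int],
    offsets: Sequence[float] | None = None,
    dispersion: float = 0.1,
) -> tuple[float, float]:
    """Likelihood-ratio test of equal NB means between two groups.

    Fits group-specific and common means under NB(mu, phi) with log link and
    fixed log-library-size offsets; the statistic 2*(l_groups - l_common) is
    referred to chi-square with 1 df.  An all-zero gene returns (0, 1).
    """
    x = np.asarray(counts_x, dtype=float)
    y = np.asarray(counts_y, dtype=float)
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    if offsets is None:
        offs = np.zeros(x.size + y.size)
    else:
        offs = np.asarray(offsets, dtype=float)
        if offs.size != x.size + y.size:
            raise ValueError("offsets must cover both groups (x first, then y)")
    if x.sum() == 0 and y.sum() == 0:
        return 0.0, 1.0
    o_x, o_y = offs[: x.size], offs[x.size:]
    mu_x = _nb_fit_mean(x, o_x, dispersion)
    mu_y = _nb_fit_mean(y, o_y, dispersion)
    mu_0 = _nb_fit_mean(np.concatenate([x, y]), offs, dispersion)
    ll_alt = _nb_loglik(x, mu_x, dispersion) + _nb_loglik(y, mu_y, dispersion)
    ll_null = _nb_loglik(np.concatenate([x, y]), mu_0, dispersion)
    lrt = max(0.0, 2.0 * (ll_alt - ll_null))
    p = float(scipy.stats.chi2.sf(lrt, df=1))
    return lrt, min(1.0, max(p, np.finfo(float).tiny))


def estimate_dispersion(
    values: np.ndarray,
    group_idx: Sequence[np.ndarray],
    lib_sizes: np.ndarray,
) -> float:
    """Pooled method-of-moments NB dispersion across genes.

    Counts are scaled to a common depth; per gene the within-group moment
    estimate (var - mean) / mean^2 is formed and the estimates are pooled by
    their mean.  The per-gene estimate is unbiased but right-skewed at small
    n, so the mean pools without the downward bias a median would introduce.
    Floored at 1e-8.
    """
    lib = np.asarray(lib_sizes, dtype=float)
    sf = lib / lib.mean()
    z = values / sf  # depth-adjusted counts
    ests = []
    for idx in group_idx:
        if len(idx) < 2:
            continue
        sub = z[:, idx]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        ok = m > 0
        ests.append(((v[ok] - m[ok]) / m[ok] ** 2))
    if not ests:
        return 0.1
    allest = np.concatenate(ests)
    if allest.size == 0:
        return 1e-8
    return float(max(np.mean(allest), 1e-8))


# ---------------------------------------------------------------------------
# FDR / enrichment / correlation


def bh_fdr(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values in the input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def hypergeom_test(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric over-representation p-value, P[X >= k].

    ``k`` genes of a size-``K`` set appear in a size-``n`` query drawn from a
    universe of ``N`` genes.
    """
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise ValueError(f"inconsistent hypergeometric counts k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    return float(scipy.stats.hypergeom.sf(k - 1, N, K, n))


def spearman_corr(a: Sequence[float], b: Sequence[float]) -> float:
    """Spearman rank correlation with mid-ranks for ties.

    Raises on constant input, where the coefficient is undefined.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 2:
        raise ValueError("spearman_corr needs equal-length vectors of size >= 2")
    if np.unique(a).size < 2 or np.unique(b).size < 2:
        raise ValueError("spearman correlation undefined for a constant vector")
    ra = scipy.stats.rankdata(a)
    rb = scipy.stats.rankdata(b)
    return float(np.corrcoef(ra, rb)[0, 1])


# ---------------------------------------------------------------------------
# orchestration


def de_table(
    m: CountMatrix,
    groups: Mapping[str, str],
    method: Literal["wilcoxon", "nb_lrt"] = "nb_lrt",
    alpha: float = 0.05,
    disease_group: str | None = None,
    dispersion: float | None = None,
    min_cpm: float = 1.0,
    min_prop: float = 0.7,
) -> DETable:
    """Two-group differential expression over a count matrix.

    Low-expressed genes are dropped first; normalization is internal (TMM
    log-CPM for the Wilcoxon path, TMM-effective library offsets for the NB
    path).  ``disease_group`` fixes the sign convention (defaults to the
    lexicographically later group label).
    """
    labels = pd.Series([groups[c] for c in m.column_ids], index=m.column_ids)
    uniq = sorted(labels.unique())
    if len(uniq) != 2:
        raise ValueError(f"de_table requires exactly 2 groups; got {uniq}")
    if disease_group is None:
        disease_group = uniq[1]
    control_group = [g for g in uniq if g != disease_group][0]
    idx_d = np.flatnonzero((labels == disease_group).to_numpy())
    idx_c = np.flatnonzero((labels == control_group).to_numpy())
    if method == "nb_lrt" and (idx_d.size < 2 or idx_c.size < 2):
        raise ValueError("nb_lrt requires at least 2 columns per group")

    if m.n_genes == 0 or m.n_columns == 0:
        empty = pd.DataFrame(columns=["log2fc", "p", "q", "direction"])
        return DETable(empty, test=method)
    mf = filter_low_expressed(m, groups, min_cpm=min_cpm, min_prop=min_prop)
    if mf.n_genes == 0:
        empty = pd.DataFrame(columns=["log2fc", "p", "q", "direction"])
        return DETable(empty, test=method)

    factors = tmm_factors(mf)
    norm = log_cpm(mf, factors)
    lfc = norm.values[:, idx_d].mean(axis=1) - norm.values[:, idx_c].mean(axis=1)

    pvals = np.empty(mf.n_genes)
    if method == "wilcoxon":
        for i in range(mf.n_genes):
            _, pvals[i] = wilcoxon_rank_sum(
                norm.values[i, idx_d], norm.values[i, idx_c], mode="auto"
            )
    elif method == "nb_lrt":
        lib = mf.library_sizes() * factors
        offs = np.log(lib)
        if dispersion is None:
            dispersion = estimate_dispersion(mf.values, [idx_d, idx_c], lib)
        for i in range(mf.n_genes):
            _, pvals[i] = nb_lrt_test(
                mf.values[i, idx_d],
                mf.values[i, idx_c],
                offsets=np.concatenate([offs[idx_d], offs[idx_c]]),
                dispersion=dispersion,
            )
    else:
        raise ValueError(f"unknown DE method {method!r}")

    q = bh_fdr(pvals)
    table = pd.DataFrame(
        {
            "log2fc": lfc,
            "p": pvals,
            "q": q,
            "direction": np.sign(lfc).astype(int),
        },
        index=mf.gene_ids,
    )
    table.index.name = "gene"
    return DETable(table, test=method)
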