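"""Normalization and filtering shared by all modalities.

Between-sample normalization follows the trimmed-mean-of-M-values (TMM)
scheme of Robinson & Oshlack: per-column scaling factors are a doubly
trimmed, inverse-variance-weighted mean of gene-wise log ratios against a
reference column, so they correct for composition while library size handles
depth.  Low-expression filtering mirrors the filterByExpr rule (CPM above a
floor in at least a group-sized number of columns), and the high-abundance
filter removes panel genes (GFAP-like) that dominate total transcript counts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .io_formats import CountMatrix, SpatialTranscriptTable

__all__ = [
    "NormalizedMatrix",
    "filter_low_expressed",
    "tmm_factors",
    "log_cpm",
    "high_abundance_filter",
]


@dataclass
class NormalizedMatrix:
    """log2-CPM values with the normalization factors that produced them."""

    values: np.ndarray  # genes x columns, log2 CPM
    gene_ids: list[str]
    column_ids: list[str]
    norm_factors: np.ndarray
    prior_count: float

    def __post_init__(self) -> None:
        self.norm_factors = np.asarray(self.norm_factors, dtype=float)
        if np.any(self.norm_factors <= 0):
            raise ValueError("normalization factors must be positive")
        gm = float(np.exp(np.mean(np.log(self.norm_factors))))
        if abs(gm - 1.0) > 1e-9:
            raise ValueError(f"geometric mean of norm factors is {gm}, expected 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.column_ids)


def _cpm(values: np.ndarray) -> np.ndarray:
    lib = values.sum(axis=0).astype(float)
    lib = np.where(lib > 0, lib, 1.0)
    return values / lib * 1e6


def filter_low_expressed(
    m: CountMatrix,
    groups: Mapping[str, str],
    min_cpm: float = 1.0,
    min_prop: float = 0.7,
) -> CountMatrix:
    """Drop genes not expressed at ``min_cpm`` in enough columns.

    A gene is kept iff its CPM reaches ``min_cpm`` in at least
    ``ceil(min_prop * smallest group size)`` columns (any columns, as in the
    filterByExpr heuristic where the smallest group sets the sample floor).
    Gene order is preserved; filtering twice is a no-op.
    """
    labels = [groups[c] for c in m.column_ids]
    sizes = pd.Series(labels).value_counts()
    if len(sizes) < 2:
        raise ValueError("filter_low_expressed requires at least 2 groups")
    n_required = math.ceil(min_prop * int(sizes.min()))
    cpm = _cpm(m.values)
    keep = (cpm >= min_cpm).sum(axis=1) >= n_required
    if not keep.any():
        warnings.warn("filter_low_expressed removed every gene", stacklevel=2)
    kept_genes = [g for g, k in zip(m.gene_ids, keep) if k]
    return CountMatrix(m.values[keep], kept_genes, m.column_ids, m.column_meta)


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    logratio_trim: float,
    sum_trim: float,
    a_cutoff: float,
) -> float:
    """Robinson-Oshlack TMM factor of one column against the reference."""
    pos = (obs > 0) & (ref > 0)
    obs = obs[pos].astype(float)
    ref = ref[pos].astype(float)
    if obs.size == 0:
        warnings.warn("no genes positive in both columns; TMM factor set to 1", stacklevel=3)
        return 1.0
    p_obs = obs / lib_obs
    p_ref = ref / lib_ref
    M = np.log2(p_obs / p_ref)
    A = 0.5 * np.log2(p_obs * p_ref)
    # asymptotic (delta-method) variance of M
    w = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    fin = np.isfinite(M) & np.isfinite(A) & (A > a_cutoff)
    M, A, w = M[fin], A[fin], w[fin]
    n = M.size
    if n == 0:
        warnings.warn("no genes survive TMM trimming; factor set to 1", stacklevel=3)
        return 1.0
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = pd.Series(M).rank().to_numpy()
    rank_a = pd.Series(A).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        warnings.warn("no genes survive TMM trimming; factor set to 1", stacklevel=3)
        return 1.0
    f = np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def tmm_factors(
    m: CountMatrix,
    ref_column: str | None = None,
    logratio_trim: float = 0.30,
    sum_trim: float = 0.05,
    a_cutoff: float = -1e10,
) -> np.ndarray:
    """Per-column TMM normalization factors with geometric mean 1.

    The reference defaults to the column whose upper-quartile count rate is
    closest to the mean upper-quartile across columns.
    """
    values = m.values
    lib = values.sum(axis=0).astype(float)
    if np.any(lib <= 0):
        bad = m.column_ids[int(np.argmin(lib))]
        raise ValueError(f"column {bad} has non-positive total count")
    if ref_column is None:
        uq = np.quantile(values / lib, 0.75, axis=0)
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref_idx = m.column_ids.index(ref_column)
    factors = np.ones(m.n_columns)
    for j in range(m.n_columns):
        if j == ref_idx:
            continue
        factors[j] = _tmm_pair(
            values[:, j], values[:, ref_idx], lib[j], lib[ref_idx],
            logratio_trim, sum_trim, a_cutoff,
        )
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def log_cpm(
    m: CountMatrix,
    factors: np.ndarray | None = None,
    prior_count: float = 0.5,
) -> NormalizedMatrix:
    """log2 counts-per-million on TMM-effective library sizes.

    value = log2((count + prior) / ((lib * factor + 2 * prior) / 1e6)).
    """
    if prior_count <= 0:
        raise ValueError("prior_count must be positive")
    if factors is None:
        factors = np.ones(m.n_columns)
    factors = np.asarray(factors, dtype=float)
    if factors.shape != (m.n_columns,):
        raise ValueError("one factor per column required")
    if np.any(factors <= 0):
        raise ValueError("factors must be positive")
    eff_lib = m.library_sizes() * factors
    vals = np.log2((m.values + prior_count) / ((eff_lib + 2 * prior_count) / 1e6))
    return NormalizedMatrix(vals, list(m.gene_ids), list(m.column_ids), factors, prior_count)


def high_abundance_filter(
    data: SpatialTranscriptTable | CountMatrix,
    max_fraction: float = 0.40,
) -> tuple[SpatialTranscriptTable | CountMatrix, pd.DataFrame]:
    """Remove genes whose share of all transcripts exceeds ``max_fraction``.

    Motivated by ubiquitously dominant panel genes (a GFAP-like species can
    account for half or more of detected transcripts and swamp per-cell
    profiles).  Returns the filtered dataset and a report frame with columns
    ``gene`` and ``fraction`` for every removed gene.
    """
    if isinstance(data, SpatialTranscriptTable):
        counts = data.genes.value_counts()
        total = float(counts.sum())
        frac = counts / total if total > 0 else counts.astype(float)
        removed = frac[frac > max_fraction]
        keep_rows = ~data.genes.isin(removed.index)
        out: SpatialTranscriptTable | CountMatrix = SpatialTranscriptTable(
            data.data.loc[keep_rows].reset_index(drop=True),
            pixel_size_um=data.pixel_size_um,
        )
    elif isinstance(data, CountMatrix):
        totals = data.values.sum(axis=1).astype(float)
        grand = totals.sum()
        frac_arr = totals / grand if grand > 0 else totals
        removed_mask = frac_arr > max_fraction
        removed = pd.Series(frac_arr[removed_mask],
                            index=[g for g, r in zip(data.gene_ids, removed_mask) if r])
        keep = [g for g, r in zip(data.gene_ids, removed_mask) if not r]
        out = data.subset_genes(keep)
    else:
        raise TypeError(f"unsupported input type {type(data)!r}")
    report = pd.DataFrame(
        {"gene": removed.index.to_list(), "fraction": removed.to_list()}
    ).sort_values("fraction", ascending=False, ignore_index=True)
    return out, report
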