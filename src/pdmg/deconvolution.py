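"""Bulk deconvolution against a multi-donor single-cell reference.

The estimator is a single-pass, cross-donor-variance-weighted non-negative
least squares: cell-type basis vectors are pooled relative expression
profiles scaled by mean per-cell library size, and each gene is weighted by
the inverse of its cross-donor variance (plus a floor), so genes whose type
profiles are unstable across donors contribute less.  This retains the
weighting principle of multi-subject deconvolution while staying
deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.optimize

from .io_formats import CountMatrix

__all__ = [
    "DeconvReference",
    "DeconvResult",
    "build_reference",
    "deconvolve",
    "class_average_proportions",
]


@dataclass
class DeconvReference:
    """Per-type reference profiles with cross-donor variability."""

    genes: list[str]
    cell_types: list[str]
    pooled_profiles: pd.DataFrame     # genes x types, rows of relative expression
    donor_profiles: dict[str, pd.DataFrame]  # type -> genes x donors
    cross_donor_var: pd.DataFrame     # genes x types
    mean_lib_size: pd.Series          # per type, mean per-cell total count

    def __post_init__(self) -> None:
        sums = self.pooled_profiles.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("pooled type profiles must each sum to 1")
        if (self.cross_donor_var.to_numpy() < 0).any():
            raise ValueError("cross-donor variances must be non-negative")


@dataclass
class DeconvResult:
    proportions: pd.Series  # per cell type, sums to 1
    residual_norm: float

    def __post_init__(self) -> None:
        p = self.proportions.to_numpy(dtype=float)
        if (p < -1e-12).any():
            raise ValueError("proportions must be non-negative")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")


def build_reference(sn: CountMatrix, meta: pd.DataFrame) -> DeconvReference:
    """Summarize a single-nucleus count matrix into deconvolution profiles.

    ``meta`` must carry ``donor`` and ``cell_type`` per cell (indexed by cell
    id).  Per (donor, type) the cells are summed and normalized to a relative
    profile; the pooled profile is the across-donor mean re-normalized to sum
    one, and the cross-donor variance is taken per gene.
    """
    for col in ("donor", "cell_type"):
        if col not in meta.columns:
            raise ValueError(f"cell metadata must contain a '{col}' column")
    meta = meta.loc[sn.column_ids]
    donors = sorted(meta["donor"].astype(str).unique())
    if len(donors) < 2:
        raise ValueError("build_reference requires at least 2 donors")
    types = sorted(meta["cell_type"].astype(str).unique())
    genes = list(sn.gene_ids)

    donor_profiles: dict[str, pd.DataFrame] = {}
    pooled = {}
    var = {}
    mean_lib = {}
    counts = sn.to_frame()
    totals = counts.sum(axis=0)
    for t in types:
        cols = {}
        for d in donors:
            cells = meta.index[(meta["cell_type"] == t) & (meta["donor"].astype(str) == d)]
            if len(cells) == 0:
                continue
            summed = counts[cells].sum(axis=1).astype(float)
            s = summed.sum()
            cols[d] = summed / s if s > 0 else summed
        prof = pd.DataFrame(cols, index=genes)
        if prof.shape[1] < 2:
            warnings.warn(
                f"cell type '{t}' observed in a single donor; cross-donor variance is 0",
                stacklevel=2,
            )
        donor_profiles[t] = prof
        mean_prof = prof.mean(axis=1)
        pooled[t] = mean_prof / mean_prof.sum()
        var[t] = prof.var(axis=1, ddof=1) if prof.shape[1] >= 2 else prof.iloc[:, 0] * 0.0
        type_cells = meta.index[meta["cell_type"] == t]
        mean_lib[t] = float(totals[type_cells].mean())
    return DeconvReference(
        genes=genes,
        cell_types=types,
        pooled_profiles=pd.DataFrame(pooled, index=genes),
        donor_profiles=donor_profiles,
        cross_donor_var=pd.DataFrame(var, index=genes),
        mean_lib_size=pd.Series(mean_lib),
    )


def deconvolve(
    bulk_column: Mapping[str, float] | pd.Series,
    ref: DeconvReference,
    eps: float = 1e-8,
) -> DeconvResult:
    """Estimate cell-type proportions underlying one bulk profile.

    Solves min ||W^(1/2) (b - M p')|| with p' >= 0, where b is the bulk
    relative profile on the shared genes, M's columns are pooled type
    profiles scaled by mean per-cell library size, and W is the inverse
    cross-donor variance (floored by ``eps``); p' is normalized to
    proportions.  Scale-invariant in the bulk column.
    """
    bulk = pd.Series(bulk_column, dtype=float)
    shared = [g for g in ref.genes if g in bulk.index]
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} genes shared with the reference (need >= 10)")
    b = bulk[shared].to_numpy()
    if b.sum() <= 0:
        raise ValueError("bulk profile is all zero")
    b = b / b.sum()
    M = (ref.pooled_profiles.loc[shared] * ref.mean_lib_size).to_numpy()
    v = ref.cross_donor_var.loc[shared].mean(axis=1).to_numpy()
    w = 1.0 / (v + eps)
    sw = np.sqrt(w)[:, None]
    x, _ = scipy.optimize.nnls(M * sw, b * sw[:, 0])
    total = x.sum()
    if total <= 0:
        raise ValueError("NNLS returned an all-zero solution")
    resid = float(np.linalg.norm((b - M @ x) * sw[:, 0]))
    props = pd.Series(x / total, index=ref.cell_types)
    return DeconvResult(proportions=props, residual_norm=resid)


def class_average_proportions(
    results: Sequence[DeconvResult] | Sequence[pd.Series],
    class_labels: Sequence[str],
) -> pd.DataFrame:
    """Arithmetic per-class mean of per-sample proportions, no renormalization.

    This is the radar-chart convention: class values are simple averages of
    member proportions per cell type (reported percentages need not sum to
    100 when members' proportion vectors are reported on different gene
    supports; for complete vectors linearity preserves the unit sum).
    """
    if len(results) != len(class_labels):
        raise ValueError("one class label per result required")
    rows = [
        (r.proportions if isinstance(r, DeconvResult) else pd.Series(r, dtype=float))
        for r in results
    ]
    df = pd.DataFrame(rows)
    df["__class"] = list(class_labels)
    return df.groupby("__class").mean()
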