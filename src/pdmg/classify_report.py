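"""Consensus / non-consensus classification and class-level summaries.

A disease-brain microglial cell is a *consensus* cell when its per-gene
deviations from the healthy microglial reference agree in sign with the
cross-modality signature for at least a fraction ``tau`` of the evaluable
signature genes (default 1.0: every gene must follow the signature).  Cells
from control donors are the healthy class and are never classified.

Class summaries mirror the panel figure conventions: per-gene distribution
percentages of average expression across the three classes, pairwise
Wilcoxon differential expression, and presence/absence categories.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import deconvolution, io_formats, signature as signature_mod, spatial as spatial_mod
from .io_formats import ConsensusSignature
from .preprocess import high_abundance_filter
from .spatial import CellTable, log_normalize_cells
from .stats import DETable, bh_fdr, de_table, wilcoxon_rank_sum
from .synthetic_data import (
    MARKER_GENES,
    gen_bulk_counts,
    gen_sn_counts,
    gen_spatial,
    make_gene_sets,
    make_truth,
)

__all__ = [
    "healthy_reference",
    "classify_consensus",
    "distribution_percentage",
    "class_specific_genes",
    "class_de",
    "build_class_summary",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

CLASSES = ["healthy", "consensus", "non-consensus"]


def healthy_reference(
    microglia: CellTable,
    conditions: pd.Series,
    stat: str = "mean",
) -> pd.Series:
    """Per-gene mean (or median) log-normalized expression of control microglia."""
    ctrl = conditions.index[conditions == "control"]
    ctrl = [c for c in ctrl if c in microglia.counts.index]
    if not ctrl:
        raise ValueError("no control-donor microglia to build the healthy reference")
    lognorm = log_normalize_cells(microglia.counts.loc[ctrl])
    return lognorm.median(axis=0) if stat == "median" else lognorm.mean(axis=0)


def classify_consensus(
    microglia: CellTable,
    sig: ConsensusSignature,
    healthy_ref: pd.Series,
    conditions: pd.Series | None = None,
    tau: float = 1.0,
    epsilon: float = 0.0,
) -> pd.Series:
    """Classify disease microglia as consensus vs non-consensus.

    For each disease cell and each panel-resident signature gene g the
    deviation d_g = lognorm expression - healthy_ref[g] *agrees* with the
    signature iff sign(d_g) == direction(g) and |d_g| > epsilon.  The cell is
    consensus iff the agreement fraction over evaluable genes reaches
    ``tau``.  Control cells (when ``conditions`` is given) are labeled
    "healthy".  Stores and returns ``meta['class']``.
    """
    if len(sig) == 0:
        raise ValueError("classification undefined for an empty signature")
    genes = [e.gene for e in sig.entries if e.gene in microglia.counts.columns]
    if not genes:
        raise ValueError("no signature gene is present on the panel")
    dirs = np.array([sig.directions()[g] for g in genes])
    lognorm = log_normalize_cells(microglia.counts)
    dev = lognorm[genes].to_numpy() - healthy_ref[genes].to_numpy()
    agree = (np.sign(dev) == dirs) & (np.abs(dev) > epsilon)
    n_eval = len(genes)
    concordance = agree.sum(axis=1) / n_eval
    cls = np.where(concordance >= tau, "consensus", "non-consensus")
    out = pd.Series(cls, index=microglia.counts.index, name="class")
    if conditions is not None:
        is_ctrl = conditions.reindex(out.index) == "control"
        out[is_ctrl] = "healthy"
    microglia.meta["class"] = out
    microglia.meta["concordance"] = concordance
    return out


def distribution_percentage(class_means: pd.DataFrame) -> pd.DataFrame:
    """Per-gene share (in %) of each class in the summed class averages.

    ``class_means``: genes x classes of non-negative average expression.
    Rows whose class means are all zero are undefined and returned as NaN
    with the ``defined`` flag False.
    """
    if (class_means.to_numpy() < 0).any():
        raise ValueError("class means must be non-negative")
    total = class_means.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = class_means.div(total, axis=0) * 100.0
    pct[total == 0] = np.nan
    pct["defined"] = total > 0
    return pct


def class_mean_expression(ct: CellTable, classes: pd.Series) -> pd.DataFrame:
    """Per-gene class averages on the natural scale (expm1 of log-normalized)."""
    lognorm = log_normalize_cells(ct.counts)
    natural = 2.0**lognorm - 1.0
    out = {}
    for c in classes.unique():
        cells = classes.index[classes == c]
        out[c] = natural.loc[cells].mean(axis=0)
    return pd.DataFrame(out)


def class_specific_genes(
    ct: CellTable,
    classes: pd.Series,
    min_cells: int = 2,
    min_frac: float = 0.01,
) -> pd.DataFrame:
    """Presence flags and presence-pattern categories per gene.

    A gene is *expressed* in a class iff detected (count > 0) in at least
    max(min_cells, ceil(min_frac * class size)) of its cells.  Categories:
    ``none`` (expressed nowhere), ``class-specific`` (exactly one class),
    ``class-absent`` (missing from exactly one class), ``all-classes``.
    Pass ``classes`` as a Categorical to declare the expected classes; a
    declared class with no cells is an error.
    """
    if isinstance(classes.dtype, pd.CategoricalDtype):
        labels = list(classes.cat.categories)
    else:
        labels = list(classes.unique())
    present = {}
    for c in labels:
        cells = classes.index[classes == c]
        if len(cells) == 0:
            raise ValueError(f"class {c!r} has no cells")
        thr = max(min_cells, int(np.ceil(min_frac * len(cells))))
        present[c] = (ct.counts.loc[cells] > 0).sum(axis=0) >= thr
    flags = pd.DataFrame(present)
    n_present = flags.sum(axis=1)
    n_classes = flags.shape[1]
    category = pd.Series("all-classes", index=flags.index)
    category[n_present == 0] = "none"
    category[n_present == 1] = "class-specific"
    category[(n_present == n_classes - 1) & (n_classes > 2)] = "class-absent"
    flags["category"] = category
    specific_in = flags.columns[:n_classes][np.argmax(flags.iloc[:, :n_classes].to_numpy(), axis=1)]
    flags["specific_class"] = np.where(category == "class-specific", specific_in, "")
    absent_from = flags.columns[:n_classes][np.argmin(flags.iloc[:, :n_classes].to_numpy(), axis=1)]
    flags["absent_class"] = np.where(category == "class-absent", absent_from, "")
    return flags


def class_de(ct: CellTable, classes: pd.Series) -> dict[tuple[str, str], DETable]:
    """Pairwise Wilcoxon DE between classes on log-normalized expression."""
    lognorm = log_normalize_cells(ct.counts)
    labels = sorted(classes.unique())
    out: dict[tuple[str, str], DETable] = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            ca = classes.index[classes == a]
            cb = classes.index[classes == b]
            if len(ca) < 2 or len(cb) < 2:
                raise ValueError(f"classes {a!r} vs {b!r} need >= 2 cells each")
            p = np.empty(lognorm.shape[1])
            lfc = np.empty(lognorm.shape[1])
            for j, g in enumerate(lognorm.columns):
                xa = lognorm.loc[ca, g].to_numpy()
                xb = lognorm.loc[cb, g].to_numpy()
                _, p[j] = wilcoxon_rank_sum(xa, xb, mode="auto")
                lfc[j] = xa.mean() - xb.mean()
            tab = pd.DataFrame(
                {"log2fc": lfc, "p": p, "q": bh_fdr(p),
                 "direction": np.sign(lfc).astype(int)},
                index=lognorm.columns,
            )
            tab.index.name = "gene"
            out[(a, b)] = DETable(tab, test="wilcoxon")
    return out


def build_class_summary(ct: CellTable, classes: pd.Series, alpha: float = 0.05) -> pd.DataFrame:
    """Combined per-gene class summary: distribution %, presence, DE category."""
    means = class_mean_expression(ct, classes)
    pct = distribution_percentage(means)
    flags = class_specific_genes(ct, classes)
    de = class_de(ct, classes)
    summary = pct.rename(columns={c: f"pct_{c}" for c in means.columns})
    for (a, b), tab in de.items():
        summary[f"q_{a}_vs_{b}"] = tab.table["q"]
    summary["category"] = flags["category"]
    # refine the all-present pattern with the DE calls
    if {"healthy", "consensus", "non-consensus"}.issubset(set(classes.unique())):
        qch = de[("consensus", "healthy")].table
        qcn = de[("consensus", "non-consensus")].table
        qhn = de[("healthy", "non-consensus")].table
        cons_up = (
            (qch["q"] < alpha) & (qch["direction"] > 0)
            & (qcn["q"] < alpha) & (qcn["direction"] > 0)
        )
        noncons_down = (
            (qhn["q"] < alpha) & (qhn["direction"] > 0)
            & (qcn["q"] < alpha) & (qcn["direction"] < 0)
        )
        allp = summary["category"] == "all-classes"
        summary.loc[allp & cons_up, "category"] = "consensus-enriched"
        summary.loc[allp & noncons_down & ~cons_up, "category"] = "non-consensus-depleted"
    return summary


# ---------------------------------------------------------------------------
# pipeline


DEFAULT_SIM_CONFIG: dict = {
    "truth": {"n_signature": 10, "seed": 0},
    "bulk": {"n_per_group": 6, "depth": 1e6},
    "sn": {"donors_per_group": 3, "cells_per_donor": 150},
    "spatial": {"n_cells": 400, "field": [512, 512]},
    "sets": {"n_sets": 50, "n_signature_sets": 2, "set_size": 20},
    "alpha": 0.05,
    "tau": 1.0,
    "epsilon": 0.0,
}


def _merge(base: Mapping, override: Mapping) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), Mapping):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def run_pipeline(
    config: Mapping | None = None,
    out_dir: str | Path = "pdmg_run",
    simulate: bool = True,
    seed: int | None = None,
) -> dict:
    """End-to-end synthetic run: simulate, DE, signature, deconvolve, classify.

    Writes de_bulk.tsv, de_sn.tsv, signature.json, props.csv, cells.csv,
    class_summary.tsv, report.json and pipeline.log into ``out_dir`` and
    returns the report dict.  Deterministic given the config seed.
    """
    if not simulate:
        raise NotImplementedError(
            "only the simulation-driven pipeline is wired; pass simulate=True"
        )
    cfg = _merge(DEFAULT_SIM_CONFIG, config or {})
    if seed is not None:
        cfg["truth"]["seed"] = int(seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        import numpy as _np
        import pandas as _pd

        logger.info("config: %s", json.dumps(cfg, sort_keys=True, default=str))
        logger.info("numpy %s / pandas %s", _np.__version__, _pd.__version__)
        truth = make_truth(cfg["truth"])
        logger.info("truth seed %d, %d signature genes", truth.seed,
                    len(truth.signature_genes))
        alpha = float(cfg["alpha"])

        # --- bulk modality
        bulk, bulk_groups = gen_bulk_counts(truth, **cfg["bulk"])
        de_bulk = de_table(bulk, bulk_groups, method="nb_lrt", alpha=alpha,
                           disease_group="disease")
        de_bulk.table.to_csv(out / "de_bulk.tsv", sep="\t")

        # --- single-nucleus modality (DE on microglia only)
        sn, sn_meta = gen_sn_counts(truth, **cfg["sn"])
        mg_cells = sn_meta.index[sn_meta["cell_type"] == "microglia"]
        sn_mg = sn.subset_columns(list(mg_cells))
        sn_groups = sn_meta.loc[mg_cells, "condition"].to_dict()
        de_sn = de_table(sn_mg, sn_groups, method="wilcoxon", alpha=alpha,
                         disease_group="disease", min_prop=0.1)
        de_sn.table.to_csv(out / "de_sn.tsv", sep="\t")

        # --- consensus signature
        sets = make_gene_sets(truth, **cfg["sets"])
        sig = signature_mod.build_consensus_signature(
            de_bulk, de_sn, sets, universe=truth.gene_universe, alpha=alpha
        )
        io_formats.write_signature(sig, out / "signature.json")
        logger.info("signature: %d genes, %d conflicts", len(sig), len(sig.conflicts))

        # --- deconvolution of bulk samples against the sn reference
        ref = deconvolution.build_reference(sn, sn_meta)
        props = {}
        bulk_frame = bulk.to_frame()
        for col in bulk.column_ids:
            props[col] = deconvolution.deconvolve(bulk_frame[col], ref).proportions
        props_df = pd.DataFrame(props).T
        props_df.index.name = "sample"
        props_df.to_csv(out / "props.csv")
        class_props = deconvolution.class_average_proportions(
            [props_df.loc[c] for c in bulk.column_ids],
            [bulk_groups[c] for c in bulk.column_ids],
        )

        # --- spatial modality
        transcripts, mask, cell_truth = gen_spatial(truth, **cfg["spatial"])
        filtered, removed = high_abundance_filter(transcripts)
        ct = spatial_mod.assign_transcripts(filtered, mask)
        spatial_mod.cluster_cells(ct, seed=truth.seed)
        marker_sets = [io_formats.GeneSet(name=t, members=m)
                       for t, m in MARKER_GENES.items()]
        spatial_mod.annotate_clusters(ct, marker_sets)
        ct.meta["condition"] = cell_truth["condition"].reindex(ct.counts.index)

        mg_idx = ct.meta.index[ct.meta["cell_type"] == "microglia"]
        mg = CellTable(
            counts=ct.counts.loc[mg_idx],
            meta=ct.meta.loc[mg_idx].copy(),
            genes=ct.genes,
        )
        conditions = mg.meta["condition"]
        ref_expr = healthy_reference(mg, conditions)
        classes = classify_consensus(
            mg, sig, ref_expr, conditions=conditions,
            tau=float(cfg["tau"]), epsilon=float(cfg["epsilon"]),
        )
        ct.meta["class"] = classes.reindex(ct.meta.index).fillna("NA")
        cells_out = pd.concat([ct.meta, ct.counts], axis=1)
        cells_out.to_csv(out / "cells.csv")

        summary = build_class_summary(mg, classes, alpha=alpha)
        summary.to_csv(out / "class_summary.tsv", sep="\t")

        n_pd = int((classes != "healthy").sum())
        n_cons = int((classes == "consensus").sum())
        truth_dirs = dict(truth.signature_genes)
        recovered = set(sig.genes)
        planted = set(truth_dirs)
        jacc = (
            len(recovered & planted) / len(recovered | planted)
            if recovered | planted
            else 1.0
        )
        report = {
            "seed": truth.seed,
            "n_cells_spatial": int(ct.n_cells),
            "n_microglia": int(len(mg_idx)),
            "n_pd_microglia": n_pd,
            "n_consensus": n_cons,
            "n_non_consensus": int(n_pd - n_cons),
            "consensus_percentage": (100.0 * n_cons / n_pd) if n_pd else None,
            "signature_size": len(sig),
            "signature_jaccard_vs_truth": jacc,
            "direction_conflicts": sig.conflicts,
            "removed_dominant_genes": removed.to_dict("records"),
            "unassigned_transcripts": int(ct.unassigned),
            "class_average_proportions": {
                str(k): {t: float(v) for t, v in row.items()}
                for k, row in class_props.iterrows()
            },
        }
        (out / "report.json").write_text(
            json.dumps(report, indent=1, sort_keys=True) + "\n"
        )
        logger.info("report written: %d/%d consensus", n_cons, n_pd)
        return report
    finally:
        logger.removeHandler(handler)
        handler.close()
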