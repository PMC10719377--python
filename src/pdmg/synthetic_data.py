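"""Synthetic multi-modal data with known planted structure.

Three generators emulate the three modalities the pipeline consumes:

* :func:`gen_bulk_counts` — negative-binomial bulk RNA-seq counts for a
  mutant-vs-isogenic two-group design with a planted directional microglial
  disease signature;
* :func:`gen_sn_counts` — multi-donor single-nucleus counts over five brain
  cell types, where disease-donor microglia carry the same signature;
* :func:`gen_spatial` — a 100-gene spatial panel over a field of
  non-overlapping disc "cells" with a segmentation label mask, a dominant
  ubiquitous GFAP-like gene emitted both inside cells and as background, and
  a planted consensus subpopulation among disease microglia whose
  signature-gene means are shifted in the signature directions.

All planted parameters live in :class:`SimTruth`, so every downstream stage
can be verified by parameter recovery.  Every generator is deterministic
given the truth and a seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import CountMatrix, GeneSet, LabelMask, SpatialTranscriptTable

__all__ = [
    "SimTruth",
    "ConfigError",
    "make_truth",
    "make_gene_sets",
    "gen_bulk_counts",
    "gen_sn_counts",
    "gen_spatial",
    "MARKER_GENES",
    "DEFAULT_CELL_TYPE_PROPS",
]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


# canonical marker genes carried on the spatial panel, one family per type
MARKER_GENES: dict[str, list[str]] = {
    "microglia": ["TMEM119", "P2RY12", "MERTK", "CX3CR1"],
    "astrocyte": ["AQP4", "SLC1A2", "GJA1"],
    "neuron": ["RBFOX3", "SYT1", "SNAP25"],
    "oligodendrocyte": ["PLP1", "MBP", "MOG"],
    "endothelial": ["CLDN5", "PECAM1", "FLT1"],
}

DEFAULT_CELL_TYPE_PROPS: dict[str, float] = {
    "microglia": 0.3,
    "astrocyte": 0.2,
    "neuron": 0.2,
    "oligodendrocyte": 0.2,
    "endothelial": 0.1,
}


@dataclass
class SimTruth:
    """Planted ground truth shared by the three generators."""

    signature_genes: list[tuple[str, int]]
    sig_log2fc: float
    cell_type_props: dict[str, float]
    consensus_fraction: float
    nb_dispersion: float
    dominant_gene: str
    dominant_fraction: float
    seed: int
    gene_universe: list[str] = field(default_factory=list)
    # spatial-specific planted parameters
    panel_size: int = 100
    spatial_log2fc: float = 2.5
    spatial_sig_mean: float = 10.0

    def __post_init__(self) -> None:
        total = sum(self.cell_type_props.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"cell_type_props sum to {total}, expected 1")
        if any(v < 0 for v in self.cell_type_props.values()):
            raise ConfigError("cell_type_props must be non-negative")
        if not 0.0 <= self.consensus_fraction <= 1.0:
            raise ConfigError("consensus_fraction must lie in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ConfigError("nb_dispersion must be positive")
        if not 0.0 <= self.dominant_fraction < 1.0:
            raise ConfigError("dominant_fraction must lie in [0, 1)")
        universe = set(self.gene_universe)
        for g, d in self.signature_genes:
            if d not in (+1, -1):
                raise ConfigError(f"signature direction for {g} must be +1 or -1")
            if g not in universe:
                raise ConfigError(f"signature gene {g} not in the gene universe")
        if self.dominant_gene not in universe:
            raise ConfigError(f"dominant gene {self.dominant_gene} not in the universe")

    @property
    def signature_directions(self) -> dict[str, int]:
        return dict(self.signature_genes)

    @property
    def cell_types(self) -> list[str]:
        return list(self.cell_type_props)

    def to_json(self, path: str | Path) -> None:
        obj = dataclasses.asdict(self)
        obj["signature_genes"] = [[g, d] for g, d in self.signature_genes]
        Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        obj = json.loads(Path(path).read_text())
        obj["signature_genes"] = [(g, int(d)) for g, d in obj["signature_genes"]]
        return cls(**obj)


def make_truth(config: Mapping | None = None) -> SimTruth:
    """Draw a reproducible :class:`SimTruth` from a configuration mapping.

    Recognized keys (with defaults): ``n_genes`` (2000 generic genes besides
    the named marker/dominant genes), ``n_signature`` (40), ``sig_log2fc``
    (1.0), ``cell_type_props``, ``consensus_fraction`` (0.054, the observed
    share of consensus cells among disease microglia), ``nb_dispersion``
    (0.1), ``dominant_gene`` ("GFAP"), ``dominant_fraction`` (0.6, within the
    observed 0.49-0.89 range), ``panel_size`` (100), ``spatial_log2fc``
    (2.5), ``spatial_sig_mean`` (10.0), ``seed`` (0).  Signature genes are
    drawn without replacement from the generic pool with Bernoulli(0.5)
    directions.
    """
    cfg = dict(config or {})
    n_genes = int(cfg.pop("n_genes", 2000))
    n_signature = int(cfg.pop("n_signature", 40))
    sig_log2fc = float(cfg.pop("sig_log2fc", 1.0))
    props = dict(cfg.pop("cell_type_props", DEFAULT_CELL_TYPE_PROPS))
    consensus_fraction = float(cfg.pop("consensus_fraction", 0.054))
    nb_dispersion = float(cfg.pop("nb_dispersion", 0.1))
    dominant_gene = str(cfg.pop("dominant_gene", "GFAP"))
    dominant_fraction = float(cfg.pop("dominant_fraction", 0.6))
    panel_size = int(cfg.pop("panel_size", 100))
    spatial_log2fc = float(cfg.pop("spatial_log2fc", 2.5))
    spatial_sig_mean = float(cfg.pop("spatial_sig_mean", 10.0))
    seed = int(cfg.pop("seed", 0))
    if cfg:
        raise ConfigError(f"unknown simulation config keys: {sorted(cfg)}")

    generic = [f"G{i:04d}" for i in range(1, n_genes + 1)]
    named = [dominant_gene] + [g for ms in MARKER_GENES.values() for g in ms]
    universe = named + generic
    if n_signature > n_genes:
        raise ConfigError(
            f"signature size {n_signature} exceeds the generic gene pool ({n_genes})"
        )
    if panel_size > len(universe):
        raise ConfigError("panel size exceeds the gene universe")
    rng = np.random.default_rng(seed)
    sig_idx = rng.choice(n_genes, size=n_signature, replace=False)
    directions = rng.integers(0, 2, size=n_signature) * 2 - 1
    signature = [(generic[i], int(d)) for i, d in zip(sorted(sig_idx), directions)]
    return SimTruth(
        signature_genes=signature,
        sig_log2fc=sig_log2fc,
        cell_type_props=props,
        consensus_fraction=consensus_fraction,
        nb_dispersion=nb_dispersion,
        dominant_gene=dominant_gene,
        dominant_fraction=dominant_fraction,
        seed=seed,
        gene_universe=universe,
        panel_size=panel_size,
        spatial_log2fc=spatial_log2fc,
        spatial_sig_mean=spatial_sig_mean,
    )


def make_gene_sets(
    truth: SimTruth,
    n_sets: int = 50,
    n_signature_sets: int = 5,
    set_size: int = 20,
    seed: int | None = None,
) -> list[GeneSet]:
    """A synthetic gene-set collection with the signature planted in a few sets.

    Signature genes are spread round-robin over the first ``n_signature_sets``
    sets (padded with random non-signature genes up to ``set_size``); the
    remaining sets are random draws from the non-signature pool.
    """
    rng = np.random.default_rng(truth.seed + 101 if seed is None else seed)
    sig_genes = [g for g, _ in truth.signature_genes]
    pool = [g for g in truth.gene_universe if g not in set(sig_genes)]
    sets: list[GeneSet] = []
    buckets: list[list[str]] = [[] for _ in range(n_signature_sets)]
    for i, g in enumerate(sig_genes):
        buckets[i % n_signature_sets].append(g)
    for i, bucket in enumerate(buckets):
        pad = max(0, set_size - len(bucket))
        filler = list(rng.choice(len(pool), size=pad, replace=False))
        members = bucket + [pool[j] for j in filler]
        sets.append(GeneSet(name=f"SET{i + 1:03d}", members=members,
                            description="signature-bearing"))
    for i in range(n_signature_sets, n_sets):
        idx = rng.choice(len(pool), size=set_size, replace=False)
        sets.append(GeneSet(name=f"SET{i + 1:03d}", members=[pool[j] for j in idx],
                            description="background"))
    return sets


# ---------------------------------------------------------------------------
# shared helpers


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """Negative-binomial draws parameterized by mean and dispersion.

    var = mu + phi * mu^2; implemented as Poisson-Gamma mixture so phi -> 0
    recovers Poisson.
    """
    mean = np.asarray(mean, dtype=float)
    if phi < 1e-12:
        return rng.poisson(mean)
    shape = 1.0 / phi
    lam = rng.gamma(shape, scale=mean * phi)
    return rng.poisson(lam)


def _baseline_abundance(rng: np.random.Generator, n: int) -> np.ndarray:
    """Log-normal(meanlog 1, sdlog 1) baseline expression levels."""
    return rng.lognormal(mean=1.0, sigma=1.0, size=n)


def _largest_remainder(quotas: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment of ``total`` items proportional to ``quotas``."""
    counts = np.floor(quotas).astype(int)
    short = total - counts.sum()
    if short > 0:
        order = np.argsort(-(quotas - counts), kind="stable")
        counts[order[:short]] += 1
    return counts


# ---------------------------------------------------------------------------
# bulk


def gen_bulk_counts(
    truth: SimTruth,
    n_per_group: int = 6,
    depth: float = 1e6,
    seed: int | None = None,
) -> tuple[CountMatrix, dict[str, str]]:
    """Bulk NB counts for a mutant-vs-isogenic-control two-group design.

    Gene baselines are log-normal relative abundances; disease means are the
    control means times 2**(direction * sig_log2fc) on signature genes;
    library sizes vary around ``depth`` (Poisson).  Returns the count matrix
    and a column -> group ("disease"/"control") map.
    """
    if n_per_group < 2:
        raise ConfigError("n_per_group must be >= 2")
    if depth <= 0:
        raise ConfigError("depth must be positive")
    rng = np.random.default_rng(truth.seed + 11 if seed is None else seed)
    genes = truth.gene_universe
    q = _baseline_abundance(rng, len(genes))
    q = q / q.sum()
    fold = np.ones(len(genes))
    dirs = truth.signature_directions
    for i, g in enumerate(genes):
        if g in dirs:
            fold[i] = 2.0 ** (dirs[g] * truth.sig_log2fc)
    cols, labels, mat = [], {}, []
    for group, gene_fold in (("control", np.ones(len(genes))), ("disease", fold)):
        for r in range(n_per_group):
            lib = rng.poisson(depth)
            mean = q * gene_fold
            mean = mean / mean.sum() * lib  # library size is the depth handle
            counts = _nb_draw(rng, mean, truth.nb_dispersion)
            name = f"{group}_{r + 1}"
            cols.append(name)
            labels[name] = group
            mat.append(counts)
    values = np.column_stack(mat)
    meta = pd.DataFrame({"condition": [labels[c] for c in cols]}, index=cols)
    return CountMatrix(values, list(genes), cols, meta), labels


# ---------------------------------------------------------------------------
# single-nucleus


def gen_sn_counts(
    truth: SimTruth,
    donors_per_group: int = 5,
    cells_per_donor: int = 150,
    mean_counts_per_cell: float = 4000.0,
    donor_sd: float = 0.1,
    type_profile_sd: float = 0.5,
    marker_boost: float = 8.0,
    seed: int | None = None,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Multi-donor single-nucleus counts over the five brain cell types.

    Each cell draws a type from ``truth.cell_type_props`` and a donor; type
    profiles share a log-normal baseline modulated per (gene, type), with
    marker genes boosted in their own type; a per-donor log-normal random
    effect (sd ``donor_sd`` on the log scale, small enough that cell-level
    rank tests are not swamped by between-donor shifts) perturbs gene means.  Microglia
    of disease donors carry the planted signature shift.  Returns counts and
    metadata (cell_id, donor, condition, cell_type).
    """
    if donors_per_group < 2:
        raise ConfigError("donors_per_group must be >= 2")
    if len(truth.cell_type_props) < 2:
        raise ConfigError("need at least 2 cell types")
    rng = np.random.default_rng(truth.seed + 23 if seed is None else seed)
    genes = truth.gene_universe
    n_genes = len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    base = _baseline_abundance(rng, n_genes)
    types = truth.cell_types
    profiles = {}
    for t in types:
        mod = rng.lognormal(mean=0.0, sigma=type_profile_sd, size=n_genes)
        prof = base * mod
        for g in MARKER_GENES.get(t, []):
            if g in gene_pos:
                prof[gene_pos[g]] *= marker_boost
        profiles[t] = prof / prof.sum()
    sig_fold = np.ones(n_genes)
    for g, d in truth.signature_genes:
        sig_fold[gene_pos[g]] = 2.0 ** (d * truth.sig_log2fc)

    donors = [f"PD{i + 1}" for i in range(donors_per_group)] + [
        f"CTRL{i + 1}" for i in range(donors_per_group)
    ]
    conditions = {d: ("disease" if d.startswith("PD") else "control") for d in donors}
    donor_effect = {
        d: rng.lognormal(mean=0.0, sigma=donor_sd, size=n_genes) for d in donors
    }

    probs = np.array([truth.cell_type_props[t] for t in types])
    columns, rows, meta_rows = [], [], []
    cell_no = 0
    for d in donors:
        type_idx = rng.choice(len(types), size=cells_per_donor, p=probs)
        for ti in type_idx:
            t = types[ti]
            cell_no += 1
            mean = profiles[t] * donor_effect[d]
            if conditions[d] == "disease" and t == "microglia":
                mean = mean * sig_fold
            size = rng.lognormal(mean=0.0, sigma=0.3) * mean_counts_per_cell
            mean = mean / mean.sum() * size
            rows.append(_nb_draw(rng, mean, truth.nb_dispersion))
            cid = f"cell{cell_no:05d}"
            columns.append(cid)
            meta_rows.append((cid, d, conditions[d], t))
    meta = pd.DataFrame(
        meta_rows, columns=["cell_id", "donor", "condition", "cell_type"]
    ).set_index("cell_id")
    if not rows:
        values = np.zeros((n_genes, 0), dtype=np.int64)
    else:
        values = np.column_stack(rows)
    return CountMatrix(values, list(genes), columns, meta.loc[columns] if columns else meta), meta


# ---------------------------------------------------------------------------
# spatial


def spatial_panel(truth: SimTruth) -> list[str]:
    """The spatial gene panel: dominant gene, markers, signature genes that
    fit, then generic filler up to ``truth.panel_size`` genes."""
    panel = [truth.dominant_gene]
    for ms in MARKER_GENES.values():
        panel.extend(g for g in ms if g in set(truth.gene_universe))
    for g, _ in truth.signature_genes:
        if len(panel) >= truth.panel_size:
            break
        if g not in panel:
            panel.append(g)
    for g in truth.gene_universe:
        if len(panel) >= truth.panel_size:
            break
        if g not in panel:
            panel.append(g)
    return panel[: truth.panel_size]


def _place_discs(
    rng: np.random.Generator,
    n_cells: int,
    shape: tuple[int, int],
    radius: float,
    max_tries: int,
) -> np.ndarray:
    """Rejection-sample non-overlapping disc centers; (n, 2) as (x, y)."""
    h, w = shape
    margin = radius + 1.0
    if w - 2 * margin <= 0 or h - 2 * margin <= 0:
        raise ConfigError(f"field {shape} too small for discs of radius {radius}")
    centers = np.empty((n_cells, 2))
    min_d2 = (2 * radius + 1.0) ** 2
    # coarse grid for neighbor lookup
    cell_w = 2 * radius + 1.0
    grid: dict[tuple[int, int], list[int]] = {}
    placed = 0
    tries = 0
    while placed < n_cells:
        tries += 1
        if tries > max_tries:
            raise ConfigError(
                f"could not pack {n_cells} discs of radius {radius} into field {shape} "
                f"after {max_tries} tries"
            )
        x = rng.uniform(margin, w - margin)
        y = rng.uniform(margin, h - margin)
        gx, gy = int(x // cell_w), int(y // cell_w)
        ok = True
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for j in grid.get((gx + dx, gy + dy), []):
                    if (centers[j, 0] - x) ** 2 + (centers[j, 1] - y) ** 2 < min_d2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            centers[placed] = (x, y)
            grid.setdefault((gx, gy), []).append(placed)
            placed += 1
    return centers


def gen_spatial(
    truth: SimTruth,
    n_cells: int = 400,
    field: tuple[int, int] = (512, 512),
    radius: float = 8.0,
    pd_fraction: float = 0.5,
    n_pd_donors: int = 7,
    n_ctrl_donors: int = 8,
    base_mean: float = 0.3,
    marker_mean: float = 8.0,
    background_share: float = 0.5,
    cell_size_sd: float = 0.2,
    max_place_tries: int = 2_000_000,
    seed: int | None = None,
) -> tuple[SpatialTranscriptTable, LabelMask, pd.DataFrame]:
    """Simulate a spatial transcriptomics field of disc-shaped cells.

    Cells are non-overlapping discs of radius ``radius`` px; condition and
    cell type counts are apportioned deterministically (largest remainder) to
    ``pd_fraction`` and ``truth.cell_type_props``.  Per cell, panel-gene
    counts are NB draws from its type profile (markers boosted in their own
    type; signature genes expressed at ``truth.spatial_sig_mean`` in
    microglia), and transcript positions are uniform in the disc.  Among
    disease microglia, a ``truth.consensus_fraction`` share is planted as
    consensus with signature means shifted by 2**(direction *
    truth.spatial_log2fc).  The dominant gene is emitted partly inside cells
    and partly as uniform background so its overall share of transcripts
    equals ``truth.dominant_fraction``.

    Returns the transcript table, the label mask (labels 1..n_cells), and a
    ground-truth cell table (cell_id, x, y, donor, condition, cell_type,
    is_consensus).
    """
    if n_cells < 1:
        raise ConfigError("n_cells must be >= 1")
    rng = np.random.default_rng(truth.seed + 37 if seed is None else seed)
    h, w = field
    panel = spatial_panel(truth)
    panel_pos = {g: i for i, g in enumerate(panel)}
    types = truth.cell_types

    # deterministic condition x type apportionment
    conds = ["disease", "control"]
    cond_p = np.array([pd_fraction, 1.0 - pd_fraction])
    type_p = np.array([truth.cell_type_props[t] for t in types])
    quotas = np.outer(cond_p, type_p).ravel() * n_cells
    counts = _largest_remainder(quotas, n_cells)
    assign: list[tuple[str, str]] = []
    for (ci, ti), c in zip(
        [(i, j) for i in range(len(conds)) for j in range(len(types))], counts
    ):
        assign.extend([(conds[ci], types[ti])] * c)
    rng.shuffle(assign)  # type: ignore[arg-type]

    centers = _place_discs(rng, n_cells, (h, w), radius, max_place_tries)

    # label mask: rasterize discs (pixel centers within radius of disc center)
    mask = np.zeros((h, w), dtype=np.int64)
    rr = int(np.ceil(radius))
    for k, (cx, cy) in enumerate(centers, start=1):
        y0, y1 = max(0, int(cy) - rr - 1), min(h, int(cy) + rr + 2)
        x0, x1 = max(0, int(cx) - rr - 1), min(w, int(cx) + rr + 2)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        inside = (xx + 0.5 - cx) ** 2 + (yy + 0.5 - cy) ** 2 <= radius**2
        mask[y0:y1, x0:x1][inside] = k

    # type profiles over the panel (dominant gene handled separately)
    profiles = {}
    for t in types:
        prof = np.full(len(panel), base_mean)
        for tt, ms in MARKER_GENES.items():
            for g in ms:
                if g in panel_pos:
                    prof[panel_pos[g]] = marker_mean if tt == t else base_mean
        if t == "microglia":
            for g, _ in truth.signature_genes:
                if g in panel_pos:
                    prof[panel_pos[g]] = truth.spatial_sig_mean
        prof[panel_pos[truth.dominant_gene]] = 0.0
        profiles[t] = prof
    sig_shift = np.ones(len(panel))
    for g, d in truth.signature_genes:
        if g in panel_pos:
            sig_shift[panel_pos[g]] = 2.0 ** (d * truth.spatial_log2fc)

    # plant the consensus subset among disease microglia
    pd_mg = [i for i, (c, t) in enumerate(assign) if c == "disease" and t == "microglia"]
    n_cons = int(round(truth.consensus_fraction * len(pd_mg)))
    cons_cells = set(
        rng.choice(pd_mg, size=n_cons, replace=False).tolist() if n_cons else []
    )

    donors_pd = [f"PD{i + 1}" for i in range(n_pd_donors)]
    donors_ct = [f"CTRL{i + 1}" for i in range(n_ctrl_donors)]

    xs, ys, gs = [], [], []
    truth_rows = []
    point_radius = max(radius - 1.0, 0.5)
    for i, (cond, t) in enumerate(assign):
        cx, cy = centers[i]
        mean = profiles[t].copy()
        is_cons = i in cons_cells
        if is_cons:
            mean = mean * sig_shift
        mean = mean * rng.lognormal(mean=0.0, sigma=cell_size_sd)
        counts_i = _nb_draw(rng, mean, truth.nb_dispersion)
        n_tx = int(counts_i.sum())
        if n_tx:
            theta = rng.uniform(0, 2 * np.pi, size=n_tx)
            r = point_radius * np.sqrt(rng.uniform(0, 1, size=n_tx))
            xs.append(cx + r * np.cos(theta))
            ys.append(cy + r * np.sin(theta))
            gs.extend(np.repeat(panel, counts_i))
        donor = rng.choice(donors_pd if cond == "disease" else donors_ct)
        truth_rows.append(
            {
                "cell_id": i + 1,
                "x": cx,
                "y": cy,
                "donor": donor,
                "condition": cond,
                "cell_type": t,
                "is_consensus": bool(is_cons),
            }
        )

    n_nd = len(gs)
    f = truth.dominant_fraction
    n_dom = int(round(f / (1.0 - f) * n_nd)) if n_nd else 0
    if n_dom:
        in_cell = rng.random(n_dom) >= background_share
        n_in = int(in_cell.sum())
        n_bg = n_dom - n_in
        if n_in:
            which = rng.integers(0, n_cells, size=n_in)
            theta = rng.uniform(0, 2 * np.pi, size=n_in)
            r = point_radius * np.sqrt(rng.uniform(0, 1, size=n_in))
            xs.append(centers[which, 0] + r * np.cos(theta))
            ys.append(centers[which, 1] + r * np.sin(theta))
            gs.extend([truth.dominant_gene] * n_in)
        if n_bg:
            xs.append(rng.uniform(0, w - 1e-9, size=n_bg))
            ys.append(rng.uniform(0, h - 1e-9, size=n_bg))
            gs.extend([truth.dominant_gene] * n_bg)

    table = pd.DataFrame(
        {
            "x": np.concatenate(xs) if xs else np.array([]),
            "y": np.concatenate(ys) if ys else np.array([]),
            "gene": gs,
        }
    )
    perm = rng.permutation(len(table))
    table = table.iloc[perm].reset_index(drop=True)
    cell_truth = pd.DataFrame(truth_rows).set_index("cell_id")
    return SpatialTranscriptTable(table), LabelMask(mask), cell_truth
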