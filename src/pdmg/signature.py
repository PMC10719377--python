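"""Marker-set scoring and the cross-modality consensus microglia signature.

The consensus signature captures genes that place significantly deregulated
gene sets in *both* modalities (bulk mutant-vs-isogenic microglia and
disease-vs-control single-nucleus microglia): sets enriched in both DE
results, each backed by at least one significant gene from each modality,
contribute their significant genes, with per-gene directions required to
agree wherever both modalities call the gene.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import ConsensusSignature, GeneSet, SignatureEntry
from .stats import DETable, bh_fdr, hypergeom_test

__all__ = ["ssgsea_score", "ora", "build_consensus_signature"]


def ssgsea_score(
    expr: Mapping[str, float] | pd.Series,
    gene_set: GeneSet,
    alpha_weight: float = 0.25,
) -> float:
    """Single-sample gene-set enrichment (running-sum) score.

    Genes are ranked by descending expression (ties broken by gene id so the
    score is deterministic); walking down the ranking, the score accumulates
    the difference between the rank-weighted cumulative fraction of set
    members (weight = rank value ** alpha_weight, where the top gene has rank
    value N) and the unweighted cumulative fraction of non-members.
    """
    expr = pd.Series(expr, dtype=float)
    universe = set(expr.index)
    members = set(gene_set.members) & universe
    if not members:
        raise ValueError(f"gene set '{gene_set.name}' has no genes in the profile")
    if members == universe:
        raise ValueError("gene set equals the whole profile; score undefined")
    order = sorted(expr.index, key=lambda g: (-expr[g], g))
    n = len(order)
    in_set = np.array([g in members for g in order])
    rank_value = np.arange(n, 0, -1, dtype=float)  # top gene -> N
    w = rank_value**alpha_weight
    w_in = np.where(in_set, w, 0.0)
    p_in = np.cumsum(w_in) / w_in.sum()
    p_out = np.cumsum(~in_set) / float(n - len(members))
    return float(np.sum(p_in - p_out))


def ora(
    de: DETable,
    sets: Sequence[GeneSet],
    universe: Sequence[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each set in the significant DEGs.

    The query is the set of genes at q < ``alpha`` in ``de``; p-values are
    BH-adjusted across sets.  Returns a frame indexed by set name with
    columns ``overlap`` (sorted overlapping genes), ``directions`` (their DE
    signs), ``k``, ``K``, ``n``, ``p``, ``q``.  Sets disjoint from the
    universe are skipped with a warning.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty gene universe")
    de_genes = set(de.table.index)
    if not de_genes.issubset(universe_set):
        raise ValueError("DE table contains genes outside the universe")
    sig = de.significant(alpha)
    query = set(sig.index)
    dir_map = sig["direction"].to_dict()
    rows = []
    for s in sets:
        members = set(s.members) & universe_set
        if not members:
            warnings.warn(
                f"gene set '{s.name}' shares no genes with the universe; skipped",
                stacklevel=2,
            )
            continue
        overlap = sorted(members & query)
        p = hypergeom_test(len(overlap), len(members), len(query), len(universe_set))
        rows.append(
            {
                "set": s.name,
                "overlap": overlap,
                "directions": [int(dir_map[g]) for g in overlap],
                "k": len(overlap),
                "K": len(members),
                "n": len(query),
                "p": p,
            }
        )
    out = pd.DataFrame(rows).set_index("set") if rows else pd.DataFrame(
        columns=["overlap", "directions", "k", "K", "n", "p"]
    )
    out["q"] = bh_fdr(out["p"].to_numpy()) if len(out) else []
    return out


def build_consensus_signature(
    de_bulk: DETable,
    de_sn: DETable,
    sets: Sequence[GeneSet],
    universe: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> ConsensusSignature:
    """Construct the cross-modality consensus signature.

    1. Run over-representation of each gene set in each modality's DEGs.
    2. Keep sets significant (q < alpha) in BOTH modalities that also contain
       at least one significant gene from EACH modality.
    3. The signature is the union of the surviving sets' significant genes.
    4. A gene significant in both modalities is kept only when the two signs
       agree (conflicts are excluded and logged); a gene significant in one
       modality takes that modality's sign.
    """
    if universe is None:
        universe = sorted(set(de_bulk.table.index) | set(de_sn.table.index))
    ora_bulk = ora(de_bulk, sets, universe, alpha)
    ora_sn = ora(de_sn, sets, universe, alpha)

    sig_bulk = de_bulk.significant(alpha)
    sig_sn = de_sn.significant(alpha)
    shared = [
        s
        for s in ora_bulk.index
        if s in ora_sn.index
        and ora_bulk.loc[s, "q"] < alpha
        and ora_sn.loc[s, "q"] < alpha
        and ora_bulk.loc[s, "k"] >= 1
        and ora_sn.loc[s, "k"] >= 1
    ]
    if not shared:
        warnings.warn("no gene set is enriched in both modalities; empty signature",
                      stacklevel=2)

    set_members = {s.name: set(s.members) for s in sets}
    conflicts: list[str] = []
    entries: list[SignatureEntry] = []
    candidate_genes: set[str] = set()
    for s in shared:
        candidate_genes |= set(ora_bulk.loc[s, "overlap"])
        candidate_genes |= set(ora_sn.loc[s, "overlap"])
    for gene in sorted(candidate_genes):
        in_bulk = gene in sig_bulk.index
        in_sn = gene in sig_sn.index
        support = tuple(
            m for m, flag in (("bulk", in_bulk), ("sn", in_sn)) if flag
        )
        if in_bulk and in_sn:
            d_b = int(sig_bulk.loc[gene, "direction"])
            d_s = int(sig_sn.loc[gene, "direction"])
            if d_b != d_s:
                conflicts.append(
                    f"{gene}: bulk direction {d_b:+d} vs sn direction {d_s:+d}"
                )
                continue
            direction = d_b
        elif in_bulk:
            direction = int(sig_bulk.loc[gene, "direction"])
        else:
            direction = int(sig_sn.loc[gene, "direction"])
        if direction == 0:
            continue
        contributing = tuple(sorted(s for s in shared if gene in set_members[s]))
        if not contributing:
            continue
        entries.append(
            SignatureEntry(gene=gene, direction=direction, support=support,
                           sets=contributing)
        )
    return ConsensusSignature(
        entries=entries,
        alpha_used=alpha,
        provenance={
            "n_sets": len(sets),
            "shared_sets": sorted(shared),
            "n_sig_bulk": int(len(sig_bulk)),
            "n_sig_sn": int(len(sig_sn)),
        },
        conflicts=conflicts,
    )
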