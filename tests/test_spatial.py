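"""Transcript-to-cell assignment against brute force; clustering invariances."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from pdmg.io_formats import GeneSet, LabelMask, SpatialTranscriptTable
from pdmg.spatial import (
    CellTable,
    annotate_clusters,
    assign_transcripts,
    cluster_cells,
    log_normalize_cells,
)
from pdmg.synthetic_data import MARKER_GENES


def _table(points):
    return SpatialTranscriptTable(
        pd.DataFrame(points, columns=["x", "y", "gene"]).astype(
            {"x": float, "y": float}
        )
    )


def brute_force_assign(x, y, mask, expansion):
    """Exhaustive nearest-labeled-pixel search (lowest label on ties)."""
    lab_r, lab_c = np.nonzero(mask)
    r, c = int(np.floor(y)), int(np.floor(x))
    h, w = mask.shape
    if not (0 <= r < h and 0 <= c < w):
        return 0
    if mask[r, c] > 0:
        return int(mask[r, c])
    d2 = (lab_r - r) ** 2 + (lab_c - c) ** 2
    dmin = np.sqrt(d2.min())
    if dmin > expansion + 1e-9:
        return 0
    ties = np.sqrt(d2) <= dmin + 1e-9
    return int(mask[lab_r[ties], lab_c[ties]].min())


class TestAssignTranscripts:
    MASK = np.array(
        [
            [0, 0, 0, 0, 0, 0],
            [0, 1, 1, 0, 0, 0],
            [0, 1, 1, 0, 0, 0],
            [0, 0, 0, 0, 2, 2],
            [0, 0, 0, 0, 2, 2],
            [0, 0, 0, 0, 0, 0],
        ]
    )

    def test_transcript_on_labeled_pixel(self):
        t = _table([(1.5, 1.5, "g")])
        ct = assign_transcripts(t, LabelMask(self.MASK), expansion_px=0)
        assert ct.counts.loc[1, "g"] == 1 and ct.unassigned == 0

    def test_background_beyond_expansion_unassigned(self):
        mask = np.zeros((20, 20), dtype=int)
        mask[0, 0] = 1
        t = _table([(15.0, 15.0, "g")])  # ~21 px from the only labeled pixel
        ct = assign_transcripts(t, LabelMask(mask), expansion_px=8)
        assert ct.unassigned == 1
        assert ct.counts.to_numpy().sum() == 0

    def test_toy_matches_brute_force(self, rng):
        mask = self.MASK
        pts = [
            (float(rng.uniform(0, 6)), float(rng.uniform(0, 6)), "g")
            for _ in range(12)
        ]
        t = _table(pts)
        for expansion in (0, 1.5, 3, 8):
            ct = assign_transcripts(t, LabelMask(mask), expansion_px=expansion)
            expected = np.zeros(3, dtype=int)  # [unassigned, cell1, cell2]
            for x, y, _ in pts:
                expected[brute_force_assign(x, y, mask, expansion)] += 1
            assert ct.unassigned == expected[0]
            assert ct.counts.loc[1, "g"] == expected[1]
            assert ct.counts.loc[2, "g"] == expected[2]

    def test_fuzz_conservation_and_zero_expansion_histogram(self, rng):
        for _ in range(25):
            h, w = int(rng.integers(5, 15)), int(rng.integers(5, 15))
            mask = rng.integers(0, 4, size=(h, w))
            if (mask > 0).sum() == 0:
                mask[0, 0] = 1
            n = int(rng.integers(1, 40))
            pts = [
                (float(rng.uniform(0, w + 2)), float(rng.uniform(0, h + 2)), "g")
                for _ in range(n)
            ]
            t = _table(pts)
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # out-of-bounds points warn
                ct = assign_transcripts(t, LabelMask(mask), expansion_px=2.0)
                ct0 = assign_transcripts(t, LabelMask(mask), expansion_px=0)
            assert int(ct.counts.to_numpy().sum()) + ct.unassigned == n
            hist = np.zeros(mask.max() + 1, dtype=int)
            for x, y, _ in pts:
                r, c = int(np.floor(y)), int(np.floor(x))
                if 0 <= r < h and 0 <= c < w:
                    hist[mask[r, c]] += 1
            for lab in range(1, mask.max() + 1):
                got = (
                    int(ct0.counts.loc[lab].sum()) if lab in ct0.counts.index else 0
                )
                assert got == hist[lab]

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="no cells"):
            assign_transcripts(_table([(0.5, 0.5, "g")]), LabelMask(np.zeros((3, 3), int)))

    def test_all_mask_labels_become_cells(self):
        # a cell with zero transcripts is kept (no count-based filtering)
        t = _table([(1.5, 1.5, "g")])
        ct = assign_transcripts(t, LabelMask(self.MASK), expansion_px=0)
        assert list(ct.counts.index) == [1, 2]
        assert ct.counts.loc[2].sum() == 0


def _two_population_table(rng, n=120):
    """Two clearly separated expression programs over 12 genes."""
    genes = [f"g{i}" for i in range(12)]
    counts = np.zeros((n, 12), dtype=int)
    for i in range(n):
        hi = slice(0, 6) if i < n // 2 else slice(6, 12)
        counts[i, hi] = rng.poisson(50.0, 6)
        counts[i, 0 if i >= n // 2 else 6] += rng.poisson(1.0)
        counts[i] += rng.poisson(1.0, 12)
    df = pd.DataFrame(counts, index=range(1, n + 1), columns=genes)
    meta = pd.DataFrame(index=df.index)
    truth = np.array([0] * (n // 2) + [1] * (n - n // 2))
    return CellTable(counts=df, meta=meta), truth


class TestClusterCells:
    def test_two_separated_populations(self, rng):
        ct, truth = _two_population_table(rng)
        labels = cluster_cells(ct, seed=0)
        assert labels.nunique() == 2
        assert adjusted_rand_score(truth, labels) >= 0.95

    def test_duplication_invariance(self, rng):
        ct, _ = _two_population_table(rng)
        base = cluster_cells(ct, seed=0)
        doubled = pd.concat([ct.counts, ct.counts.set_axis(ct.counts.index + 1000)])
        ct2 = CellTable(counts=doubled, meta=pd.DataFrame(index=doubled.index))
        lab2 = cluster_cells(ct2, seed=0)
        assert adjusted_rand_score(base, lab2.iloc[: len(base)]) == pytest.approx(1.0)

    def test_gene_order_invariance(self, rng):
        ct, _ = _two_population_table(rng)
        a = cluster_cells(ct, seed=0)
        shuffled = ct.counts[list(reversed(ct.counts.columns))]
        ct2 = CellTable(counts=shuffled, meta=pd.DataFrame(index=shuffled.index))
        b = cluster_cells(ct2, seed=0)
        assert adjusted_rand_score(a, b) == pytest.approx(1.0)

    def test_fewer_genes_than_requested_warns(self, rng):
        ct, _ = _two_population_table(rng)
        with pytest.warns(UserWarning, match="using all"):
            cluster_cells(ct, n_var_genes=50, seed=0)


class TestAnnotateClusters:
    def _cell_table_with_clusters(self, rng):
        genes = ["TMEM119", "P2RY12", "AQP4", "SLC1A2"]
        counts = np.vstack(
            [
                np.column_stack(
                    [rng.poisson(40, 30), rng.poisson(40, 30),
                     rng.poisson(1, 30), rng.poisson(1, 30)]
                ),
                np.column_stack(
                    [rng.poisson(1, 30), rng.poisson(1, 30),
                     rng.poisson(40, 30), rng.poisson(40, 30)]
                ),
            ]
        )
        df = pd.DataFrame(counts, index=range(1, 61), columns=genes)
        meta = pd.DataFrame({"cluster": [0] * 30 + [1] * 30}, index=df.index)
        ct = CellTable(counts=df, meta=meta)
        return ct

    def test_marker_driven_annotation(self, rng):
        ct = self._cell_table_with_clusters(rng)
        sets = [
            GeneSet("microglia", MARKER_GENES["microglia"]),
            GeneSet("astrocyte", MARKER_GENES["astrocyte"]),
        ]
        types = annotate_clusters(ct, sets)
        assert (types.iloc[:30] == "microglia").all()
        assert (types.iloc[30:] == "astrocyte").all()

    def test_renamed_sets_follow_names(self, rng):
        ct = self._cell_table_with_clusters(rng)
        sets = [
            GeneSet("typeA", MARKER_GENES["microglia"]),
            GeneSet("typeB", MARKER_GENES["astrocyte"]),
        ]
        types = annotate_clusters(ct, sets)
        assert set(types.unique()) <= {"typeA", "typeB"}

    def test_tied_scores_yield_unknown(self, rng):
        ct = self._cell_table_with_clusters(rng)
        same = GeneSet("A", ["TMEM119", "P2RY12"])
        same2 = GeneSet("B", ["TMEM119", "P2RY12"])
        types = annotate_clusters(ct, [same, same2])
        assert (types == "unknown").all()

    def test_disjoint_marker_set_warns(self, rng):
        ct = self._cell_table_with_clusters(rng)
        with pytest.warns(UserWarning, match="no genes"):
            types = annotate_clusters(
                ct,
                [GeneSet("microglia", MARKER_GENES["microglia"]),
                 GeneSet("ghost", ["NOPE1", "NOPE2"])],
            )
        assert "ghost" not in set(types)


def test_end_to_end_microglia_recall(small_truth):
    from pdmg.preprocess import high_abundance_filter
    from pdmg.synthetic_data import gen_spatial

    tr, mask, cell_truth = gen_spatial(small_truth, n_cells=200, field=(420, 420))
    filtered, _ = high_abundance_filter(tr)
    ct = assign_transcripts(filtered, mask)
    cluster_cells(ct, seed=0)
    sets = [GeneSet(name=t, members=m) for t, m in MARKER_GENES.items()]
    ann = annotate_clusters(ct, sets)
    truth_types = cell_truth["cell_type"].reindex(ann.index)
    mg = truth_types == "microglia"
    recall = float((ann[mg] == "microglia").mean())
    assert recall >= 0.9
    # every cluster is annotated as its majority ground-truth type
    for cl in ct.meta["cluster"].unique():
        cells = ct.meta.index[ct.meta["cluster"] == cl]
        majority = truth_types.loc[cells].mode()[0]
        got = ann.loc[cells].iloc[0]
        if got != "unknown":
            assert got == majority
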