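# pdmg — cross-modality PD-microglia consensus signature

`pdmg` re-implements, as a tested Python pipeline, a computational chain used
to characterize microglia in Parkinson's disease (PD) across three
transcriptomic modalities:

1. **Bulk RNA-seq** of mutant (LRRK2-G2019S) vs isogenic-control
   iPSC-derived microglia-like cells: TMM-normalized log2-CPM, low-expression
   filtering, and a negative-binomial likelihood-ratio test with BH FDR
   control.
2. **Single-nucleus RNA-seq** of PD and control midbrain: Wilcoxon rank-sum
   differential expression of microglia at the cell level, and an NNLS
   deconvolution of bulk profiles against the multi-donor single-cell
   reference (cross-donor-variance weighted, MuSiC-style).
3. **Spatial transcriptomics** (a 100-gene panel): transcript-to-cell
   assignment over a segmentation label mask, removal of a dominant
   ubiquitous gene (GFAP can contribute half or more of all transcripts),
   clustering on the 10 most variable transcripts and 5 principal
   components, and marker-based cell-type annotation.

The two differential-expression results are combined into a **consensus
PD-microglia signature**: gene sets significantly over-represented in *both*
modalities, each backed by at least one significant gene from each modality,
contribute their significant genes with sign-consistent directions.  Spatial
microglia from PD donors are then classified as **consensus PD-microglia**
when their per-gene deviations from the healthy microglial reference follow
the signature's directions (for a cell with log-normalized expression `x`
and healthy reference `r`, gene `g` agrees iff
`sign(x_g − r_g) = direction(g)`; the cell is consensus iff the agreement
fraction ≥ τ, default τ = 1).  In the motivating study this class comprised
5.4% (35 of 653) of PD-brain microglia.

Because the study's raw data are not bundled, the package ships a
first-class synthetic generator (`pdmg.synthetic_data`) that emulates all
three modalities with planted ground truth (signature genes and directions,
cell-type proportions, consensus fraction, dominant-gene share), so every
stage is verified by parameter recovery.

## Worked example

Run the full synthetic pipeline (simulate → DE in both modalities →
signature → deconvolution → spatial classification):

```sh
pdmg run --simulate --seed 7 --out run7
```

prints

```
{
 "consensus_percentage": 4.411764705882353,
 "n_consensus": 3,
 "n_pd_microglia": 68,
 "signature_jaccard_vs_truth": 0.9,
 "signature_size": 9
}
```

Of the 68 disease-donor microglia found in the simulated tissue section, 3
(4.4%) followed the recovered 9-gene signature in every evaluable gene and
were classified consensus — close to the planted 5.4% consensus fraction.
The recovered signature overlaps the planted 10-gene truth with Jaccard 0.9
and no direction errors.  `run7/` contains the per-stage artifacts:
`de_bulk.tsv`, `de_sn.tsv`, `signature.json`, `props.csv` (deconvolved
cell-type proportions per bulk sample), `cells.csv` (per-cell counts,
cluster, type, class), `class_summary.tsv` (distribution percentages,
pairwise Wilcoxon q-values, presence categories) and `report.json`.

Individual stages are also exposed (`pdmg simulate`, `pdmg preprocess`,
`pdmg de`, `pdmg signature`, `pdmg deconvolve`, `pdmg spatial`,
`pdmg classify`); see `examples/sim.yaml` for the simulation knobs and
`examples/markers.gmt` for the marker-set format.

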