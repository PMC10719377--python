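# Simulation configuration for `pdmg simulate` / `pdmg run`.
# All values shown are the defaults used by `pdmg run --simulate`.
truth:
  n_genes: 2000          # generic genes besides the named marker/dominant genes
  n_signature: 10        # planted directional signature genes
  sig_log2fc: 1.0        # bulk / single-nucleus effect size (log2)
  consensus_fraction: 0.054   # share of disease microglia planted as consensus
  nb_dispersion: 0.1
  dominant_gene: GFAP
  dominant_fraction: 0.6 # share of all spatial transcripts from the dominant gene
  spatial_log2fc: 2.5    # consensus-cell shift on the spatial panel
  spatial_sig_mean: 10.0 # baseline signature-gene counts per microglial cell
  seed: 7
bulk:
  n_per_group: 6
  depth: 1000000.0
sn:
  donors_per_group: 5
  cells_per_donor: 150
spatial:
  n_cells: 400
  field: [512, 512]
alpha: 0.05
tau: 1.0        # required signature-concordance fraction for a consensus call
epsilon: 0.0    # minimum per-gene deviation magnitude
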