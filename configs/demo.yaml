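# Demo configuration for a small synthetic universe.
#
# The degree/link/module thresholds are scaled down from the proteome-scale
# defaults (300/300/200 links, 5-core) because the demo universe is three
# orders of magnitude smaller than a real interactome; the LR cutoff is
# likewise chosen for a network of this size.

universe:
  n_proteins: 150
  true_density: 0.02
  rho_signal: 0.7
  ddi_signal: 0.7
  interolog_fidelity: 0.7
  source_noise: 0.2
  n_samples: 40
  seed: 0

bayes:
  pseudocount: 1.0
  prior_odds: 1.0
  lr_cutoff: 10.0
  n_rho_bins: 10
  ssbp_edges: [5, 10, 25, 100]

sts:
  n_negative: null   # default: balanced with the held-out positives

hubs:
  degree: 6
  classical_links: 2
  novel_links: 1
  k_core: 3
  sam_delta: 1.0
  sam_permutations: 200

subnet:
  radius: 1
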