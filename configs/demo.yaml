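# Demo: 80-subject synthetic crossover cohort (43 young + 37 old), two
# sleep conditions, default bilateral covariance modules at r = 0.40, plus a
# condition-specific covariance increase of +0.30 in the paralimbic module
# (insula, parahippocampal, temporal pole, transverse temporal, entorhinal,
# both hemispheres) under sleep restriction.
seed: 20260925
q: 0.05
permutations: 1000
n_random: 100
conditions: [restricted, full]
stratify: false
input_table: null
synthetic:
  n_young: 43
  n_old: 37
  base_mean_mm: 2.5
  base_sd_mm: 0.25
  subject_reliability: 0.5
  modules: default
  covariance_boost:
    - rois: [lh_insula, rh_insula, lh_parahippocampal, rh_parahippocampal,
             lh_temporalpole, rh_temporalpole, lh_transversetemporal,
             rh_transversetemporal, lh_entorhinal, rh_entorhinal]
      condition: restricted
      delta_r: 0.3
metrics:
  global: [clustering, path_length, global_efficiency, local_efficiency]
  nodal: [degree, nodal_efficiency, betweenness]
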