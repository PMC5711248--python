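# Evaluation objectives for the packaged synthetic phantom: the same
# three-level scheme as the clinical protocol, restricted to the structures
# the phantom carries (nested PTVs, a posterior serial-OAR surrogate with
# PRV, and paired lateral parallel-OAR surrogates).
objectives:
  - {id: ptv1_d95, structure: ptv1, level: 1, metric: D_at_volume, metric_param: 95, threshold: 66.5, direction: at_least}
  - {id: ptv1_d99, structure: ptv1, level: 1, metric: D_at_volume, metric_param: 99, threshold: 63.0, direction: at_least}
  - {id: ptv2_d95, structure: ptv2, level: 1, metric: D_at_volume, metric_param: 95, threshold: 59.9, direction: at_least}
  - {id: ptv2_d99, structure: ptv2, level: 1, metric: D_at_volume, metric_param: 99, threshold: 56.7, direction: at_least}
  - {id: ptv3_d95, structure: ptv3, level: 1, metric: D_at_volume, metric_param: 95, threshold: 53.2, direction: at_least}
  - {id: ptv3_d99, structure: ptv3, level: 1, metric: D_at_volume, metric_param: 99, threshold: 50.4, direction: at_least}
  - {id: body_max, structure: body, level: 1, metric: max, threshold: 77.0, direction: at_most}
  - {id: cord_max, structure: cord_prv, level: 2, metric: max, threshold: 50.0, direction: at_most}
  - {id: parotid_l_mean, structure: parotid_l, level: 3, metric: mean, threshold: 26.0, direction: at_most}
  - {id: parotid_r_mean, structure: parotid_r, level: 3, metric: mean, threshold: 26.0, direction: at_most}
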