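# Full clinical evaluation-objective protocol for a three-dose-level
# head-and-neck (nasopharynx) simultaneous integrated boost: 70 / 63 / 56 Gy
# in 33 fractions.  Doses in Gy (total), volume parameters in %.
# Level 1: target coverage and the global maximum; level 2: serial OARs
# (PRV = OAR + 5 mm margin); level 3: parallel OARs, with optional stricter
# aspiration targets ("target") used by the sparing strategy.
objectives:
  - {id: ptv1_d95, structure: ptv1, level: 1, metric: D_at_volume, metric_param: 95, threshold: 66.5, direction: at_least}
  - {id: ptv1_d99, structure: ptv1, level: 1, metric: D_at_volume, metric_param: 99, threshold: 63.0, direction: at_least}
  - {id: ptv2_d95, structure: ptv2, level: 1, metric: D_at_volume, metric_param: 95, threshold: 59.9, direction: at_least}
  - {id: ptv2_d99, structure: ptv2, level: 1, metric: D_at_volume, metric_param: 99, threshold: 56.7, direction: at_least}
  - {id: ptv3_d95, structure: ptv3, level: 1, metric: D_at_volume, metric_param: 95, threshold: 53.2, direction: at_least}
  - {id: ptv3_d99, structure: ptv3, level: 1, metric: D_at_volume, metric_param: 99, threshold: 50.4, direction: at_least}
  - {id: body_max, structure: body, level: 1, metric: max, threshold: 77.0, direction: at_most}
  - {id: cord_prv_max, structure: spinal_cord_prv, level: 2, metric: max, threshold: 50.0, direction: at_most}
  - {id: brainstem_prv_max, structure: brainstem_prv, level: 2, metric: max, threshold: 60.0, direction: at_most}
  - {id: optics_max, structure: optics, level: 2, metric: max, threshold: 55.0, direction: at_most}
  - {id: cochlea_mean, structure: cochleae, level: 3, metric: mean, threshold: 40.0, direction: at_most, target: 35.0}
  - {id: parotid_mean, structure: parotids, level: 3, metric: mean, threshold: 26.0, direction: at_most}
  - {id: larynx_mean, structure: larynx, level: 3, metric: mean, threshold: 50.0, direction: at_most, target: 45.0}
  - {id: oral_cavity_mean, structure: oral_cavity, level: 3, metric: mean, threshold: 60.0, direction: at_most, target: 55.0}
  - {id: eyes_max, structure: eyes, level: 3, metric: max, threshold: 45.0, direction: at_most, target: 40.0}
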