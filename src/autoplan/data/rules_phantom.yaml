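# The predefined rule set (the planner's "initialization file") for the
# packaged synthetic phantom.
#
# constraints: the optimization-constraint templates, introduced by priority
#   stage (1 targets + global max, 2 serial OARs, 3 parallel OARs + rinds).
#   Doses are absolute Gy ({value: ...}) or prescription fractions
#   ({fraction: ..., of: rx1|rx2|rx3}); fractional doses track the live
#   prescription under the escalation strategy.  step: up = coverage
#   constraint may rise (bounded by the same structure's uniform/max dose),
#   down = sparing constraint may fall (bounded by floor).
# rules: objective id -> ordered associated constraints + permitted actions.
# ladder: the penalty-weight sequence; all weights start at 1.
constraints:
  - {id: ptv1_min_dvh, structure: ptv1, ctype: min_dvh, stage: 1, volume_pct: 95,
     dose: {fraction: 0.95, of: rx1}, adjust_dose: true, step: up,
     ceiling: {fraction: 1.0, of: rx1}}
  - {id: ptv1_min, structure: ptv1, ctype: min_dose, stage: 1,
     dose: {fraction: 0.90, of: rx1}, adjust_dose: true, step: up,
     ceiling: {fraction: 1.0, of: rx1}}
  - {id: ptv1_uniform, structure: ptv1, ctype: uniform_dose, stage: 1,
     dose: {fraction: 1.0, of: rx1}}
  - {id: ptv2_min_dvh, structure: ptv2, ctype: min_dvh, stage: 1, volume_pct: 95,
     dose: {fraction: 0.95, of: rx2}, adjust_dose: true, step: up,
     ceiling: {fraction: 1.0, of: rx2}}
  - {id: ptv2_min, structure: ptv2, ctype: min_dose, stage: 1,
     dose: {fraction: 0.90, of: rx2}, adjust_dose: true, step: up,
     ceiling: {fraction: 1.0, of: rx2}}
  - {id: ptv3_min_dvh, structure: ptv3, ctype: min_dvh, stage: 1, volume_pct: 95,
     dose: {fraction: 0.95, of: rx3}, adjust_dose: true, step: up,
     ceiling: {fraction: 1.0, of: rx3}}
  - {id: ptv3_min, structure: ptv3, ctype: min_dose, stage: 1,
     dose: {fraction: 0.90, of: rx3}, adjust_dose: true, step: up,
     ceiling: {fraction: 1.0, of: rx3}}
  - {id: body_max, structure: body, ctype: max_dose, stage: 1,
     dose: {fraction: 1.10, of: rx1}, adjust_dose: true, step: down,
     floor: {fraction: 1.0, of: rx1}}
  - {id: cord_max, structure: cord_prv, ctype: max_dose, stage: 2,
     dose: {value: 50.0}, adjust_dose: true, step: down, floor: {value: 25.0}}
  - {id: parotid_l_eud, structure: parotid_l, ctype: max_eud, stage: 3, eud_a: 1.0,
     dose: {value: 26.0}, adjust_dose: true, step: down, floor: {value: 1.0}}
  - {id: parotid_r_eud, structure: parotid_r, ctype: max_eud, stage: 3, eud_a: 1.0,
     dose: {value: 26.0}, adjust_dose: true, step: down, floor: {value: 1.0}}
  - {id: rind1_max, structure: rind1, ctype: max_dose, stage: 3,
     dose: {fraction: 0.95, of: rx1}, floor: {fraction: 0.90, of: rx1}}
  - {id: rind2_max, structure: rind2, ctype: max_dose, stage: 3,
     dose: {fraction: 0.95, of: rx2}, floor: {fraction: 0.90, of: rx2}}
  - {id: rind3_max, structure: rind3, ctype: max_dose, stage: 3,
     dose: {fraction: 0.95, of: rx3}, floor: {fraction: 0.90, of: rx3}}
rules:
  ptv1_d95: {constraints: [ptv1_min_dvh], actions: [raise_weight, step_dose_up]}
  ptv1_d99: {constraints: [ptv1_min], actions: [raise_weight, step_dose_up]}
  ptv2_d95: {constraints: [ptv2_min_dvh], actions: [raise_weight, step_dose_up]}
  ptv2_d99: {constraints: [ptv2_min], actions: [raise_weight, step_dose_up]}
  ptv3_d95: {constraints: [ptv3_min_dvh], actions: [raise_weight, step_dose_up]}
  ptv3_d99: {constraints: [ptv3_min], actions: [raise_weight, step_dose_up]}
  body_max: {constraints: [body_max], actions: [raise_weight, step_dose_down]}
  cord_max: {constraints: [cord_max], actions: [raise_weight, step_dose_down]}
  parotid_l_mean: {constraints: [parotid_l_eud], actions: [raise_weight, step_dose_down]}
  parotid_r_mean: {constraints: [parotid_r_eud], actions: [raise_weight, step_dose_down]}
ladder: [1, 10, 25, 50, 75, 100]
step_gy: 1.0
rind_tighten_factor: 0.98
rind_floor_fraction: 0.90
sparing_step_gy: 1.0
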