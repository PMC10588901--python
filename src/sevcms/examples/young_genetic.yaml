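# Study config for the combined young genetic-model dataset (Scn1a + Gria1),
# analyzed separately per age bracket (early vs late adolescence).
group_burden_map:
  wildtype: 0
  mutant: 1
exclusion_list:
  homecage_distance: 60-minute pilot acquisition, no circadian coverage
  homecage_velocity: 60-minute pilot acquisition, no circadian coverage
  homecage_center: covered cage top; center not comparable to open field
  body_weight_g: background-strain differences between the genetic models
  body_weight_change_pct: background-strain differences between the genetic models
post_correlation_exclusions:
  of_center_time: redundant with wall-zone duration; transient thigmotaxis makes
    the wall zone the informative readout
  of_immobility: redundant with open-field distance (strong negative r)
keep_rules:
  - of_wall_time
  - of_distance
k: 4
seed: 0
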