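# Study config for the combined adult induced-epilepsy dataset
# (intrahippocampal kainate + hippocampal and amygdala kindling).
group_burden_map:
  naive: exclude
  sham: 0
  treated: 1
exclusion_list:
  body_weight_g: model-specific weight gain unrelated to distress
  body_weight_change_pct: model-specific weight gain unrelated to distress
  soiling_level: assessed in a single subproject only
  corticosterone_serum: invasive sampling; fecal metabolites retained
  telemetry_recording: invasive instrumentation without added value
  spontaneous_seizures: model-defining outcome, not a welfare parameter
  induced_seizures: model-defining outcome, not a welfare parameter
post_correlation_exclusions:
  of_wall_time: redundant with open-field center time (strong negative r)
  of_immobility: redundant with open-field distance (strong negative r)
  of_velocity: redundant with open-field distance (velocity = distance/time)
  epm_closed_arms: redundant with open-arm duration and head dips
  burrowing_overnight: light-phase burrowing is the more sensitive readout
keep_rules:
  - burrowing_2h_light
  - of_distance
  - of_center_time
  - epm_open_arms
  - epm_head_dips
k: 6
seed: 0
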