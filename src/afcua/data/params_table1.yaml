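age_mean: 64.0
age_sd: 8.0
bleed_split_dab_raw:
  extracranial: 0.904
  intracranial: 0.126
bleed_split_warfarin:
  extracranial: 0.58
  intracranial: 0.42
cohort_size: 10000
cost_dab_daily: 3.2
cost_genotyping: 615.0
cost_inr_month_gtw_y1: 5.0
cost_inr_month_later: 4.03
cost_inr_month_sdw_y1: 8.06
cost_lmwh_course: 27.9
cost_warfarin_daily: 0.074
discount_annual: 0.03
event_costs:
  dvt: 2576.0
  extracranial_bleed: 8146.0
  ich_mild: 21218.0
  ich_none: 1067.0
  ich_severe: 36451.0
  mi: 7177.0
  pe: 8799.0
  stroke_mild: 23772.0
  stroke_none: 845.0
  stroke_severe: 42620.0
  subdural: 31942.0
flags:
  additive_ttr_uplift: false
  literal_ich_utilities: false
  literal_rr_labels: false
frac_below_of_out_of_range: 0.54
gtw_ttr_uplift: 0.073
horizon_days: 1825
ich_outcomes:
  death_first_month: 0.42
  mild: 0.16
  no_deficit: 0.08
  severe: 0.34
n_replicates: 1000
p_bleed_annual_inrange: 0.014
p_death_dvt: 0.06
p_death_extracranial: 0.02
p_death_mi: 0.07
p_death_pe: 0.12
p_te_annual_inrange: 0.024
post_event_monthly:
  mild: 1855.0
  severe: 6259.0
psa_cohort_size: 5000
psa_iterations: 1000
rr_bleed_dab: 0.93
rr_bleed_out_of_range: 4.7
rr_te_dab:
  dvt: 1.0
  mi: 1.38
  pe: 1.61
  stroke: 0.66
rr_te_other_out_of_range: 0.9
rr_te_subtherapeutic: 3.5
stop_after_gi_bleed_days: 30
stroke_outcomes:
  death_m1: 0.083
  death_m2: 0.056
  death_m3: 0.056
  mild: 0.425
  none: 0.091
  severe: 0.402
te_split_warfarin:
  dvt: 0.05
  mi: 0.125
  pe: 0.3
  stroke: 0.525
ttr_sdw: 0.64
utilities:
  dvt: 0.84
  extracranial: 0.8
  ich_mild: 0.75
  ich_none: 0.95
  ich_severe: 0.51
  mi: 0.84
  no_event_dab: 0.95
  no_event_warfarin: 0.95
  pe: 0.76
  stroke_mild: 0.75
  stroke_none: 0.95
  stroke_severe: 0.39
wtp_threshold: 50000.0
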