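# Treatment-intensification scenario: activity support during pregnancy for
# all pregnant women (metabolic channel only, no weight change), alongside a
# more complete glycaemic-management response after diagnosis.
horizon_years: 36
burn_in_years: 26
calendar_start_year: 1982
seed: 1
population:
  n_women: 10000
  frac_high_risk: 0.2
  seed: 1
diagnostic_schedule:
  entries:
  - [1982, 5.0]
  - [2013, 3.3]
treatment_m_full: 0.7
interventions:
- name: antenatal_activity
  target: population
  timing: during_pregnancy
  uptake: 0.5
  bmi_effect_kg: 0.0
  s_multiplier: 1.10
  duration_years: 0.75
  adherence_decay: 1.0
  start_year: 2010
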