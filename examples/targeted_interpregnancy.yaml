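# Targeted inter-pregnancy program for screening-high-risk women: intensive
# weight management between pregnancies.
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
interventions:
- name: targeted_interpregnancy
  target: high_risk
  timing: inter_pregnancy
  uptake: 0.6
  bmi_effect_kg: -6.0
  s_multiplier: 1.12
  duration_years: 3.0
  adherence_decay: 0.3
  start_year: 2010
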