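# Population-level pre-pregnancy lifestyle program: modest weight loss plus
# a physical-activity effect on metabolic function, offered to all women of
# reproductive age before their first pregnancy from 2010.
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
- name: population_lifestyle
  target: population
  timing: pre_pregnancy
  uptake: 0.35
  bmi_effect_kg: -3.0
  s_multiplier: 1.08
  duration_years: 2.0
  adherence_decay: 0.4
  start_year: 2010
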