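# Narrative templates for agent life stories, one per event kind.
# Edit freely: these are plain format strings with the placeholders
# {age} {year} {G} {threshold} {week} {category} {bmi}.
birth: She was born in {year}.
conception: At age {age} ({year}) she became pregnant.
booking: At age {age} ({year}) she booked in with the antenatal service.
early_screen: At age {age} ({year}) she had an early screening test (glycemic index {G} against the threshold {threshold} then in force).
ogtt: At age {age} ({year}) she had the routine oral glucose tolerance test (glycemic index {G} against the threshold {threshold} then in force).
diagnosis: At age {age} ({year}) she was diagnosed with gestational diabetes at the {week}-week screening test (threshold in force {threshold}).
lifestyle_rx: At age {age} ({year}) she began dietary and physical-activity management of her pregnancy glucose levels.
pharmaco_rx: At age {age} ({year}) she commenced pharmacological treatment for diabetes in pregnancy.
delivery_care: At age {age} ({year}) she gave birth.
postpartum_test: At age {age} ({year}) she attended a postpartum glucose tolerance test.
adverse_outcome: At age {age} ({year}) the birth involved an adverse perinatal outcome.
weight_milestone: At age {age} ({year}) she moved into the {category} range (BMI {bmi}).
intervention_enrol: At age {age} ({year}) she enrolled in a prevention program.
death: In {year} she left the population.
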