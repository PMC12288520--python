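# Default healthy-lifestyle-index cutpoints. Each factor scores 0 (least
# healthy) to 4 (healthiest); the total spans 0-20. Numeric factors are
# binned by four ordered edges; "lower_better" reverses the score so that
# e.g. a low BMI scores high. Smoking is categorical on (status, intensity)
# coded upstream. Edges are conventions for the synthetic cohort, editable
# for any real dataset.
bmi:
  type: numeric
  column: bmi
  direction: lower_better
  edges: [22.5, 25.0, 27.5, 30.0]
smoking:
  type: categorical
  column: smoking_class
  scores:
    never: 4
    former_light: 3
    former_heavy: 2
    current_light: 1
    current_heavy: 0
alcohol:
  type: numeric
  column: alcohol_gday
  direction: lower_better
  edges: [6.0, 12.0, 24.0, 60.0]
diet:
  type: numeric
  column: diet_score
  direction: higher_better
  edges: [4.0, 6.0, 8.0, 10.0]
activity:
  type: numeric
  column: activity_met
  direction: higher_better
  edges: [20.0, 35.0, 50.0, 70.0]
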