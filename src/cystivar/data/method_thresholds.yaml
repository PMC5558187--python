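# Severity thresholds per predictor method.
# direction: which end of the score scale is damaging.
# severe_threshold: cut-off between mild (1) and severe (2) calls.
# boundary_rule: whether a score exactly at the severe threshold is severe.
methods:
  sift:
    direction: lower_is_worse
    standard_deleterious_threshold: 0.05
    severe_threshold: 0.025
    boundary_rule: severe_at_threshold
  polyphen2:
    direction: higher_is_worse
    standard_deleterious_threshold: 0.5
    severe_threshold: 0.80
    boundary_rule: severe_at_threshold
  mutation_assessor:
    direction: higher_is_worse
    standard_deleterious_threshold: 1.9
    severe_threshold: 2.7
    boundary_rule: severe_at_threshold
  fathmm:
    direction: lower_is_worse
    standard_deleterious_threshold: -1.5
    severe_threshold: -8.5
    boundary_rule: severe_beyond_threshold
  condel:
    direction: higher_is_worse
    standard_deleterious_threshold: 0.522
    severe_threshold: 0.672
    boundary_rule: severe_beyond_threshold
  cadd:
    direction: higher_is_worse
    standard_deleterious_threshold: 15.0
    severe_threshold: 27.5
    boundary_rule: severe_at_threshold
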