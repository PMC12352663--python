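# Default life-stage table: age intervals (years) per weight class (lbs).
#
# NON-AUTHORITATIVE default.  These cutoffs follow the common veterinary
# convention that heavier dogs reach maturity and seniority earlier; any
# study should supply its own table matching the guidelines its cohort was
# curated under.  Intervals are half-open [lo, hi): an age exactly on a
# boundary belongs to the older stage.  Weight classes partition (0, inf).
weight_classes:
  - name: small
    weight_lbs: [0, 20]
    stages:
      puppy: [0, 1.0]
      young_adult: [1.0, 6.0]
      mature_adult: [6.0, 10.0]
      senior: [10.0, .inf]
  - name: medium
    weight_lbs: [20, 50]
    stages:
      puppy: [0, 1.0]
      young_adult: [1.0, 5.5]
      mature_adult: [5.5, 9.5]
      senior: [9.5, .inf]
  - name: large
    weight_lbs: [50, 90]
    stages:
      puppy: [0, 1.0]
      young_adult: [1.0, 5.0]
      mature_adult: [5.0, 8.75]
      senior: [8.75, .inf]
  - name: giant
    weight_lbs: [90, .inf]
    stages:
      puppy: [0, 0.75]
      young_adult: [0.75, 4.5]
      mature_adult: [4.5, 7.5]
      senior: [7.5, .inf]
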