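# Named sift presets: the four-parameter sets of the reference protocol.
# Thresholds for carbohydrate/protein/total fat (macro) and
# fiber/saturated fat/sugar (secondary) are percentage points of
# proportion-of-calories difference; the sodium threshold is a relative
# difference fraction. "inf" disables a filter.
first:
  name: first
  macro_threshold: 20
  secondary_threshold: 10
  sodium_threshold: 0.5
  min_fuzzy_score: 0
  use_min_fuzzy: false
  use_fuzzy_optimization: true
first_plus:
  name: first_plus
  macro_threshold: 60
  secondary_threshold: 60
  sodium_threshold: 0.5
  min_fuzzy_score: 50
  use_min_fuzzy: true
  use_fuzzy_optimization: false
second:
  name: second
  macro_threshold: 40
  secondary_threshold: 40
  sodium_threshold: 0.5
  min_fuzzy_score: 0
  use_min_fuzzy: false
  use_fuzzy_optimization: true
third:
  name: third
  macro_threshold: inf
  secondary_threshold: inf
  sodium_threshold: inf
  min_fuzzy_score: 0
  use_min_fuzzy: false
  use_fuzzy_optimization: true
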