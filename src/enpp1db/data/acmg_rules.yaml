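# Default ACMG/AMP evidence-combining configuration.
# Strength classes are derived from the code prefix unless overridden here.
# Combination rules use >= semantics on per-strength counts and are
# evaluated top to bottom within each side; the strongest verdict whose
# requirements are met wins.
strength_overrides: {}
frequency_thresholds:
  ba1: 0.05
  bs1: 0.01
  pm2: 0.0001
  mode: popmax        # which AF field drives the thresholds: overall | popmax
conflict_on_strong_both_sides: true
pathogenic_rules:
  - {verdict: Pathogenic, requires: {very_strong: 1, strong: 1}}
  - {verdict: Pathogenic, requires: {very_strong: 1, moderate: 2}}
  - {verdict: Pathogenic, requires: {very_strong: 1, moderate: 1, supporting: 1}}
  - {verdict: Pathogenic, requires: {very_strong: 1, supporting: 2}}
  - {verdict: Pathogenic, requires: {strong: 2}}
  - {verdict: Pathogenic, requires: {strong: 1, moderate: 3}}
  - {verdict: Pathogenic, requires: {strong: 1, moderate: 2, supporting: 2}}
  - {verdict: Pathogenic, requires: {strong: 1, moderate: 1, supporting: 4}}
  - {verdict: Likely Pathogenic, requires: {very_strong: 1, moderate: 1}}
  - {verdict: Likely Pathogenic, requires: {strong: 1, moderate: 1}}
  - {verdict: Likely Pathogenic, requires: {strong: 1, supporting: 2}}
  - {verdict: Likely Pathogenic, requires: {moderate: 3}}
  - {verdict: Likely Pathogenic, requires: {moderate: 2, supporting: 2}}
  - {verdict: Likely Pathogenic, requires: {moderate: 1, supporting: 4}}
benign_rules:
  - {verdict: Benign, requires: {stand_alone_benign: 1}}
  - {verdict: Benign, requires: {strong_benign: 2}}
  - {verdict: Likely Benign, requires: {strong_benign: 1, supporting_benign: 1}}
  - {verdict: Likely Benign, requires: {supporting_benign: 2}}
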