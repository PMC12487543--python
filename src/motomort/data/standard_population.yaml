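# WHO world standard population 2000-2025 (percent), 80-84 and 85+ collapsed
# into 80+ by summing.  Edit or pass an alternative file with the same keys to
# standardize against a different reference population.
source: WHO world standard 2000-2025
weights:
  0-4: 8.86
  5-9: 8.69
  10-14: 8.60
  15-19: 8.47
  20-24: 8.22
  25-29: 7.93
  30-34: 7.61
  35-39: 7.15
  40-44: 6.59
  45-49: 6.04
  50-54: 5.37
  55-59: 4.55
  60-64: 3.72
  65-69: 2.96
  70-74: 2.21
  75-79: 1.52
  80+: 1.545
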