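{
 "description": "Contingency counts from a reader-agreement study comparing automated sentences (AS) with three radiologists' coded report findings (RR1-3) and their 2-of-3 majority vote (RRm) over 92 memory-clinic cases.",
 "n_cases": 92,
 "n_structures": 23,
 "tissue_presence": {
  "AS-RR1": [45, 12, 15, 20],
  "AS-RR2": [32, 25, 4, 31],
  "AS-RR3": [45, 12, 15, 20]
 },
 "ventricle_presence": {
  "AS-RR1": [5, 30, 0, 57],
  "AS-RR2": [5, 30, 0, 57],
  "AS-RR3": [3, 32, 0, 57]
 },
 "structure_level": {
  "AS-RR1": [23, 94, 98, 1901],
  "AS-RR2": [31, 86, 90, 1909],
  "AS-RR3": [34, 85, 83, 1914],
  "AS-RRm": [28, 89, 56, 1943],
  "RR1-RR2": [39, 82, 82, 1913],
  "RR1-RR3": [36, 85, 83, 1912],
  "RR2-RR3": [42, 79, 76, 1919],
  "RR1-RRm": [59, 64, 25, 1968],
  "RR2-RRm": [64, 58, 20, 1974],
  "RR3-RRm": [61, 58, 23, 1974]
 },
 "counts_order": ["tp", "fp", "fn", "tn"]
}
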