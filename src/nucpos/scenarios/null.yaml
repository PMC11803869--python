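# Null scenario: two independent populations drawn from one composition
# model.  Expect flat delta-W (baseline mean ~0), no significant positions,
# and no counterphase DCC excess.
name: "null"
contig: chrS
contig_length: 20000000
populations:
  reference:
    label: popA
    n_positions: 2000
    occurrence: {law: fixed, value: 50}
    length_weights: {147: 0.6, 148: 0.25, 149: 0.15}
    composition:
      w_baseline: 0.5
      periodic_amplitude: 0.05
      period: 10.4
  comparison:
    label: popB
    derive: independent
    n_positions: 2000
    occurrence: {law: fixed, value: 50}
    length_weights: {147: 0.6, 148: 0.25, 149: 0.15}
    composition:
      w_baseline: 0.5
      periodic_amplitude: 0.05
      period: 10.4
analysis:
  length_filter: {min: 147, max: 149}
  period: 10.4
  baseline_regions: [[10, 29], [35, 74]]
  dcc: {max_dist: 100, min_occurrence: 0}
  classifier: {threshold: 0.1}
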