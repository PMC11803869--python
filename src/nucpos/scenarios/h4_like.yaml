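# H4-tail-like scenario: 30% of comparison dyads are shifted by 10n + 5 bp
# (counterphase, rotational setting inverted), 70% by 10n bp (in-phase).
# Expect a DCC peak at 15 bp and a counterphase mass fraction near 0.30.
name: h4_like
contig: chrS
contig_length: 20000000
populations:
  reference:
    label: wt
    n_positions: 2000
    occurrence: {law: fixed, value: 50}
    length_weights: {147: 0.6, 148: 0.25, 149: 0.15}
    composition:
      w_baseline: 0.5
      periodic_amplitude: 0.1
      period: 10.4
  comparison:
    label: tailless
    derive: shifted
    shifts:
      unmoved: 0.0
      inphase: 0.7
      counterphase: 0.3
      shift_ns: {1: 0.6, 2: 0.4}
analysis:
  length_filter: {min: 147, max: 149}
  period: 10.4
  baseline_regions: [[10, 29], [35, 74]]
  dcc: {max_dist: 100, min_occurrence: 0}
  classifier: {threshold: 0.1}
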