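# H2A-tail-like scenario: the reference population carries a single planted
# adenine-only W bump near SHL +/-4 (height 0.02) that the comparison
# population lacks; comparison dyads are shifted in-phase (10n bp).
# Expect: delta-W peak localized at the SHL +/-4 sites, adenine-only
# asymmetry, and DCC peaks at multiples of 10 bp.
name: h2a_like
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
      periodic_amplitude: 0.05
      period: 10.4
      offpeak_bumps:
        - {shl: 4.0, height: 0.02, width: 3.0, a_over_t_bias: 1.0}
  comparison:
    label: tailless
    derive: shifted
    shifts:
      unmoved: 0.0
      inphase: 1.0
      counterphase: 0.0
      shift_ns: {0: 0.4, 1: 0.4, 2: 0.2}
    composition_override:
      w_baseline: 0.5
      periodic_amplitude: 0.05
      period: 10.4
      offpeak_bumps: []
analysis:
  length_filter: {min: 147, max: 149}
  period: 10.4
  baseline_regions: [[10, 29], [35, 74]]
  dcc: {max_dist: 100, min_occurrence: 0}
  classifier: {threshold: 0.1}
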