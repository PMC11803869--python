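# nucpos

Dyad-aligned sequence analysis of nucleosome populations:

- **fragment_io** — read mapped nucleosome-sized fragments (BED + reference
  FASTA, BAM/SAM, or plain FASTA), apply inclusive length filters
  (e.g. 147–149 bp or 146–148 bp), assign dyad positions
  (`start + floor((L-1)/2)`), and build per-position dyad occurrence tables.
- **profiles** — positional mono- (A, T, W=A+T) and dinucleotide
  (WW = {AA,AT,TA,TT}, SS = {GG,GC,CG,CC}) frequency profiles in the
  dyad-aligned frame (1-based positions 1..147, dyad at 74), with 3-bp
  running averages, dyad symmetrization (plain or complement-aware),
  SHL coordinate mapping (default 10.4 bp/turn), off-peak detection near
  SHL ±4 (P1) and SHL ±1 (P2), and A-vs-T strand asymmetry.
- **differential** — ΔW/ΔA/ΔT profiles (reference minus comparison),
  baseline mean/SD over configurable region unions (default 10–29 ∪ 35–74),
  position-wise two-proportion z-tests with Bonferroni (or BH) correction,
  and the ΔW-vs-W anti-phase correlation diagnostic.
- **dcc** — occurrence-weighted distance cross-correlation between two dyad
  tables (two dyads 20 bp apart occurring 5 and 10 times contribute
  5 × 10 = 50 at distance 20), peak calling, and partition of correlation
  mass into in-phase (10n bp) and counterphase (10n + 5 bp) components.
- **rotational** — per-fragment phase score (Pearson correlation of the
  WW-minus-SS dimer signal against a cosine template with maxima at
  half-integer SHLs) and population classification into canonical /
  anti-WW/SS / weak rotational settings (default threshold 0.1).
- **synthetic** — fragment populations sampled from a position-specific
  composition model with planted, analytically known structure: periodic W
  modulation, localized off-peak bumps with A/T bias, strand splits, length
  jitter (146–149 bp), occurrence laws, and 10n / 10n+5 inter-population
  dyad shifts. Ground truth is emitted as JSON for every run.
- **pipeline / cli** — end-to-end orchestration with packaged scenarios.

## CLI

```bash
# full simulated run of a packaged scenario (null, h2a_like, h4_like)
nucpos run-all --scenario h2a_like --seed 17 --outdir out/

# individual stages
nucpos simulate --scenario h4_like --seed 1 --outdir sim/
nucpos filter frags.fa --format FASTA --min-len 147 --max-len 149 \
    --out-fasta kept.fa --out-dyads dyads.tsv
nucpos profile kept.fa --format FASTA --motif W --smooth --symmetrize \
    --period 10.4 --out w.tsv
nucpos diff --ref wt.w.tsv --cmp mut.w.tsv --regions 10-29,35-74 --out dw.tsv
nucpos dcc --table1 a.dyads.tsv --table2 b.dyads.tsv --max-dist 100 \
    --min-occurrence 0 --out dcc.tsv
nucpos classify kept.fa --format FASTA --threshold 0.1 --out scores.tsv
```

Exit codes: 0 success, 2 configuration error, 3 data error. Real mapped
data enters through `--format BED --reference ref.fa` or `--format BAM`;
the documented occurrence threshold for deep real-data DCC runs is
`--min-occurrence 5000`.

## Conventions

- Coordinates are 0-based half-open internally; reports use 1-based
  nucleosome positions 1..147 with the dyad at position 74.
- Even-length fragments take the 5′-of-center base as dyad; sequences are
  stored reference-forward, and strand-asymmetry analyses refer to that
  strand.
- Fragments containing N are kept at I/O but excluded position-wise from
  profile denominators; longer-than-147 fragments contribute only to the
  positions they cover (coverage-weighted denominators).
- DCC distances are unsigned and each cross-population pair is counted
  once; the occurrence threshold is strictly-greater-than.

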