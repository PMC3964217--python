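# etsgeo

Promoter-architecture analysis of transcription-factor ChIP-Seq data,
centered on the binding geometry of ETS-family motifs.

Gain-of-function mutant p53 (R273H) does not bind DNA sequence-specifically
itself; it is recruited to chromatin through ETS-family factors (ETS1,
GABPA) bound at ETS motifs (canonical 7-mer `CCGGAAG`). This package
implements the analyses that characterize that recruitment from promoter
annotation plus aligned ChIP-Seq reads:

* **Bidirectional promoters** — divergent gene pairs with TSSs back-to-back
  within 1 kb — are detected, and the enrichment of factor binding among
  them is scored with an upper-tail hypergeometric test (regions counted
  once per pair).
* **7-mer over-representation** between bound-promoter sequences and the
  full promoter universe (presence/absence per promoter, either strand,
  hypergeometric upper tail with Bonferroni adjustment).
* **Motif multiplicity**: the probability of binding versus ETS motif copy
  number k per promoter (0–6), with an exponential fit
  P(bound | k) ≈ a·e^(b·k) by log-linear least squares, and the
  replicate-normalized binding *signal* versus k with a linear fit — the
  contrast that distinguishes "more sites, more bound molecules" (GABPA)
  from "more sites, same occupancy" (p53/ETS1).
* **Inverted-pair spacing geometry**: for promoters with exactly two
  opposite-strand motifs, the signed center-to-center distance d ∈
  [−1000, 1000] (negative = face-to-face, positive = back-to-back) is
  summarized as a 100-bp sliding-window density track, and positional
  significance is assigned against a resampling null (N samples with
  replacement at the bound-set size, a normal fitted per position,
  Bonferroni-corrected alpha 0.05/2001).
* **Helical phase**: φ = 360°·(d mod 10.4)/10.4 mapped to (−180°, 180°]
  assuming B-DNA pitch 10.4 bp/turn, with relative binding profiled in 40°
  circular windows and a two-harmonic smooth fit.
* **Binding calls** are non-parametric: coverage normalized to a
  genome-wide mean of 1 read per kb, forward/reverse strand offset estimated
  by correlation and corrected, a signal threshold set on pooled
  negative-control promoters at FDR ≤ 0.005, a promoter called bound only if
  every treatment replicate passes, and replicate-and-control-positive
  promoters removed as bias.

A fully seeded synthetic-data module (`etsgeo.synth`) generates annotation,
promoter sequences with planted motifs, and simulated ChIP reads for three
factor archetypes, so the entire pipeline is testable without external data.

## Worked example

Run the full synthetic pipeline (500 genes, three factors, seed 7):

```python
from etsgeo.pipeline import RunConfig, run

manifest = run(RunConfig(outdir="demo", seed=7, synth={"n_genes": 500}))
print(manifest["exp_fit_p53"])
print(manifest["signal_fit_gabpa"])
```

Output (abridged):

```
offset_p53: 71                      # estimated strand offset, bp
p53 bound: 66 of 500 promoters
exp_fit_p53:    a=0.0154, b=0.774, r=0.895
signal_fit_p53: b=0.024             # flat signal: constant-occupancy law
exp_fit_gabpa:  a=0.0566, b=0.459
signal_fit_gabpa: b=0.254, r=0.955  # signal rises with motif count
```

Reading this: the p53-archetype's probability of binding grows
exponentially with motif copy number (fitted exponent b = 0.77 against a
planted 0.8) while its binding signal stays flat (slope ≈ 0.02), whereas the
GABPA archetype's signal grows with copy number (slope ≈ 0.25) — the two
occupancy laws the analysis is designed to separate. The estimated strand
offset of 71 bp is the coverage-profile separation implied by the simulated
120-bp fragment shift with 50-bp reads (120 − 50 + read-end effects).

The same stages are available from the shell:

```bash
etsgeo synth --seed 7 --out demo_data
etsgeo promoters --genes demo_data/genes.tsv --out promoters.bed --pairs pairs.tsv
etsgeo call --treatment demo_data/reads_p53_rep*.bed \
            --control demo_data/reads_control_rep*.bed \
            --promoters promoters.bed --genome demo_data/genome.fa \
            --fdr 0.005 --out calls.tsv
```

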