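# heterosiskit

A toolkit for dissecting **heterosis (hybrid vigour) in thermal tolerance**
from transcriptomic and cardiac-physiology data, modelled on the analysis of
an interspecific hybrid and its two parental populations sampled under
control and heat-stress conditions.

It is written for researchers who have (or can simulate) three matched
expression datasets — maternal parent (P1), paternal parent (P2), F1 hybrid —
plus heart-rate thermal ramps and splice-junction counts, and who want the
standard heterosis readouts:

- **Dominance-mode classification.** For each gene the degree of dominance
  is the ratio of the dominance deviation to the additive effect,

  d/|a| = (F1 − μ) / |P1 − P2|,  μ = (P1 + P2)/2,

  classified into under-dominance `UDO (−∞,−1.2)`, low-parent dominance
  `LPD [−1.2,−0.8)`, negative partial dominance `NPD [−0.8,−0.2)`, additive
  `ADD [−0.2,0.2]`, positive partial dominance `PPD (0.2,0.8]`, high-parent
  dominance `HPD (0.8,1.2]`, over-dominance `ODO (1.2,∞)`. Genes with
  (numerically) equal parents carry a `PARENT_EQUAL` sentinel instead of a
  ratio. Both the full-gap denominator above and the classical half-gap
  convention (a = |P1−P2|/2, exactly twice the full-gap ratio) are provided.
- **Arrhenius break temperature (ABT).** On Arrhenius axes — ln(heart rate)
  versus 1000/K — cardiac performance is piecewise linear; the break where
  the slope changes is found by exhaustive two-segment least squares and is
  a standard proxy for an ectotherm's upper thermal limit. One-way ANOVA
  compares ABT distributions between groups.
- **Splice divergence.** Percent spliced in per event and sample,
  ψ = (I/lI) / (I/lI + S/lS) from length-normalised inclusion/skipping
  junction counts; events are kept when mean junction reads across samples
  exceed 5, |Δψ| ≥ 0.1 and Benjamini–Hochberg FDR < 0.05.
- **Differential expression (stand-in).** Trimmed-mean-of-M-values (TMM)
  scaling to counts per million, then a Welch t-test on log2(CPM + 0.5)
  with BH adjustment and the usual FDR < 0.05, |log2FC| > 1 cut. This is a
  deliberate, documented stand-in for count-model DE packages — see
  `docs/methods.md`.
- **Integration.** Exact Venn partitions of gene sets, hypergeometric
  over-representation tests against user-supplied pathway maps, and the
  headline overlap: genes simultaneously heat-responsive in all three
  populations, over-dominant in the hybrid, and divergently spliced.
- **Synthetic data with ground truth** for every stage (negative-binomial
  count triads with planted dominance classes, piecewise-Arrhenius cardiac
  ramps, Beta-binomial splice tables), so the whole pipeline installs,
  runs and validates without any external download.

## Worked example

`examples/01_dominance_classification.py` simulates a 2,000-gene triad
(3 replicates per population and condition, negative-binomial dispersion
0.05), classifies the heat condition and checks the calls against the
planted truth:

```text
genes classified: 2000 (0 undetected)
non-additive share: 81.65% of detected genes
class shares over non-additive genes:
  UDO:  28.05%  (458 genes)
  ODO:  21.56%  (352 genes)
  NPD:  17.58%  (287 genes)
  PPD:  15.49%  (253 genes)
  LPD:   9.31%  (152 genes)
  HPD:   8.02%  (131 genes)
planted labels recovered: 97.48% of 1308 classifiable genes
```

The last line is the headline number: with three replicates of realistic
count noise, 97.5 % of genes land in the exact dominance interval they were
planted in. `examples/02_cardiac_abt.py` does the same for cardiac ramps —
a hybrid with a break planted 0.5 °C above one parent and 1.7 °C above the
other is recovered as

```text
one-way ANOVA: F = 126.3, p = 1.96e-12
hybrid thermal gain: +0.51 degC vs parent_B, +1.73 degC vs parent_A
```

The remaining examples cover differential expression, splice-divergence
filtering and the end-to-end pipeline (`heterosiskit run` on the command
line; every output table carries a provenance header and the run manifest
records seed, parameters and checksums).

## Layout

```
src/heterosiskit/   dominance, cardiac, de, splicing, integration,
                    simulate, io, pipeline, cli
examples/           one narrative script per capability
tests/              pytest suite (unit, property and acceptance tests,
                    with independent brute-force oracles in tests/oracles.py)
docs/methods.md     models, assumptions, parameter choices, limitations
```
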