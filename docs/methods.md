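# Methods

This note documents the models implemented by `heterosiskit`, the
assumptions behind them, the defaults and why they were chosen, and what
the synthetic-data generators do and do not emulate.

## Dominance-mode classification

For a gene with parental group means P1, P2 and hybrid mean F1, the degree
of dominance is

    d/|a| = (F1 − μ) / |P1 − P2|,    μ = (P1 + P2)/2.

The seven classification intervals tile the real line with no gaps:
UDO (−∞,−1.2), LPD [−1.2,−0.8), NPD [−0.8,−0.2), ADD [−0.2,0.2],
PPD (0.2,0.8], HPD (0.8,1.2], ODO (1.2,∞). Boundary membership follows the
criteria table this scheme derives from: ±0.2 are additive, 1.2 is
high-parent dominance, −1.2 low-parent dominance.

Two denominator conventions exist in the literature. The `full_gap`
default divides by the full parental difference, exactly as the formula
above is printed in the source scheme; the classical quantitative-genetics
convention (`half_gap`) divides by the additive effect a = |P1 − P2|/2 and
is exactly twice the full-gap ratio. Under `full_gap` a hybrid sitting on
the high parent scores 0.5 (PPD); under `half_gap` it scores 1.0 (HPD).
Because the ±0.8/±1.2 boundaries are most natural under `half_gap`, both
conventions are exposed and every output row carries its convention tag;
the default implements the printed formula and makes the discrepancy
visible rather than silently resolving it.

Genes whose parental gap falls below `epsilon` (default 1e-8 on the
normalised scale) are reported as `PARENT_EQUAL` and excluded from ratio
classification: the criteria explicitly apply only to genes not equally
expressed in the two parents, and no rule is given for the rest. Note that
with replicate noise a *planted* parent-equal gene will rarely be
*measured* as parent-equal — its estimated gap is a small nonzero number
and the resulting ratio is essentially unstable. This is intrinsic to the
statistic, not an implementation artefact, and is why recovery statements
are made over ratio-classifiable genes only.

`classify_matrix` computes group means per condition on TMM-scaled CPM
(`tmm_linear`, default) or on replicate means of log2(CPM + 0.5) (`log2`).
The classification scale is genuinely a free choice of the analyst; the
log2 scale is the one on which the synthetic generator plants truth,
because on the linear scale under-dominance ratios below about −1.5 would
require negative expression means and are unrealisable.

Percentages in `ModeSummary` are computed exactly from integer counts with
decimal arithmetic and rounded half-up to two decimals, so published-style
summary tables reproduce digit for digit. Class shares are quoted over
non-additive genes (the conventional denominator); the non-additive share
itself is quoted over all classified genes.

## Arrhenius break temperature

Heart rate r(T) along a warming ramp is transformed to Arrhenius
coordinates x = 1000/(T + 273.15), y = ln r. The break is located by
exhaustive search: every split leaving at least `min_segment` points per
side is scored by the summed RSS of independent OLS lines fitted to each
side, and the minimising split wins. Design choices:

- the break sits at a data-point boundary and the ABT is reported as the
  temperature of the last cool-side point — the standard grid practice for
  this assay, and exactly testable;
- `min_segment = 3`, because two points fit any line and would produce
  spurious zero-RSS segments;
- no continuity constraint between the segments (two free lines);
- ties in total RSS break toward the lower temperature (a conservative
  thermal-limit estimate);
- the fit is flagged `degenerate` when the RSS profile's range is below
  1e-9 times the total sum of squares of y — a collinear trace has no
  break and its argmin is numerical noise.

At the default ramp (20–38 °C at 0.1 °C per sample, break at 32 °C,
Gaussian noise of 0.05 on ln rate) the estimator's mean absolute error is
about 0.18 °C over 100 simulated ramps, comfortably inside the 0.3 °C
working tolerance used by the acceptance checks; noiseless ramps are
recovered to the grid step. Group comparison is classical one-way ANOVA
with pairwise group-mean differences in °C.

## TMM normalisation and the DE stand-in

Scaling factors follow the trimmed-mean-of-M-values construction: for each
library against a reference, genes positive in both contribute a log-ratio
M and log-abundance A of their count *proportions*; the doubly trimmed set
(30 % of M, 5 % of A — the original method's defaults) is averaged with
inverse-approximate-variance weights and exponentiated. Two deliberate
variants of the textbook construction:

- the reference is the column whose upper-quartile count proportion is
  closest to the mean of those quantiles, and the M-variance weights are
  computed on the proportion scale. Both choices make the factors exactly
  invariant to a uniform rescaling of any library — pure sequencing depth
  carries no composition information — which a depth-dependent reference
  rule or absolute-count weights would break;
- factors are rescaled to geometric mean one and turn library sizes into
  effective sizes, on which CPM are computed.

Differential expression heat-vs-control within one population is a Welch
two-sample t-test on log2(CPM + 0.5) with Benjamini–Hochberg adjustment
and the FDR < 0.05, |log2FC| > 1 rule. **This is a stand-in**: it is not a
negative-binomial count model, has no dispersion shrinkage, and its power
at three replicates is markedly below a dedicated DE package, especially
for weakly expressed genes. It exists because the downstream heterosis
analyses consume only gene *sets*, and a transparent, dependency-free test
with controlled false-discovery behaviour is sufficient and honest for
that purpose. The pseudo-count 0.5 avoids log of zero. Zero-variance
degenerate cases are resolved by their mean difference (identical groups
are null, separated constant groups maximally significant).

## Splice divergence

ψ = (I/lI) / (I/lI + S/lS) length-normalises inclusion and skipping
junction counts (the inclusion isoform spans more junctions; raw counts
would bias ψ upward), with an undefined sentinel when an event has no
coverage. Δψ is mean control ψ minus mean heat ψ over replicates.

Event-level testing is again a stand-in for likelihood frameworks built on
junction-count models: Welch on replicate ψ by default, or a label
permutation test (exhaustive when the number of labelings is at most
1000 — e.g. all 20 of a 3-vs-3 design — random with a fixed seed
otherwise; the identity labeling is always included so p ≥ 1/#labelings).
Events with fewer than two defined ψ per condition are skipped and
reported. The significance filter keeps events with mean of (I + S) across
all samples of the comparison strictly greater than 5 (the "greater than
5" read filter is strict; averaging I+S over all six samples is the most
direct reading of the filter it reproduces, and is configurable), |Δψ| ≥
0.1 (inclusive) and FDR < 0.05 (strict). With three replicates the Welch
stand-in has high power for a planted Δψ of 0.3 when events are tested in
isolation or in effect-rich batches (≥ 95 % over 200 simulated seeds at
depth 200), but limited power inside large, mostly-null batches where the
BH threshold tightens — a known cost of the stand-in, not of the filter.

## Integration

Venn partitions are computed exactly over 2–5 named sets (every union
member assigned to exactly one membership region). Over-representation
uses the one-sided hypergeometric upper tail (the Fisher-exact family)
with BH adjustment across categories; the universe defaults to all
detected genes of the relevant condition, and pathway annotation is always
user-supplied. The headline intersection chains three upstream products:
common DEGs across the three populations ∩ hybrid over-dominant genes ∩
hybrid divergently-spliced genes, with every intermediate size and
membership reported.

## Synthetic data generators

The generators exist to provide ground truth that the analysis stages can
be validated against; their defaults describe a three-population ×
two-condition × three-replicate design.

**Count triads.** Per-gene group means are planted on the log2 CPM-like
scale: a baseline (mid-parent) level ~ Normal(8, 1), a parental gap of at
least `min_parent_gap` (default 1 log2 unit) with a Gamma(5, 1)-distributed
surplus reflecting strongly diverged parental species, and the hybrid at
mid-parent + target × gap, with the target drawn uniformly from an
interior window of its class interval (ADD ±0.10, PPD/NPD ±[0.30, 0.70],
HPD/LPD ±[0.90, 1.10], ODO/UDO ±[2.00, 2.60]). Counts are negative
binomial with shared dispersion (default 0.05) — the standard bulk RNA-seq
noise model and the one the TMM/DE stand-in assumes. A `de_fraction` of
genes receives a heat-response log2 fold-change applied to all three
populations alike, which leaves every dominance ratio untouched.

Three interacting constraints shape the remaining defaults, all of them
identifiability design rather than biology:

- with three replicates at dispersion 0.05, the standard error of the
  estimated ratio is roughly 0.19·sqrt(1.5 + 2t²)/gap log2 units, so
  planted labels are only recoverable when gaps are several log2 units
  wide and targets sit away from interval boundaries; the windows above
  and the gap surplus law follow from that power calculation (the ODO/UDO
  windows sit far beyond 1.2 because their error grows with |t|);
- normalisation needs an unchanged majority: a transcriptome in which
  every gene carries a large planted hybrid deviation has no common scale
  for TMM to recover (the hybrid's library is then dominated by
  over-dominant genes). The default class mix therefore keeps 35 % of
  genes `PARENT_EQUAL` (an invariant housekeeping core) and plants the
  non-additive classes symmetrically (ODO = UDO = 0.13, PPD = NPD = 0.08,
  HPD = LPD = 0.05, ADD = 0.13), and the product |target| × gap is capped
  at 4.5 log2 units;
- every planted mean is clamped into [3.5, 16] log2 CPM so that no group
  mean drowns in pseudo-count or shot noise and none dominates the
  library.

Under these defaults the classifier recovers 96–99 % of planted labels
across seeds, and exactly 100 % on the noise-free expected-mean matrix.
Passing a study-like class mix (heavily over-dominant, no parent-equal
core) is supported but will degrade normalisation, exactly as it would in
real data whose composition violates TMM's assumption.

**Cardiac ramps.** Temperatures rise from 20 to 38 °C in 0.1 °C steps; the
noiseless ln-rate signal is exactly two lines in Arrhenius coordinates
meeting at the planted break (default slopes −8 and +25 ln bpm per
1000/K, i.e. rates rising to the break and collapsing beyond it), plus
i.i.d. Gaussian noise on ln rate — the scale on which the regression
operates. Equal left and right slopes are an allowed degenerate input for
exercising the no-break flag.

**Splice events.** Event types default to 91 % skipped exon and 9 %
mutually exclusive exons, matching the composition reported for
significant heat-response events in the study this emulates. Baseline ψ is
uniform on [0.15, 0.85]; replicate ψ is Beta-distributed around the
condition mean with concentration 100 (replicate sd about 0.04 at
ψ = 0.5); junction totals are Poisson (default mean 100) and inclusion
counts binomial with the length-weighted inclusion probability. A
`divergent_fraction` of events gets a planted between-condition shift of
`true_delta_psi` (default 0.3), directed to stay inside [0.02, 0.98].

**What the generators do not emulate:** read-level artefacts (mapping
bias, positional coverage, duplicates), gene length and GC effects,
correlated gene-gene expression, batch structure, dispersion varying with
expression, isoform-level splice coupling, or real annotation content.
Passing tests therefore demonstrate that the *computations* are correct
and well calibrated under their stated noise models — not that those
models capture every property of real libraries.

## Numerical conventions

- Percentages: exact integer/decimal arithmetic, round half-up, two
  decimals.
- Break-fit RSS via cumulative-moment prefix sums, clipped at zero;
  segment slopes recomputed per side by closed-form OLS.
- BH adjustment via `statsmodels.stats.multitest.multipletests`; ANOVA,
  t-tests and hypergeometric tails via `scipy.stats`.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; the pipeline derives per-stage seeds from
  its single master seed, and reruns with the same configuration are
  byte-identical (checksums recorded in the run manifest).

## Known limitations

- The DE and splicing tests are stand-ins (see above); their per-gene
  p-values should not be compared with count-model outputs.
- The d/|a| statistic is unstable for genes with small parental gaps;
  `PARENT_EQUAL` handles only the exactly-equal case. An optional
  significance gate (`gate_alpha` in `classify_matrix`, off by default)
  reassigns genes whose hybrid replicates are not significantly different
  from the per-replicate mid-parent to ADD; it is off by default because
  the classification scheme this implements states only the ratio
  criteria.
- ABT estimation assumes a single break; traces with two physiological
  transitions will be summarised by whichever split dominates the RSS.
- The acceptance surface for the cardiac and classification stages is
  synthetic-truth recovery; the study's absolute ABT values and DEG/event
  counts require the original animals and raw reads.
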