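# Methods

## The screen model

A pooled CRISPRi dropout screen measures how transcriptional silencing
of each targeted gene changes cellular fitness. A lentiviral sgRNA
library is cloned as a plasmid pool, infected into a dCas9-KRAB cell
line at low multiplicity of infection (so most infected cells carry a
single guide), and the population is grown for a fixed window — here 21
days. Guides silencing growth-essential genes deplete relative to the
plasmid pool; guides silencing growth suppressors enrich. The analysis
problem is to turn two (or more) columns of sequencing counts into
calibrated per-gene calls in the presence of three confounders: unequal
plasmid representation, heterogeneous guide efficacy (many guides
silence poorly or not at all), and sequencing-depth differences between
samples.

## Normalization and fold change

Each sample is normalized to the median of the plasmid reference:
`n(g,s) = c(g,s) / median_s · median_ref`, reference column unchanged.
The per-column division is performed before the common rescale so that
multiplying a sample's raw counts by any positive constant leaves its
normalized values bit-identical (the division of exactly-representable
integers is correctly rounded, and the true quotient is unchanged by a
common factor). The log2 fold change uses a pseudocount of 1 in both
numerator and denominator, making dropout and enrichment symmetric and
bounding the statistic when endpoint counts hit zero. Guides with fewer
than 10 raw plasmid reads are flagged and excluded from gene scoring:
a guide that barely exists in the starting pool has an essentially
unconstrained ratio. One caveat follows from normalizing *to the
reference median*: rescaling the reference column rescales every
normalized column with it, so exact invariance holds for non-reference
columns; with counts in the hundreds the residual pseudocount effect on
the reference side is O(0.01) in lfc.

## Gene scoring against the NTC null

Gene-level inference uses only the non-targeting controls as the null —
no distributional assumption about counts is needed.

1. **Centering.** All fold changes are shifted by the NTC median. This
   matters more than it looks: when strong hits drop out, their
   sequencing reads are reallocated to every surviving guide, shifting
   all lfcs upward together. Without centering, nearly every resampled
   NTC pseudo-gene then has a positive median, so the null collapses to
   the enrichment side while a minority of real neutral genes (whose
   median lands on the dropout side by sampling noise) are scored
   against a null that no longer represents them. In simulation this
   inflated the neutral false-call rate from <1% to several percent,
   up to ~19% in unlucky seeds; with centering it returns to ~0.
2. **Top-3 statistic.** A gene's score is the mean lfc of its 3 most
   extreme guides in the direction of its median lfc (median exactly
   zero counts as dropout, the screen's direction of interest). Taking
   the extremes in the *dominant* direction — not the largest |lfc| —
   avoids averaging a strong dropout signal with an opposite-sign
   outlier, and matches how heterogeneous guide efficacy behaves: with
   ~70% of guides active, the top 3 are typically all active guides.
3. **Empirical null.** 10,000 pseudo-genes are drawn (without
   replacement, seeded) from the NTC lfcs, each of the same size as a
   real gene (10 guides), and scored identically. The gene z-score is
   `(top3 − μ)/σ` over those pseudo-gene scores. |z| > 3 calls a hit;
   the threshold is strict (`z = −3` exactly is not a hit).
4. **Mann-Whitney U.** Each scored gene also gets a two-sided rank-sum
   test of its guide lfcs against all NTC lfcs. The p-value is exact —
   full enumeration of all C(n+m, n) group assignments over pooled
   midranks, which is valid under ties because the permutation
   distribution of U is symmetric about nm/2 — whenever that count is at
   most 10⁵, and otherwise the tie-corrected, continuity-corrected
   normal approximation (scipy). Hit calls use the z threshold alone;
   p-values and BH q-values are informational, mirroring screens that
   report z-threshold hits rather than FDR cuts.

Ranked hit lists sort positive regulators by ascending z (descending
for enrichment), breaking ties by smaller p then gene id, and attach
each hit's top-3 guide lfcs.

## The simulator

The generator reproduces the data-shaping stages of the real protocol
with planted ground truth:

| stage | model | default |
|---|---|---|
| plasmid representation | LogNormal(0, σ) relative abundance | σ = 0.5 |
| founding | Poisson(coverage · a_g/mean(a) · P₁(MOI)) | coverage 1000, MOI 0.3 |
| growth | r_g = ln2/T_d · (1 − effect_g · efficacy_g), deterministic exponential | T_d = 1 day, 21 days |
| guide efficacy | active w.p. 0.7, efficacy 0.9 if active else 0 | — |
| sequencing | Multinomial(depth, ·), Dirichlet-multinomial if overdispersed | depth 500×/guide, dispersion 0 |

P₁(MOI) = MOI·e^(−MOI)/(1−e^(−MOI)) is the probability a transduced
cell carries exactly one integration (zero-truncated Poisson); MOI
enters only as this thinning of founders, since its experimental role is
ensuring single-copy integration. Clone growth is deterministic in
expectation: at ≥1000× coverage, founding (Poisson) and sequencing
(multinomial) sampling dominate the count noise, and omitting cell-level
birth–death keeps a full-scale screen simulation under a second.
Guides with zero founders drop out of the endpoint entirely, mimicking
library bottlenecking. Puromycin selection is not modeled as a phase;
the screen compares day 21 to the plasmid pool, so pre-growth dynamics
are absorbed into founding.

What the simulator does **not** emulate: CRISPRi silencing kinetics
(effects are constant from day 0), off-target activity, guide-position
effects on efficacy, PCR jackpotting beyond the optional
Dirichlet-multinomial overdispersion, and biological replicate
structure beyond independent endpoint redraws. Passing calibration and
recovery tests therefore demonstrates the *statistical machinery* is
sound under a realistic noise budget, not that any particular real
screen meets these assumptions.

Calibration and recovery runs use a screen scaled to 200 lncRNA genes ×
10 guides with 100 NTCs at full coverage (1000×) and depth (500
reads/guide) over 20 seeds — large enough that null tail rates at the
1% level are measurable, small enough that the whole suite runs in
seconds.

## Competition assay

In the mixed-cell validation assay, the odds of being mCherry-positive,
f/(1−f), grow as 2^(t·Δr/T_d) under a constant growth-rate difference
Δr — the fraction itself does not, which is why enrichment is defined on
odds normalized to day 0. E(t) is invariant to total cell number and
E(0) = 1 by construction. Percent decreased growth compares a knockdown
line to the *median* of the control lines (robust to one aberrant
control). The assay simulator inverts exactly: a noiseless series fit
by least squares on log2-odds returns the planted deficit to machine
precision; measurement noise is multiplicative on the measured fraction
with a chosen CV.

## Numerical and interface choices

- Spacer counting is exact string matching at a fixed offset; reads too
  short for the window count as unmatched rather than erroring, and
  matched + unmatched always equals total reads. An optional flag also
  searches the reverse complement.
- Coordinates are 0-based half-open (BED); the TSS of a minus-strand
  gene is end − 1. Category precedence is antisense > intronic >
  bidirectional > intergenic — overlap evidence beats distance evidence —
  and a gene matching no rule raises an error naming it rather than
  being silently binned.
- Duplicate spacers in a user library are an error by default (exact
  counting cannot attribute them) with an explicit opt-out that records
  warnings.
- Every stochastic step (library spacers, simulation, null resampling)
  takes an explicit seed; rerunning any pipeline with the same inputs
  and seeds is byte-identical.

## Known limitations

- The z construction (top-3 against resampled NTC pseudo-genes) is one
  reasonable formalization of "z-score vs non-targeting controls";
  published screens rarely print their exact construction, so absolute z
  values are comparable only within this pipeline.
- With few NTCs (≲50) the pseudo-gene null resamples a small pool and
  its σ becomes noisy; the pipeline runs but calibration degrades.
  The design it emulates carries 700 NTCs for this reason.
- Exact Mann-Whitney enumeration is O(C(n+m, n)); beyond the 10⁵
  cutoff the normal approximation is used, which is slightly
  conservative at the extreme tails for very unbalanced groups.
- A single endpoint vs reference comparison is assumed throughout;
  multi-timepoint trajectory models are out of scope.
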