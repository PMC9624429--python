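# Methods

## The quantity and its pipeline

For gene *g* and condition *c*, relative translation efficiency is

    RTE(g, c) = footprint RPKM(g, c) / mRNA RPKM(g, c),

where RPKM = count · 10⁹ / (CDS length in nt · library total). Because both
assays are depth- and length-normalized, RTE is invariant under independent
rescaling of either library's sequencing depth (asserted as a property
test). RTE is a *relative* measure: RPKM is compositional, so all statements
are about the allocation of reads among genes, not absolute molecule counts.

The pipeline order is: raw counts → RPKM → replicate average (arithmetic
mean per condition) → expression filter → RTE → correlation structure /
differential screens / variability indices → codon features → classifier.
Replicate-averaged values (12 points per gene) enter the cross-condition
correlations, not the 36 replicate columns.

Key parameter defaults:

| parameter | default | rationale |
|---|---|---|
| expression filter | mean RPKM over conditions > 10^1.5 | a single global cut on the condition-averaged level; the `min`-across-conditions convention is selectable |
| fold-change screen | log₂ FC > 4 (or < −4), p < 0.05 | matched to the screen the analysis reproduces; no multiple-testing correction by design (a BH option can be layered on the returned p-values) |
| pseudocount | 0.5 RPKM inside log₂ fold changes | selected genes pass the mRNA filter but footprint RPKM can be 0 |
| t-test flavor | two-sample Welch on log₂ replicate RPKM | "Student's t-test" with no equal-variance guarantee across conditions |
| Spearman ties | average ranks | the common convention |
| scrambles | 50 | pooled null size = genes × scrambles; 50 gives ~10⁵ draws at 2000 genes |
| variability index | variance (ddof=1); Fano = σ²/μ; CV = σ/μ | all three available; labels split at the median of the chosen index, exact-median genes fall in the low class |

## The permutation null and two noise artifacts worth knowing

The null distribution for the per-gene mRNA–RTE correlation permutes each
gene's RTE vector across conditions independently (preserving its value
multiset) and recomputes Spearman rho against the unscrambled mRNA vector.
The pooled null is symmetric with zero mean; at ≤ 8 conditions the module
can also enumerate every permutation exactly, and the sampled null is tested
against that enumeration.

Two structural effects of the RTE ratio deserve explicit mention because
they shape what simulations can and cannot show:

1. **Shared-noise anti-correlation.** RTE contains the mRNA measurement in
   its denominator, so for genes with *no* true regulation the sampling
   noise alone drives corr(mRNA, RTE) toward −1/√2 when both assays are
   equally noisy — a scale-free effect that does not vanish at high depth.
   An all-stable synthetic population therefore shows a strongly negative
   median rho, while its scrambled null remains centered at zero. This is
   precisely why the permutation null, which preserves marginals while
   destroying the pairing, is the right reference for the actual
   distribution.
2. **Compositional coupling.** In a mixed population the per-condition
   normalization totals fluctuate with the strongly regulated genes, adding
   a small common positive component to every stable gene's correlation.
   In simulations at the default design this leaves stable-class medians
   within ±0.2 while concordant/antagonistic medians sit beyond ±0.5.

## Codon analyses

A gene's codon profile is its 64-vector of codon proportions (lexicographic
order, stop codons included, counted over in-frame codons from position 0).
The background is the pooled codon count over the analyzed gene set
(length-weighted; an equal-gene-weight alternative is selectable), and
centered profiles are elementwise differences. Group contrasts compare the
equal-gene-weight mean centered profiles of two gene sets by Spearman rho
over the 64 entries; pathway contrasts exclude shared genes first.

Two rank-geometry facts matter for interpreting contrasts:

- With only *k* informative codons among 64, the Spearman correlation
  between group mean profiles is bounded: four concordant-extreme codons
  contribute roughly −60/341 ≈ −0.18 however strong the tilt. Reproducing a
  strong contrast (≈ −0.55 and beyond) requires class-linked usage
  differences across many codons — which real genomes have. The synthetic
  CDS generator therefore tilts a *dense* default set (12 A/T-ending codons
  for the high-variability class, led by AAA and GAT; 12 G/C-ending codons
  for the low-variability class, led by CGT and CTG; none of the nine rare
  codons AGA, AGG, ATA, CCC, CGA, CGG, CTA, GGA, TTA, whose neutrality is a
  tested invariant). Narrow tilts remain available for oracles that target
  specific codons.
- Centering by an in-sample background makes the *sampling noise* of
  disjoint gene-set mean profiles anti-correlated (exactly −0.5 when the two
  sets exhaust the background). On real data the biological gene-to-gene
  codon variation dominates this; in synthetic constructions where genes
  within a class are exchangeable it can dominate instead, so constructions
  asserting positive between-set similarity use dense tilts.

## The variability classifier

Labels are a median split of the chosen variability index. Each evaluation
repeat draws a plain (unstratified) random 80/20 split — classes are
near-balanced by construction — trains a 200-tree random forest (minimum
leaf 5, √p features per split), and scores the held-out genes. Sensitivity,
specificity, and accuracy use threshold 0.5 on the vote fraction; AUC is
trapezoidal; ROC curves are vertically averaged on a fixed 101-point
false-positive-rate grid; importances are mean impurity decrease (an
approximation when comparing to permutation-style rankings). Degenerate
repeats (single-class training split) are discarded and redrawn so exactly
`n_repeats` valid repeats aggregate; reported SDs are over repeats and thus
include retraining variation. Chance-level calibration on permuted labels
averages over *fresh* permutations (one per repeat): a single fixed random
labeling retains a labeling-specific chance association with the features
and biases the AUC above 0.5.

## Footprint processing

Reads outside 20–45 nt are removed first. Offset inference histograms the
distance from each read's 3′ end to the first nucleotide of the start and of
the stop codon (±40 nt windows) and takes each argmax; ties go to the
smallest offset and are flagged. The A-site offset defaults to the
stop-codon argmax; a configurable `stop_peak_correction` (default 0)
subtracts a one-nucleotide boundary convention under which a 12 nt stop peak
maps to an 11 nt A-site offset — the two conventions differ by one
nucleotide and the module reports both argmaxes rather than enforcing
consistency. The P site is the A site plus one codon. A-site assignment
(nt = 3′ − offset, codon = ⌊(nt − start)/3⌋) drops reads outside the CDS
with counts, and every input read is exactly one of length-filtered,
out-of-bounds, or assigned (a conservation property test). Metagene profiles
divide each gene's per-codon density by that gene's mean before averaging,
so highly expressed genes do not dominate; genes shorter than twice the
profile length are excluded and counted. The per-codon, per-gene-mean
normalization is this package's convention.

## Physiology

Total ribosomes per average cell: Rt = V_c·C_p·RPR·f_r/m_r (cell volume m³,
protein concentration g/m³, RNA-to-protein mass ratio, rRNA mass fraction of
total RNA, rRNA mass per ribosome in g) — degree-1 homogeneous in each
parameter, which the tests assert. Polysome traces are corrected by the mean
of the final 50 readings (negatives retained, not clipped), then a·exp(−kx)
is least-squares fit over a user-chosen leading window and subtracted
everywhere; peak areas are trapezoidal over user-specified non-overlapping
windows (window choice was interactive in the original workflow, so an
automatic proposal is deliberately not authoritative). The 70S peak is
decomposed into two Gaussians; the lower-sedimentation component is labelled
free (high potassium shifts mRNA-free 70S to lower density), and coincident
means fall back to a single-peak report with a warning. Elongation rate fits
a line to √(accumulated signal) versus time past onset — the accumulated
first-enzyme signal grows quadratically, so the √-space fit is linear with
x-intercept equal to the measured delay T — and returns
lacZ length / (T − 10 s); raw-space fitting is selectable. The lacZ length
default is 1024 aa and configurable.

## What the synthetic data does and does not emulate

The generator reproduces the *statistical* structure the analysis consumes:
the 12-condition × 3-replicate design (C-/N-/P-limited chemostats at 0.1 and
0.6 h⁻¹, two batch cultures, two mutant chemostats), lognormal baseline
expression, per-condition lognormal multipliers with sign structure per
regulation class (σ = effect_size_log2·ln 2, default 2 log₂ units),
negative-binomial counts with variance μ + φμ² (φ = 0.05 by default, a
typical bulk-RNA-seq replicate dispersion; the design has no published
replicate-dispersion estimate), class-linked codon tilts via exponential
tilting of a uniform sense-codon background, footprint reads with a known
3′ offset and elevated start/stop density, and traces/series with recorded
truth. It does not emulate amino-acid plausibility, Shine–Dalgarno motifs,
mRNA structure, rRNA contamination, operon structure, or condition-specific
tRNA pools — so passing tests demonstrate correctness of the *computations*
and recoverability of constructed effects, not biological realism of any
particular parameter value.

Problem sizes used by the test suite and the acceptance script — 2000 genes
for pipeline-level statistics, 1000 for classifier calibration, 600 for
module fixtures, 100 evaluation repeats — are the package's chosen
desk-scale defaults; all are parameters.

## Known limitations

- The expression-filter convention (mean vs per-condition minimum) changes
  the retained gene set; both are implemented, `mean` is the default.
- RPKM-level analyses inherit compositionality; no absolute calibration to
  protein-synthesis rates is attempted.
- The per-gene fold-change screen is deliberately uncorrected for multiple
  testing, mirroring the analysis it reproduces.
- Offset inference assumes elevated ribosome density at start/stop codons;
  data lacking those peaks will produce flagged ties or errors rather than
  estimates.
- The pause-motif feature block is empty by default; users supply motif
  lists, as no canonical set is bundled.
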