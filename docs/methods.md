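# Methods

## The model

Expression of gene *i* in strain *j* and replicate *k* is modeled as
y_{ijk} = β_{ij} + ε_{ijk} on the log2-CPM scale, where *j* ranges over
the four genotypes of the 2×2 TF × cofactor factorial (double deletion,
cofactor only, TF only, both). β_{ij} is estimated as the mean over
replicates; the pooled residual variance s_i² has d = n − 4 degrees of
freedom.

Because per-gene variances from few replicates are noisy, they are
shrunk toward a common prior: (d0, s0²) are estimated by matching the
first two moments of log s² to a scaled-F distribution (digamma /
trigamma inversion, Newton-free via bracketed root finding), and the
moderated variance is the df-weighted average
s̃² = (d0·s0² + d·s²)/(d0 + d). When the observed spread of log s² is no
larger than its pure sampling spread, d0 = ∞ and every s̃² = s0².

Induction is tested against the composite null |log2 FC| ≤ lfc (default
lfc = 1, i.e. fold change ≤ 2):

p = P(T > (|logFC| − lfc)/se) + P(T > (|logFC| + lfc)/se), T ~ t(d0+d).

This is conservative at the boundary (measured rejection 0.049 at
nominal 0.05). p-values are pooled across *all* contrasts before
Benjamini–Hochberg adjustment, so one raw-p cutoff applies to every
comparison; a gene is "induced" when q < 0.05 with positive fold change
(which forces logFC > lfc).

The mutant-cycle components are the three factorial contrasts listed in
the README. They are linear in β, so X_TF + X_cof + CO equals the full
induction exactly and adding a constant to all four genotype means of a
gene changes nothing. Component standard errors reuse s̃² with leverage
Σ 1/n_j over the genotypes entering the contrast (two for the solo
components, four for CO). Classes are a Ward cut (k = 3) on the raw
(unstandardized) component estimates — magnitudes are meaningful, so no
z-scoring — with clusters labeled by a centroid rule: class I maximizes
X_TF − |CO|, class II maximizes CO − X_TF, class III is the remainder.
Component p-values are reported unadjusted (a −log10 p companion table
accompanies the clipped display table; stored values are never clipped).

## Normalization choices

- Low-expression filter: a gene is removed iff it has CPM < 1 in at
  least 3 samples, with CPM computed on raw library sizes before TMM.
  With two replicates per genotype this is read per-sample, not
  per-genotype-group.
- TMM: reference sample = the one whose upper-quartile count fraction is
  closest to the across-sample mean; per-gene log-ratios M weighted by
  inverse asymptotic (binomial delta-method) variance; genes with a zero
  in either library excluded; double trim of 30% on each side of M and
  5% on each side of A; factors rescaled to geometric mean 1. A sample
  sharing no genes with the reference gets factor 1 with a warning.
- log-CPM: log2((count + 0.5)/(lib·factor + 1)·10⁶). The pseudocount
  0.5 is the convention of the transform this follows. Precision
  weights on the mean–variance trend are deliberately not applied: at
  two replicates per genotype they change the genotype means little, and
  the unweighted model keeps every estimate a closed-form mean. This is
  the one simplification of the published-style workflow and is the
  natural extension point.

## ChIP analysis

Tracks are scaled to genome-wide mean coverage exactly 1. Fold
enrichment is (tf + ε)/(mock + ε) with ε = 10⁻³ guarding against
division by zero. The peak caller thresholds FE ≥ 3, discards runs
shorter than 5 bp (isolated single-bp noise excursions would otherwise
chain across merge gaps into spurious wide calls), merges surviving runs
across gaps ≤ 100 bp, drops merged runs narrower than 50 bp, and takes
the leftmost argmax as summit. It replaces the model-based callers and
the manual curation used on real data, and is adequate only for the
clean synthetic tracks it is paired with — a deliberate fidelity limit.

Occupancy ratios are max-over-peak of the normalized track without the
cofactor over the same with it (log2, ε-floored). Co-binding is any-bp
interval overlap with the cofactor's peak set (the biological notion of
"binds next to" has no canonical distance; overlap of called peaks is
the strictest reading and is configurable). A co-bound peak is
*dependent* when its height drops more than `fold_cut` = 2-fold.

Note that for a Gaussian bump of height h over baseline 1, the summit
ratio under planted attenuation α is (1 + αh)/(1 + h), which approaches
α only for tall peaks. The synthetic ChIP truth therefore draws α away
from the 0.5 decision boundary (dependent 0.10–0.35, independent
0.70–1.00) at heights 6–12, so planted labels coincide with the
>2-fold rule at realistic enrichments.

## Motif grading

CACGTG is palindromic, so a single forward scan counts each site once
and the Hamming grade is strand-invariant; N bases always mismatch
(conservative). A peak's grade is the minimum over all windows under the
peak interval (anywhere under the peak, not only at the summit). Random
sequence contains ~33 two-mismatch windows per kb, so a grade of 2 is
weak evidence by itself; grades 0–1 are the informative ones, and the
synthetic promoters are scrubbed so no background window sits within one
mismatch of the consensus.

## Target integration

Each peak is assigned to the nearest gene on each side, kept only when
the peak lies 5′ of that gene's TSS on its strand (divergent promoters
yield two assignments); peaks overlapping any CDS are dropped unless
`allow_cds`. No distance cap is applied by default (configurable via
`max_dist`). Functional categories per (peak, gene): induced in both
cofactor states → *induced-with-or-without*; only with →
*induced-only-with-cofactor*; otherwise *non-functional*; genes filtered
out upstream are *NA* and excluded from denominators. A peak serving two
genes takes its most functional category. Printed percentages use
half-up rounding (0 digits unless stated). Shared-gene sets for
dependence ratios are computed (genes induced by every variant under
comparison), never hard-coded.

## The synthetic-data generator

What it emulates: a compact yeast-like genome (2 kb gene slots, 1 kb
promoters, 500 bp CDS) with E-box sites of controlled grade planted
centrally in promoters; negative-binomial counts (variance μ + φμ²,
default φ = 0.05 — a typical replicate-level RNA-seq dispersion) whose
expected log2 expression is baseline + X_TF·[TF] + X_cof·[cof] +
CO·[both], renormalized to per-library proportions at 5×10⁶ reads per
sample (a realistic yeast RNA-seq depth); Gaussian ChIP peaks (σ = 50 bp
over baseline 1) with co-binding and attenuation drawn to the study's
proportions (77% co-bound, 14/77 dependent).

What it does not emulate: read-level sequencing, GC/mappability bias,
correlated replicate structure, fragment-size effects, nucleosome
landscapes, or sequence composition realism. Passing benchmarks
therefore demonstrates the *statistical machinery* recovers planted
truth under the stated noise model, not that the pipeline is robust to
every artifact of real libraries.

Default study conditions: 2 replicates per genotype, 10% of genes
induced with solo/collaborative effects U(1, 5) log2 (class III mixes
U(0.5, 2)), baselines U(3, 9) log2. All randomness flows from the seed
argument; same seed ⇒ byte-identical outputs.

## Numerical and benchmark notes

- Trigamma inversion uses bracketed root finding on [10⁻⁸, 10⁸];
  degenerate all-equal variances take the d0 = ∞ path without failure.
- Summit ties break leftmost; BH ties use the standard cumulative-
  minimum step-up; se = 0 in the threshold test maps to p ∈ {0, 1} by
  whether |logFC| clears the threshold.
- Component recovery at the default conditions measures MAE ≈ 0.27 for
  the solo components and ≈ 0.38 for CO (genes with baseline ≥ 50 CPM).
  The gap is structural: CO is a four-mean interaction contrast with
  twice the leverage of a solo contrast, and at φ = 0.05 the per-sample
  log2 noise floor is √trigamma(1/φ)/ln 2 ≈ 0.33 regardless of depth, so
  sd(ĈO) ≈ 0.46 with two replicates. Averaging over more replicates is
  the only way down.
- The boundary calibration of the threshold test is measured by
  averaging many 1,000-gene simulations because a single simulation's
  Monte Carlo error (±0.007) exceeds the conservatism margin (~0.001).
- Benchmark problem sizes (2,000-gene count matrices, 0.5–2 Mb toy
  genomes, 20 seeds) were chosen so each planted-truth benchmark
  measures its quantity with small Monte Carlo error while the whole
  suite stays comfortably interactive.
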