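# Methods

## Data model and conventions

Coordinates are 1-based physical positions.  The interval between consecutive
markers at `p_i` and `p_{i+1}` is the half-open span `[p_i, p_{i+1})` of
length `p_{i+1} − p_i`, which matches the use of physical distance between
SNP markers as the Poisson exposure.  External BED/bedGraph tracks are
0-based half-open and are converted at the reader boundary (round-trip
tested).  The sorting indel splits the region into a left and a right side;
the span between the last left marker and the first right marker is not
genotypable on either side's array and is not an interval.

## Breakpoint calling and QC

A retained strain has exactly one A→B or B→A transition among its non-missing
calls; the breakpoint interval runs from the last marker before the
transition to the first after it, skipping missing calls.  Exclusion rules
(with reason codes): more than `max_missing` (default 2) missing calls; any
heterozygous call — a single H exactly at the transition is classed
`ambiguous_at_breakpoint`, any other H run `het_stretch`; two or more
transitions (`double_recombinant`); no transition (`non_recombinant`).  A
breakpoint spanning several intervals because of missing flanking calls is
assigned to the interval containing the span midpoint; the conservative
alternative (drop the strain) costs information and the midpoint rule is
unbiased for isolated missing calls, so midpoint is the default.

25-kb rebinning is greedy by length: consecutive unmasked intervals are
merged until the running length reaches the 25,000-bp target, the trailing
short bin is merged backward, and bins below the three-event minimum are
merged with their smaller neighbor.  Masked intervals break runs and are
carried through unchanged, so bin boundaries always fall on marker positions.

## Count model

Crossover counts per interval are Poisson with log link and offset
`log(length)`; the side indicator is part of every model because the
genotyping design sampled equal numbers of strains per side while the
underlying crossover totals differ, making raw side rates meaningless.
Fitting is IRLS with step-halving, convergence at a relative deviance change
below 1e-10 or 100 iterations; non-convergence is flagged, never silent.
The fit is written in-package (a ~40-line IRLS) because the motif permutation
null refits thousands of tiny three-parameter models per permutation and a
batched, vectorized solver is two orders of magnitude faster than repeated
general-purpose GLM calls; the batched path is tested for equality with the
scalar path, and the scalar path against statsmodels' GLM to 1e-6.

Deviance explained by a feature is measured against the offset+side base
model (not intercept-only), so deviance attributable to the sampling design
is never credited to a feature.  Feature covariates enter as per-bp densities
(count/length), which decouples feature abundance from exposure; both this
and the baseline choice are configurable.

## Heterogeneity

The Gini coefficient orders unmasked intervals by per-bp rate (stable sort
for ties), accumulates cumulative physical and genetic fractions, and
integrates the Lorenz curve by the trapezoid rule.  The uniformity null
conditions on observed per-side totals (multinomial over intervals with
probabilities proportional to length): the totals are design-fixed, so a
Poisson-total null would overstate variance.  Because the offset+side model
has the closed-form MLE rate `total_side / length_side`, simulated residual
deviances are computed in closed form rather than by refitting (tested equal
to the IRLS fit), which makes 10,000-simulation nulls instantaneous.
Monte-Carlo p-values use the add-one (Davison–Hinkley) convention
throughout, making them super-uniform under the null.

The cross-comparison KS test places binned counts at interval right
boundaries — the per-strain data are interval-censored, so no finer position
convention exists — and uses the asymptotic two-sided p, appropriate for
per-cross totals in the hundreds.

## Constant-rate domains

The K-domain model gives each of K contiguous domains (boundaries on marker
positions) a single rate; the domain MLE rate is pooled count / pooled
length.  Rather than approximating with constrained splines, the segmentation
is solved exactly by dynamic programming over interval boundaries
(O(K·n²)), verified against exhaustive enumeration for small n.  The
statistic for adequacy is the K-domain residual deviance (twice the gap to
the saturated model); its null is a parametric bootstrap from the fitted
K-domain model, conditioned on the side total, each replicate refitted at K.
The minimal adequate K is the smallest K with add-one p ≥ alpha (default
0.05), searched up to K_max = 40.  A K-vs-K+1 comparison is available via
`lrt_statistic` differences but the saturated comparison is the default.

## Gamma landscapes

Per-kilobase rates are drawn i.i.d. from gamma(shape) and rescaled to an
expected total; within a bin the rate is constant and crossover positions are
uniform.  Simulated crossovers are censored into the marker intervals so
simulated and observed Ginis are comparable.  Shape is fitted to an observed
Gini by geometric bisection (the mean simulated Gini is decreasing in shape;
gamma CV = 1/√k), tolerance |ΔGini| < 0.002; the 95% CI is the range of grid
shapes whose simulated 2.5–97.5% Gini interval covers the observed value.
The CI grid is geometric with a configurable step (default 0.25 in log-shape,
i.e. ~28% multiplicative steps) — a compromise between resolution and the
cost of one full simulation set per grid point.  The expected max/mean rate
multiple is the Monte-Carlo mean over replicates of (max per-kb rate)/(sample
mean rate); with ≥590 bins the sample mean is indistinguishable from the
distribution mean.  Bin counts per side default to side span / 1 kb.

## Motif scan

Double-strand k-mers are canonicalized to the lexicographic minimum of motif
and reverse complement (4^k/2 + palindromes/2 entries; 136 at k = 4, 2080 at
k = 6).  Counting is a single greedy left-to-right pass in which a match of
either strand's form consumes k bases; N never matches.  The default scan
range is 4–6 bp (where real associations at this data scale are detectable);
7–8 bp are available behind the `k_range` argument at correspondingly higher
cost.  The permutation null shuffles the nucleotides within every unmasked
interval — exactly preserving per-interval base composition, strictly
stronger than preserving GC fraction alone and exactly reproducible — then
recounts and refits every motif; the per-permutation minimum residual
deviance per motif-length class is the family-wise summary.  A motif's
permutation p is the add-one fraction of permutations whose class minimum is
at most the motif's observed residual deviance; "additional deviance
explained" subtracts the permutation-mean best-motif deviance explained (the
selection effect, which is substantial even under the null).  Motif pairs are
fitted jointly (two densities) over a subset whose size is checked against a
budget before any computation; a self-pair is flagged collinear and equals
the single fit.  Degenerate (absent or constant-density) motifs are flagged
and excluded from minima.

## Genomic correlates

GC is computed from sequence with N excluded from the denominator.  Track
aggregation is length-weighted mean over the covered part (coverage gaps are
warned about) or overlap-prorated density.  Gene features come from a
simplified gene table (id, start, end, strand): gene density is TSS per bp,
"proportion intergenic" the bp fraction between nonconvergently transcribed
neighbor pairs; with no exon structure in the table, the intron-content
covariate is proxied by gene-body bp fraction.  The univariate scan reports
uncorrected p-values (a Bonferroni column is emitted as an extra); a control
covariate (e.g. an IgG binding control for nucleosome occupancy) can be
attached per feature, in which case the feature is credited only with its
increment over base+control.  Correlation clustering is Pearson, average
linkage on 1 − r.

## Synthetic data

The default scenario emulates the target study design: a 1.41-Mb shared
region (left side 820 kb, right side 590 kb around the indel), 139+138
markers with lognormal gap jitter tuned to a ~4.4-kb median and ~5.1-kb mean
spacing, per-cross (left, right) crossover totals (387, 243) and (244, 241),
gamma landscapes at shapes 1.70/3.57, and 36% GC (a chromosome-arm value for
the organism).  Noise channels — per-call missingness, het-run contamination,
double-recombinant injection (~1% in the real design) — are off by default
and switched on per test.  Truth records (every true breakpoint, planted
effect) are emitted alongside, so generators are oracles rather than black
boxes.

What the generator does *not* emulate: genotyping-intensity artifacts,
linkage between marker placement and sequence features, realistic
polymorphism (the genome is i.i.d. at fixed GC), and crossover interference
beyond the one-crossover-per-strain design.  Passing tests therefore
demonstrate correctness of the estimators under the design's sampling
structure, not robustness to every artifact of real genotyping data.

## Problem sizes in the test suite

Monte-Carlo stages run at sizes chosen for a fast desk loop: uniformity nulls
at 99–999 simulations (closed-form deviance makes larger counts cheap),
segmentation bootstraps at 99–199 simulations per K, gamma-shape fits at
150–500 simulations per evaluation, motif permutation nulls at 99
permutations over ~15–53 intervals of 300–450 bp, and the max-rate-multiple
estimate at 10,000 replicates.  All are arguments, not constants; the
production-scale counts (10,000 uniformity simulations, 1000 sequence
permutations, 5000 gamma simulations per shape, 100,000 bootstrap
simulations per segmentation model) are reachable through the same
interfaces.

## Known limitations

- The segmentation engine is exact-ML piecewise-constant fitting, not a
  spline approximation; on real data the minimal adequate domain count can
  differ by a few domains from spline-based fits of the same model class.
- The 25-kb rebinning rule is greedy-by-length; a pre-binned table from an
  authoritative source can be read directly, bypassing `rebin_25kb`.
- KS on interval-censored counts is conservative at coarse marker spacing.
- `scan_motif_pairs` does not enumerate the full pair space of the 4–8 bp
  catalog; it requires an explicit subset.
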