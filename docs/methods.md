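# Methods

`recombscape` characterises meiotic recombination in half-sib livestock
cohorts genotyped on SNP panels — the design typical of layer-chicken
breeding programmes, where many parents each have a handful of genotyped
offspring.  The pipeline has five stages: SNP quality control, crossover
detection within half-sib families, window recombination maps with
hotspot/coldspot labels and per-parent summaries (GRN, GHU), genome-feature
association, and quantitative genetics of the recombination phenotype
(repeatability animal model and Bayesian whole-genome regression).  A
synthetic-data generator with complete ground truth stands in for
proprietary breeding-program genotypes and drives every test.

## Crossover detection

Within a half-sib family (a focal parent with >= 2 genotyped offspring),
detection proceeds in three steps.

**Transmitted-allele deduction.**  At every marker where the focal parent
is heterozygous, the allele it transmitted to an offspring is deduced by
Mendelian elimination: a homozygous offspring fixes it directly; a
heterozygous offspring fixes it only when the other parent is homozygous.
Everything else is unknown.  Roughly 70–80% of focal-het markers are
deducible per offspring at the allele frequencies of commercial lines.

**Family phasing.**  The focal parent's phase — which haplotype carries the
counted allele at each heterozygous marker — is reconstructed by exact
minimum-recombinant dynamic programming over offspring origin-state
vectors.  Each marker's binary phase choice updates the origins of the
offspring deduced there at a cost of one per implied crossover; blocks of
markers are committed as soon as a unique minimum-cost state leads the
runner-up by at least two crossovers.  Three ambiguity classes are handled
explicitly:

* *Position ambiguity* — co-optimal paths that agree on the final origins
  but place a switch at different markers leave those markers uncoded, so
  the crossover is localised between the flanking committed markers rather
  than assigned arbitrarily.
* *Attribution ambiguity* — in a two-offspring family a single switch in
  the relative-origin sequence cannot be assigned to a specific offspring;
  it is attributed arbitrarily, which leaves the parent-level event count
  and interval position correct.
* *Knots* — two offspring recombining within the same uninformative gap
  are indistinguishable from the complementary pair recombining (both
  reconstructions imply two crossovers).  The block is abandoned, a fresh
  phase segment starts, and the blocked markers are replayed in the new
  segment so events downstream of the knot survive.  Knot events are lost;
  on desk-scale simulations this costs ~2–3% of true crossovers and is the
  main driver of detection incompleteness after marker density.

The global hapA/hapB swap is unobservable per phase segment and left
arbitrary; all reported quantities are invariant to it.  Intervals are
never called across segment boundaries.

**Decoding.**  Each offspring's origin sequence is decoded by an exact
two-state most-probable-path (Viterbi) pass with a Haldane-style switch
prior (`cm_per_mb`, default 3.0) and a miscode probability
`smoothing_error` (default 0.005), which absorbs isolated single-marker
flips produced by genotyping error.  With `smoothing_error = 0` every
adjacent pair of opposite origins yields an interval; this is the matched
setting for error-free data, where an isolated flip is a genuine close
double crossover.  Every state change between consecutive coded markers
becomes a recombination interval `[left marker, right marker]` with length
`r_i` in Mb.

**Map-error scan.**  Misplaced markers betray themselves either as
singleton origin flips (origin differs from both flanking markers) or as
phase conflicts (the transmitted allele was deduced but family phasing
could not assign a consistent origin).  The per-marker confidence score is
`1 − max(flip rate, conflict rate, Mendelian inconsistency rate)`; markers
scoring below 0.9 are removed and detection re-runs once (a single
cleaning pass, not iterated to a fixed point).  Markers with fewer than 20
deduced meioses keep score 1 and are flagged unscored.

Double crossovers between adjacent deduced markers are undetectable by
construction and are not corrected for.

## Window maps and parent summaries

Windows are 0-based half-open `[k·500000, (k+1)·500000)`; the terminal
partial window is kept so no base pair is unassigned.  The window rate is

    c_w = ( Σ_i x_i / r_i ) / T

where `x_i` is the Mb overlap of interval `i` with the window, `r_i` the
interval length, and `T` the number of parent–offspring pairs in the
stratum (all, sires, dams).  Because `Σ_w x_i = r_i`, window rates conserve
event counts exactly: the chromosome sum of `c_w` equals (events on that
chromosome)/T.

Hotspots are the top `ceil(0.10 × windows)` windows by `c_w` per
chromosome, ranked among windows that carry at least one mapped SNP, ties
broken toward the smaller genomic position, and only windows with positive
rate qualify; coldspots are SNP-covered windows with zero accumulated
event mass.  GRN is a parent's mean detected event count per meiosis over
all autosomes, counting zero-event offspring.  GHU is the parent's
fractional event mass inside hotspot windows divided by its event count —
fractional `x_i/r_i` attribution, consistent with the rate definition
(midpoint attribution would discretise the same quantity).  A parent with
no events has missing GHU, not zero.

When hotspot labels are derived from the same cohort whose GHU is
evaluated, the top-decile selection on noisy window ranks inflates GHU
above the labelled genome fraction; the calibration test therefore labels
windows from one half of the parents and evaluates GHU on the other half.

## Genomic features

GC fraction per window excludes N bases from the denominator.  CpG-island
density is the fraction of the window covered by islands, from a user BED
or the built-in classical scanner (200-bp windows with GC >= 0.5 and
observed/expected CpG >= 0.6, merged).  Common-haplotype-allele counts are
distinct marker strings at >= 1% frequency among haplotype strands (truth
strands in simulation mode).  LD pruning is greedy within non-overlapping
50-marker blocks: any pair with dosage r² > 0.5 drops the lower-MAF member
(ties: the later position); monomorphic markers are never tested.  The
genomic inbreeding coefficient is F = (O − E)/(L − E) with the expected
heterozygosity per marker corrected by n/(n−1) for finite samples.
Correlations pool windows across chromosomes (pairwise deletion, missing
below three pairs) and also report per-chromosome means and the
macro (1–5) / intermediate (6–10) / micro (11–28) class means.

## Quantitative genetics

**Repeatability model.**  Per-meiosis counts are analysed with
`y = Xb + Zu + Zp + e`, sex means fixed, `Var(u) = A σ²a` from the
pedigree numerator relationship matrix (tabular method, `A_ii = 1 + F_i`),
`Var(p) = I σ²p`, `Var(e) = I σ²e`.  Inference is a blocked Gibbs sampler —
flat prior on `b`, scaled-inverse-chi-square priors (df 4, scale var(y)/6)
on the components — reporting posterior means and SDs of `h²` and the
repeatability `t`; a one-way-ANOVA method-of-moments estimate of `t`
serves as a cross-check.  Fitting a Gibbs sampler rather than REML keeps a
single inference engine across the package and yields posterior SDs
directly; posterior means of h²/t carry a small upward bias under null
variances because the components live on the positive half-line.
Heritability estimated from *detected* counts is attenuated relative to
the generating value because missed events act as extra binomial thinning
noise (the 60-Mb demo recovers ≈0.13 when the generator was calibrated to
0.17 on true counts).

**Record weights.**  Parent means of n records enter the marker models
with record residual variance `σ²e / En`, where

    En = (1 − h²) / ( (1 + (n − 1) t)/n − h² ),

which reduces to `En = n` exactly when `t = h²` and to 1 at `n = 1`.

**Whole-genome regression.**  `y = Xb + Mα + e` with records weighted as
above (rows scaled by √w internally).  BayesC(π = 0) gives every SNP a
common normal effect variance with a scaled-inverse-chi-square prior;
BayesB gives each SNP a point mass at zero (prior fraction π) plus its own
variance with prior df ν_a = 4.2 and scale derived from the genetic
variance: per-marker variance `σ²α = σ²a / ((1 − π) Σ_j 2 p_j q_j)`,
`S²a = σ²α (ν_a − 2)/ν_a`.  Genetic and residual variances used for the
scales come from the pedigree repeatability fit.  The inclusion indicator
is sampled from its marginal likelihood with the effect integrated out, so
the sampler is fully conjugate (no Metropolis step); the single-site sweep
is numba-compiled and bit-reproducible from the seed.  Default chain
55,000 with 5,000 burn-in at full scale; the desk-scale analyses use
11,000/1,000 with thinning 10, which preserves posterior means at these
problem sizes.

**Window variance partition.**  Markers are binned into non-overlapping
physical 1-Mb windows that carry >= 1 marker (empty bins are excluded from
the share normalisation, which raises the per-window polygenic expectation
of 100/#windows accordingly).  Per posterior sample, the window share is
`Var(g_w) / Σ_w Var(g_w)` across individuals, so shares sum to one in
every sample; samples with zero total genetic variance are skipped for
shares but counted for WPPA.  Normalising by the sum of window variances
(rather than the variance of the summed genetic values) is what makes the
sum-to-one identity exact when windows are in LD.  `gv_pct` is the
posterior mean share × 100; `gv_pheno_pct` anchors the same window
variance to the phenotypic variance as an absolute-scale diagnostic.
WPPA is the fraction of samples with >= 1 included SNP in the window; the
lead SNP is the window's highest-SPPI marker.

**QTL calling.**  Windows with `gv_pct` >= 0.8 seed regions extended ±1 Mb
and merged when overlapping or adjacent.  A caveat that matters at desk
scale: the share threshold is relative — shares always sum to 100% — so
with few windows (say 20–120 instead of ~1,000) the polygenic expectation
100/#windows already approaches or exceeds 0.8%, and a signal-free trait
will still place some window above it.  The threshold controls false
positives only through its margin over 100/#windows; `gv_pheno_pct` is the
appropriate guard when an absolute no-signal check is wanted.  Lead SNPs
are re-fitted with the rest of their region's markers removed to estimate
the SNP-specific share, and checked in a generalised-least-squares animal
model (`V = σ²a A + diag(σ²e/En)`) with a Wald p-value.

## Synthetic cohorts

The generator emulates the study design end to end: founders draw whole
haplotypes from a finite pool (pool size is the single knob for line
diversity and inbreeding — small pools mimic a more inbred line); focal
parents run many small half-sib families with a fresh mate per offspring;
optionally the focal parents themselves come in full-sib groups from a
genotyped grandparent generation so that the pedigree carries additive
relationships.  Gametes are Poisson crossover processes on a
piecewise-constant intensity map (0.5-Mb resolution) with a configurable
hotspot fraction and multiplier; by default the map is renormalised so the
expected count per chromosome stays at the configured value while
hotspots concentrate it (10% of windows at 10× attract 52.6% of events).
Dams' meioses are multiplied by `sex_rate_multiplier` (default 1.10,
female maps in layers running ~5–20% longer).  There is no crossover
interference by default; real meiosis shows strong positive interference,
so close double crossovers — the hardest events to detect — are *more*
frequent here than in real data, making the detection benchmarks
conservative in that respect.

Each parent carries a log-normal recombination propensity
`exp(g + pe − ½σ²)` with additive `g` transmitted as mid-parent plus a
Mendelian-segregation deviation and permanent environment `pe`.  The log
variances are calibrated so per-meiosis counts show the configured
narrow-sense heritability (default 0.17) and repeatability (default 0.24):
with mean count μ and Poisson residual ≈ μ, the between-parent variance is
`t·μ/(1−t)` split `h²:t` into additive and permanent parts, mapped to the
log scale by 1/μ².  QTL act log-additively (`effect × centred dosage`), so
carriers' expected GRN scales by `e^effect` per copy; QTL variance comes on
top of the configured polygenic variance.  Genotyping error is a symmetric
±1 dosage perturbation at a configured rate (default 0).

Defaults for the study conditions: 2.0 expected crossovers per (100-Mb)
chromosome ≈ 2 cM/Mb, the genome-wide average for chicken autosomes;
20 markers/Mb, the density regime of a pruned commercial panel; founder
pool 30; allele frequencies uniform on (0.1, 0.9).  What the generator
does **not** emulate: coalescent-accurate founder LD (pool haplotypes have
independent alleles across markers, so phase carries no local LD
information and the detector cannot borrow population haplotype
frequencies — real data would be easier in this respect); mutation;
selection; Z-chromosome meiosis; any coupling between local haplotype
diversity and historical recombination rate (the haplotype-diversity
versus rate correlation observed in real lines is therefore absent unless
planted).  Passing tests demonstrate correctness of the algorithms under
these conditions, not field performance on a real 580K-chip cohort.

## Problem sizes and numerical choices

The shipped analyses and tests run at desk scale, chosen to exercise every
code path with tight Monte-Carlo error: detection benchmarks use 200
families × 4 offspring on 2 × 100 Mb at 20 SNPs/Mb (~3,000 true
crossovers); variance-component recovery uses 500 parents in 100 full-sib
groups with 2–8 records each; the WGR benchmark uses 600 individuals ×
2,000 markers in 20 one-Mb windows with chains of 11,000/1,000.  Floating
tolerances: window-mass conservation and share sums hold to 1e-9;
seeded samplers are bit-reproducible.  Ties are always broken
deterministically (documented per function).  Degenerate inputs (zero
pairs, empty strata, monomorphic markers, zero-event parents, parents with
single records) raise or return missing values as documented rather than
silently producing numbers.
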