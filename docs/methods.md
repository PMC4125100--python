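# Methods

## Data model

All analyses start from a sync table: per site and population, read
counts of A, T, C, G, N and deletions (1-based coordinates).  N reads
are ambiguous base calls and are excluded from every allele-frequency
denominator.  Deletions are real alleles for the five-class per-site
diversity π = 1 − (A² + G² + C² + T² + D²) but are never chosen as the
major/minor SNP pair in the biallelic reduction.  The two SNP alleles
are the two A/C/G/T bases with the largest read counts summed over all
populations, ties broken in base order A<C<G<T; any third allele is
dropped from the denominator.  Site-level frequencies are raw count
ratios; the pool-size-corrected estimator is used only in windowed π
(below).

## Screens and stratification

The differentiation screen (α-sites) requires ≥5× coverage in the two
ancestors and the ten constant-regime populations and initial diversity
π_ini = 2p(1−p) > 0.05, where p pools minor-allele reads across both
ancestors (count pooling rather than frequency averaging; both are
implemented, count pooling is the default because pooling reads is what
the screening description implies).  The diversity screen (χ-sites)
requires ≥15× in both ancestors, ≥10× in all twenty treatment
populations, the same diversity floor computed from the mean of the two
ancestral frequencies, and drops sites whose per-site median coverage
across those 22 populations exceeds twice the global median (the median
of the per-site medians) — a guard against collapsed repeats.

Ancestral differentiation d = |p_AC − p_AS| stratifies sites into weak
(d < 0.3), intermediate, and strong (d > 0.7) classes; boundary values
fall into the middle stratum because the defining inequalities are
strict.  Both thresholds are configurable.

## Differentiation scan

Each site is tested with a Cochran–Mantel–Haenszel test over 2×2 strata
of minor/major read counts, one stratum per replicate pair.  Because
the pairing of replicates between the two groups is arbitrary, the test
runs under five rotational pairings (pairing m matches replicate i with
replicate i+m mod 5); when the group ancestors are included they form a
pinned sixth stratum in every pairing.  No continuity correction is
applied.  Read counts enter the strata directly, which pseudo-replicates
the pool (reads are not independent chromosomes); the pseudo-treatment
permutation null — re-running the identical scan on random half/half
relabelings of the same populations — is the empirical control for
this, as well as for drift among replicates.

Per-site p-values are combined as the geometric mean over the five
pairings (floored at 1e−320 before logs) and converted to q-values with
the Benjamini–Yekutieli step-up rule, which is valid under arbitrary
dependence.  A site is called differentiated (β-site) when the combined
q passes the FDR cutoff (default 1e−5).  A second rule — each of the
five per-pairing BY q-values must pass — is used for the
pairwise-treatment scans; both rules are exposed because the two
aggregation orders answer slightly different questions and both appear
in this experimental design's analysis tradition.

## Diversity and F_ST

Windowed π uses non-overlapping 10 kb windows: per qualifying position
(read depth 4–400), π_raw = 1 − Σf² over the A/C/G/T/deletion classes
with alleles under 2 reads zeroed as sequencing noise, corrected by
c/(c−1) · n/(n−1) for the two sampling stages (c reads from the pool of
n = 140 chromosomes; both factors are the standard unbiased-sample
corrections).  A window is valid when ≥60% of its positions qualify;
window π is the mean over qualifying positions.  The truncation bias of
the 2-read allele floor is not corrected; at the coverages used here it
is far below the sampling noise.

Nei's fixation index among the five replicates of a treatment is
computed as a ratio of averages, F_ST = 1 − mean(H_S)/mean(H_T), with
H_S the mean within-population heterozygosity 2p(1−p) and H_T computed
from the unweighted mean frequency; sites with H_T = 0 are excluded
from both means.  The exact historical variant is not recoverable from
the analysis tradition alone, so the mean-of-ratios form is available
as a sensitivity toggle.  Note that with k replicates the
ratio-of-averages estimator converges to 1 − (1−F)/(1−F/k) ≈ (1−1/k)·F
under pure drift of magnitude F — the finite-k bias is inherent to the
H_T definition and is shared by all treatments being compared.

Unequal coverage inflates apparent differentiation, so treatments are
compared with a coverage-matched estimate: per site, the five
replicates of each treatment are ranked by depth, the i-th ranked
populations of all treatments are subsampled without replacement
(hypergeometric) to the minimum depth of rank i, and F_ST is averaged
over 10 independent resamplings.  With equal coverages the subsample
equals the full sample and the estimate collapses exactly to plain Nei
F_ST.

Treatment comparisons use one-way fixed-effects ANOVA over the five
replicate means per treatment with Tukey HSD post-hoc tests, and a
paired t-test for the X-versus-autosome F_ST contrast across
treatments (regions: the low-recombination-bounded left/right ends of
the major autosome arms and the X).

## Forward simulator

The regime simulator tracks one neutral site linked to n = 40
environmentally antagonistic loci in a diploid Wright–Fisher population
(default census 896 = the 448 + 448 founding pairs of the design), 42
generations.  Allele 1 at a selected locus carries fitness 1+s in
environment A and 1−s in environment B, multiplicative across loci and
allele copies.  The per-copy log-fitness is scaled by a single
calibrated amplification factor (default 2.4) representing the several
episodes of viability, fertility and adult-survival selection a real
fly generation applies relative to the single census step the model
simulates; the factor was fixed once, by matching the simulator's
selected-locus diversity to reference values for this architecture,
and is not varied per regime.

Regimes: constant A, constant B, strict generation-by-generation
alternation (temporal), and a spatial regime in which adults are
shuffled into two resident demes of N/2, selection acts with opposite
sign within demes, and each deme contributes exactly half of the next
generation (soft selection).  Replicates draw initial frequencies iid
Beta(0.8, 0.8) — a mildly U-shaped standing-variation spectrum whose
expected heterozygosity (≈0.31) matches the reference neutral level
after 42 generations of drift — and impose random initial linkage
disequilibrium by thresholding correlated Gaussians under a random LKJ
(η = 1, uniform) correlation matrix.  Selected loci assort freely
(they model targets scattered across chromosomes); the neutral site is
linked to its nearest selected locus at recombination fraction r and
effectively unlinked to the rest, summarized as the harmonic-mean
effective distance for linkage profiles.

Design choices that were genuinely open, and how they were fixed: the
resident-deme spatial scheme (rather than both demes drawing from the
full adult pool) and the census of 896 were selected during the same
one-time calibration because they reproduce the reference diversity
values most closely; dominance is absent (genic selection) as the
simplest scheme consistent with an "antagonistic alleles" architecture;
with s = 0 every regime routes through the identical drift-only code
path so regime labels cannot perturb RNG streams.  Known limitation:
the model's spatial dose-response saturates near π ≈ 0.47 by s ≈ 0.12
per copy, so it slightly overshoots the reference value at s = 0.05 and
undershoots at s = 0.07 (both by < 0.025); no single parameterization
we examined reproduces the rising 0.45 → 0.49 tail exactly.

## Synthetic experiments

The generator emulates the design end to end: a grand-ancestor SNP pool
(frequencies uniform on [0.05, 0.95], linkage equilibrium), two
ancestors of census 1,000 founded from it and diverging 50 generations
under opposite constant environments, an F1 cross (every founder is one
ancestral-salt gamete plus one ancestral-cadmium gamete, which creates
the admixture LD naturally), twenty populations of 448 evolving 42
generations under their regimes, and pooled sequencing of 70 females
(140 chromosomes, hypergeometric) at Poisson mean 17.5× with reads
binomial in the pool frequency.  Sites live on five 25 Mb arms with uniform recombination at 2 cM/Mb
(about 50 cM of female map per arm, a fly-like map length); map lengths
are halved as the sex-average because *Drosophila* males are
achiasmatic.  Arms much shorter than this collapse into single linkage
blocks and let draft from the planted sweeps erase neutral diversity
genome-wide in every non-spatial treatment.  Site classes:
environmentally antagonistic (EAS, default 1% at s = 0.1),
conditionally neutral in either direction (1% each; selected in one
environment, strictly neutral in the other), optionally uniformly
selected, the rest neutral.  The generator uses plain genic ±s fitness
(no amplification factor — that device belongs to the regime simulator's
calibration).  The ground truth records class labels, selection
coefficients and true frequencies (grand ancestor, both ancestors at
the cross, and every population's final generation); full per-generation
trajectories are not stored at genome scale.

What the generator does not emulate: sequencing error beyond binomial
read sampling, base-quality structure, reference bias, variable
recombination or inversions, unequal ancestor histories (exposed in the
config but equal by default).  Passing tests therefore demonstrate the
statistical machinery under the design's sampling structure, not
robustness to real-data artefacts upstream of a sync table.

## Problem sizes and numerics

Default test and acceptance problem sizes were chosen to make each
check statistically decisive at desk scale: 2,000-replicate smoke runs
per regime × s combination (tolerance ±0.04 against the reference
values; the full ±0.02 comparison uses 10,000 replicates), 5,000
replicates for the drift closed form (2 Monte-Carlo SE criterion),
60,000–100,000 sites for the all-neutral false-positive calibration,
and ten 20,000-site seeds for the qualitative ordering checks.  All
stochastic entry points take explicit seeds; the pipeline derives
per-stage seeds from a single global seed by hashing the stage name.
Degenerate inputs follow one rule throughout: quantities that would
divide by zero (empty strata, zero coverage, H_T = 0, zero-variance
correlations) are flagged undefined rather than silently zeroed, and
degenerate 2×2 strata are dropped from the CMH sums.
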