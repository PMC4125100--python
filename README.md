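# evoregime

Analysis of genome-wide variation within and among populations evolving
under alternative selection regimes, from pooled resequencing
(Pool-seq) data.

## The problem

An evolve-and-resequence experiment crosses two environmentally
specialized *Drosophila* ancestors — one adapted to salt-enriched and
one to cadmium-enriched larval medium — and lets twenty replicate
populations (census 448) evolve for 42 generations under four regimes:
constant salt, constant cadmium, temporally alternating environments,
and a spatially split ("soft selection") environment in which each
habitat contributes equally to the next generation.  All populations,
plus both ancestors and their common source population, are sequenced
as pools of 70 females.  Classic theory predicts that for
environmentally antagonistic loci the maintained genetic variance
orders V(spatial) > V(temporal) > V(constant); for neutral loci the
ordering instead reflects the effective population size each regime
induces through linked selection.

This package implements the full downstream analysis:

* **sync_io** — popoolation2-style sync allele-count tables and the
  population manifest;
* **site_screens** — biallelic reduction, the per-site diversity
  π = 1 − (A² + G² + C² + T² + D²), the coverage/diversity screens for
  the differentiation scan (α-sites) and the diversity analyses
  (χ-sites), and stratification by ancestral differentiation
  d = |p_AC − p_AS|;
* **differentiation** — the five-pairing Cochran–Mantel–Haenszel scan
  with Benjamini–Yekutieli FDR control, β-site calling, the
  pseudo-treatment permutation null, and 5 kb window summaries;
* **diversity_fst** — windowed Pool-seq π, one-way ANOVA + Tukey HSD
  treatment comparisons, Nei's F_ST = 1 − H̄_S/H̄_T among replicates,
  and its coverage-matched resampling estimate;
* **genome_patterns** — clustering of significant sites, F_ST decay
  around focal sites, enrichment by significance bin, inversion-marker
  frequencies, conditional-neutrality classification, standardized
  allele-frequency correlations between treatments;
* **simulate** — a forward Wright–Fisher simulator of a neutral site
  linked to 40 environmentally antagonistic loci under the four
  regimes;
* **experiment** — a synthetic-data generator that emulates the whole
  design (ancestor divergence, F1 cross, 42 generations, pooled
  sequencing at ~17.5× Poisson coverage) with a ground-truth ledger;
* **pipeline** — config-driven staged execution.

## Worked example

Simulate the spatially heterogeneous regime at s = 0.05 and compare the
mean diversity retained at the 40 selected loci with the no-selection
control:

```bash
$ evoregime simulate --regime spatial --s 0.05 --reps 2000 --seed 7
{
  "regime": "spatial",
  "s": 0.05,
  "n_reps": 2000,
  "neutral_pi": 0.27988493596291064,
  "neutral_pi_se": 0.004036871801769334,
  "selected_pi": 0.47054633904281923,
  "selected_pi_se": 0.0004054454979446043
}
$ evoregime simulate --regime temporal --s 0.05 --reps 2000 --seed 7 | grep '"selected_pi"'
  "selected_pi": 0.29749881935898137,
$ evoregime simulate --regime constant_A --s 0.05 --reps 2000 --seed 7 | grep '"selected_pi"'
  "selected_pi": 0.0017194343956149338,
```

Mean heterozygosity 2p(1−p) at the antagonistic loci after 42
generations is ~0.47 under spatial soft selection (balancing selection
maintains both alleles near frequency ½), ~0.30 under temporal
fluctuation (indistinguishable from the drift-only control), and ~0.002
in a constant environment (near-complete fixation of the favoured
alleles).  The numbered scripts under `analysis/` run the full
synthetic-experiment pathway: generation, differentiation scan with its
permutation null, diversity-by-d and F_ST contrasts, and the
genome-pattern diagnostics, writing their tables to `results/`.

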