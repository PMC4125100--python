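"""Synthetic evolve-and-resequence experiments with known ground truth.

The generator emulates the full experimental design: a large outbred
source population (grand ancestor), two ancestors diverging under
opposite constant environments, an F1 cross founding twenty populations
of N = 448 that evolve 42 generations under four selection regimes
(constant salt, constant cadmium, temporal alternation, spatial split
with soft selection), and pooled sequencing of 70 females per population
(140 chromosomes) at Poisson read depth.

Sites live on a small synthetic genome (five arms) with uniform
recombination; admixture linkage disequilibrium arises naturally from
simulating haplotypes through the cross rather than being imposed.
Site classes: environmentally antagonistic (EAS; opposite alleles
favoured in the two environments), conditionally neutral in either
direction (selected in one environment, neutral in the other), uniformly
selected, and neutral.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from evoregime.experiment import _wf
from evoregime.sync_io import PopulationManifest, SyncTable

__all__ = ["ExperimentConfig", "GroundTruth", "generate_experiment", "emulate_pool_sequencing"]

_REGIME_OF_TREATMENT = {"Salt": 0, "Cad": 1, "Temp": 2, "Spatial": 3}


@dataclass
class ExperimentConfig:
    n_sites: int = 100_000
    arm_names: tuple = ("2L", "2R", "3L", "3R", "X")
    arm_length_bp: int = 25_000_000  # ~50 cM per arm at 2 cM/Mb, fly-like
    recomb_cm_per_mb: float = 2.0  # female map; males are achiasmatic
    frac_eas: float = 0.01
    frac_cn_salt: float = 0.01  # selected in salt, neutral in cadmium
    frac_cn_cad: float = 0.01
    frac_uniform: float = 0.0
    s_eas: float = 0.1
    s_cn: float = 0.1
    s_uniform: float = 0.05
    N: int = 448
    generations: int = 42
    n_ancestor: int = 1000
    divergence_generations: tuple = (50, 50)  # (AS, AC)
    ga_census: int = 2000
    ga_freq_range: tuple = (0.05, 0.95)
    pool_size: int = 140
    mean_coverage: float = 17.5
    fitness_scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        tot = self.frac_eas + self.frac_cn_salt + self.frac_cn_cad + self.frac_uniform
        if tot > 1.0 + 1e-9:
            raise ValueError("site-class fractions must sum to <= 1 (rest neutral)")
        if self.pool_size > 2 * self.N:
            raise ValueError("pool_size cannot exceed 2N chromosomes")
        if self.N % 2:
            raise ValueError("N must be even (spatial regime splits the census)")


@dataclass
class GroundTruth:
    """Per-site truth: class labels, selection coefficients, and true
    allele frequencies (grand ancestor, both ancestors at the cross, and
    the final generation of every population)."""

    sites: pd.DataFrame  # chrom, pos, class, s, p_ga, p_as, p_ac, p_ini, d_true
    final_freqs: pd.DataFrame  # one column per population

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([self.sites, self.final_freqs], axis=1)


def emulate_pool_sequencing(
    p, pool_size: int, coverage, census: int = 2000, rng: np.random.Generator | None = None
):
    """Two-stage Pool-seq sampling of alternate-allele read counts.

    Chromosomes in the pool are drawn without replacement from the 2N in
    the population (hypergeometric), then reads are binomial draws from
    the pool frequency.  Scalars or arrays broadcast.
    """
    rng = rng or np.random.default_rng()
    p = np.asarray(p, dtype=float)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("frequencies must lie in [0,1]")
    if pool_size > 2 * census:
        raise ValueError("pool_size cannot exceed the 2N chromosomes of the population")
    ngood = np.rint(2 * census * p).astype(np.int64)
    k = rng.hypergeometric(ngood, 2 * census - ngood, pool_size)
    cov = np.asarray(coverage, dtype=np.int64)
    return rng.binomial(cov, k / pool_size)


# ---------------------------------------------------------------------------
# generator internals
# ---------------------------------------------------------------------------

def _pack_bits(bits: np.ndarray) -> np.ndarray:
    """(n_haps, n_sites_padded) bool -> (n_haps, n_words) uint64."""
    packed = np.packbits(bits, axis=1, bitorder="little")
    return packed.view(np.uint64)


def _unpack_counts(haps: np.ndarray, rows: np.ndarray, n_sites: int) -> np.ndarray:
    """Alternate-allele counts per site over the selected haplotype rows."""
    sub = haps[rows].view(np.uint8)
    bits = np.unpackbits(sub, axis=1, bitorder="little")[:, :n_sites]
    return bits.sum(axis=0, dtype=np.int64)


class _Genome:
    """Site layout: arms padded to whole 64-bit words."""

    def __init__(self, cfg: ExperimentConfig, rng: np.random.Generator):
        n_arms = len(cfg.arm_names)
        base = cfg.n_sites // n_arms
        counts = [base + (1 if a < cfg.n_sites % n_arms else 0) for a in range(n_arms)]
        self.arm_n_sites = np.array(counts, dtype=np.int64)
        self.arm_words = (self.arm_n_sites + 63) // 64
        self.arm_word_lo = np.concatenate([[0], np.cumsum(self.arm_words)])[:-1].astype(np.int64)
        self.arm_word_hi = (self.arm_word_lo + self.arm_words).astype(np.int64)
        self.n_words = int(self.arm_words.sum())
        # sex-averaged map length in Morgans (males do not recombine)
        morgans = cfg.recomb_cm_per_mb * cfg.arm_length_bp / 1e6 / 100.0
        self.arm_maplen = np.full(n_arms, morgans / 2.0)
        self.chrom = np.concatenate(
            [np.repeat(cfg.arm_names[a], counts[a]) for a in range(n_arms)]
        )
        pos = []
        for a in range(n_arms):
            pv = np.sort(rng.choice(cfg.arm_length_bp, size=counts[a], replace=False)) + 1
            pos.append(pv)
        self.pos = np.concatenate(pos).astype(np.int64)
        # global padded bit index of each site
        self.site_word = np.empty(cfg.n_sites, dtype=np.int64)
        self.site_bit = np.empty(cfg.n_sites, dtype=np.int64)
        off = 0
        for a in range(n_arms):
            local = np.arange(counts[a])
            self.site_word[off : off + counts[a]] = self.arm_word_lo[a] + (local >> 6)
            self.site_bit[off : off + counts[a]] = local & 63
            off += counts[a]

    def padded_index(self) -> np.ndarray:
        """Index of each real site in the padded unpacked bit vector."""
        return (self.site_word * 64 + self.site_bit).astype(np.int64)

    def freqs(self, haps: np.ndarray) -> np.ndarray:
        bits = np.unpackbits(haps.view(np.uint8), axis=1, bitorder="little")
        return bits[:, self.padded_index()].mean(axis=0)

    def pool_counts(self, haps: np.ndarray, rows: np.ndarray) -> np.ndarray:
        bits = np.unpackbits(haps[rows].view(np.uint8), axis=1, bitorder="little")
        return bits[:, self.padded_index()].sum(axis=0, dtype=np.int64)


def _site_classes(cfg: ExperimentConfig, rng: np.random.Generator):
    n = cfg.n_sites
    labels = np.full(n, "neutral", dtype=object)
    pool = rng.permutation(n)
    k = 0
    for name, frac in (
        ("EAS", cfg.frac_eas),
        ("CN-salt", cfg.frac_cn_salt),
        ("CN-cad", cfg.frac_cn_cad),
        ("uniform", cfg.frac_uniform),
    ):
        m = int(round(frac * n))
        labels[pool[k : k + m]] = name
        k += m
    gamma = lambda s: cfg.fitness_scale * np.log((1 + s) / (1 - s))
    g_salt = np.zeros(n)
    g_cad = np.zeros(n)
    s_of = np.zeros(n)
    eas = labels == "EAS"
    g_salt[eas], g_cad[eas], s_of[eas] = gamma(cfg.s_eas), -gamma(cfg.s_eas), cfg.s_eas
    cns = labels == "CN-salt"
    g_salt[cns], s_of[cns] = gamma(cfg.s_cn), cfg.s_cn
    cnc = labels == "CN-cad"
    g_cad[cnc], s_of[cnc] = gamma(cfg.s_cn), cfg.s_cn
    uni = labels == "uniform"
    g_salt[uni] = g_cad[uni] = gamma(cfg.s_uniform)
    s_of[uni] = cfg.s_uniform
    return labels, g_salt, g_cad, s_of


def generate_experiment(cfg: ExperimentConfig, seed: int | None = None):
    """Simulate the full design and return ``(sync, manifest, truth)``."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    genome = _Genome(cfg, rng)
    labels, g_salt, g_cad, s_of = _site_classes(cfg, rng)
    selected = np.flatnonzero((g_salt != 0) | (g_cad != 0))
    sel_word = genome.site_word[selected]
    sel_mask = (np.uint64(1) << genome.site_bit[selected].astype(np.uint64))
    sel_gA = g_salt[selected]  # environment A = salt
    sel_gB = g_cad[selected]

    p_ga = rng.uniform(*cfg.ga_freq_range, size=cfg.n_sites)

    def founding_haps(n_haps: int) -> np.ndarray:
        padded = genome.n_words * 64
        bits = np.zeros((n_haps, padded), dtype=np.uint8)
        draws = rng.random((n_haps, cfg.n_sites)) < p_ga[None, :]
        bits[:, genome.padded_index()] = draws
        return _pack_bits(bits)

    def kernel_seed():
        return int(rng.integers(0, 2**31 - 1))

    args = (genome.arm_word_lo, genome.arm_word_hi, genome.arm_n_sites, genome.arm_maplen)

    # ancestors diverge under their own constant environments
    anc = {}
    for name, regime, n_gen in (
        ("AS", 0, cfg.divergence_generations[0]),
        ("AC", 1, cfg.divergence_generations[1]),
    ):
        haps = founding_haps(2 * cfg.n_ancestor)
        _wf.evolve(haps, n_gen, regime, *args, sel_word, sel_mask, sel_gA, sel_gB, kernel_seed())
        anc[name] = haps

    manifest = PopulationManifest.default_experiment(cfg.pool_size)
    final_freqs = {}
    counts_by_pop = {}
    coverage = rng.poisson(cfg.mean_coverage, size=(cfg.n_sites, len(manifest)))

    # grand ancestor and ancestors are sequenced as pools
    p_as = genome.freqs(anc["AS"])
    p_ac = genome.freqs(anc["AC"])
    ga_cov = coverage[:, manifest.index("GA")]
    counts_by_pop["GA"] = emulate_pool_sequencing(p_ga, cfg.pool_size, ga_cov, cfg.ga_census, rng)
    final_freqs["GA"] = p_ga
    for name in ("AS", "AC"):
        rows = _sample_pool_rows(2 * cfg.n_ancestor, cfg.pool_size, rng)
        k = genome.pool_counts(anc[name], rows)
        cov = coverage[:, manifest.index(name)]
        counts_by_pop[name] = rng.binomial(cov, k / cfg.pool_size)
        final_freqs[name] = genome.freqs(anc[name])

    # twenty experimental populations founded from the AS x AC cross
    for treatment, regime in _REGIME_OF_TREATMENT.items():
        for rep in range(1, 6):
            name = f"{treatment}{rep}"
            haps = np.empty((2 * cfg.N, genome.n_words), dtype=np.uint64)
            _wf.found_cross(anc["AS"], anc["AC"], haps, *args, kernel_seed())
            _wf.evolve(
                haps, cfg.generations, regime, *args, sel_word, sel_mask, sel_gA, sel_gB,
                kernel_seed(),
            )
            rows = _sample_pool_rows(2 * cfg.N, cfg.pool_size, rng)
            k = genome.pool_counts(haps, rows)
            cov = coverage[:, manifest.index(name)]
            counts_by_pop[name] = rng.binomial(cov, k / cfg.pool_size)
            final_freqs[name] = genome.freqs(haps)

    sync = _assemble_sync(genome, manifest, counts_by_pop, coverage, rng)
    sites = pd.DataFrame(
        {
            "chrom": genome.chrom,
            "pos": genome.pos,
            "class": labels,
            "s": s_of,
            "p_ga": p_ga,
            "p_as": p_as,
            "p_ac": p_ac,
            "p_ini": 0.5 * (p_as + p_ac),
            "d_true": np.abs(p_as - p_ac),
        }
    )
    truth = GroundTruth(sites, pd.DataFrame(final_freqs))
    return sync, manifest, truth


def _sample_pool_rows(n_haps: int, pool_size: int, rng: np.random.Generator) -> np.ndarray:
    """Sample pool_size/2 diploid females; both chromosomes enter the pool."""
    inds = rng.choice(n_haps // 2, size=pool_size // 2, replace=False)
    return np.sort(np.concatenate([2 * inds, 2 * inds + 1]))


def _assemble_sync(genome, manifest, counts_by_pop, coverage, rng) -> SyncTable:
    """Build the sync table: reference base gets ref reads, one alternate
    base gets the alternate-allele reads."""
    n_sites = genome.pos.size
    n_pops = len(manifest)
    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4
    counts = np.zeros((n_sites, n_pops, 6), dtype=np.int64)
    rows = np.arange(n_sites)
    for j, pop in enumerate(manifest.names):
        alt = counts_by_pop[pop]
        cov = coverage[:, j]
        counts[rows, j, alt_idx] = alt
        counts[rows, j, ref_idx] += cov - alt
    bases = np.array(["A", "T", "C", "G"])
    return SyncTable(genome.chrom, genome.pos, bases[ref_idx], counts, manifest)
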