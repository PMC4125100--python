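"""Forward Wright-Fisher simulation of selection regimes.

A neutral site is linked to ``n_selected`` environmentally antagonistic
loci (allele 1 carries fitness 1+s in environment A and 1-s in
environment B, multiplicative across loci and allele copies).  Four
regimes mirror the experimental design: constant A, constant B, strict
generation-by-generation alternation (temporal), and a population split
each generation into two equal demes experiencing opposite environments
with equal deme contributions to the next generation (spatial, soft
selection), plus a no-selection control.

Replicates start from independently drawn allele frequencies with random
linkage disequilibrium: a random correlation matrix (LKJ, uniform over
correlation matrices at ``eta = 1``) is imposed on the founding
haplotypes through Gaussian-copula thresholding.

The per-allele-copy log-fitness is ``fitness_scale * ln((1+s)/(1-s))``.
The scale (default 2.4) is a calibrated amplification representing the
multiple episodes of viability and fertility selection a fly generation
applies relative to the single census step the model simulates; see
docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from evoregime.simulate._engine import REGIME_CODES, run_chunk

__all__ = [
    "SimConfig",
    "SimResult",
    "run_simulation",
    "random_ld_structure",
    "haplotypes_from_freq_ld",
    "selection_recursion",
    "deterministic_step",
    "deterministic_trajectory",
    "effective_recombination",
    "neutral_linkage_profile",
    "lkj_correlation",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SimConfig:
    """Parameters of one simulated treatment.

    ``init_dist`` is ``("beta", a)`` for iid Beta(a, a) initial
    frequencies, ``("uniform", lo, hi)``, or ``("fixed", p)``.
    ``ld_eta`` controls the spread of random initial LD (LKJ shape;
    ``None`` disables LD).  ``r_neutral`` is the recombination
    probability between the neutral site and its nearest selected locus.
    """

    regime: str = "spatial"
    s: float = 0.05
    n_selected: int = 40
    N: int = 896
    generations: int = 42
    fitness_scale: float = 2.4
    init_dist: tuple = ("beta", 0.8)
    ld_eta: float | None = 1.0
    r_neutral: float = 0.5
    n_reps: int = 10_000
    seed: int = 0

    def __post_init__(self):
        if self.regime not in REGIME_CODES:
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.s < 0:
            raise ValueError("s must be >= 0")
        if not 0 < self.r_neutral <= 0.5:
            raise ValueError("r_neutral must lie in (0, 0.5]")
        if self.N < 2 or self.N % 2:
            raise ValueError("N must be an even integer >= 2")
        if self.n_selected < 0 or self.n_selected > 62:
            raise ValueError("n_selected must be in [0, 62]")


@dataclass
class SimResult:
    config: SimConfig
    freqs: np.ndarray  # (n_reps, n_selected + 1) final allele frequencies

    def selected_pi(self) -> np.ndarray:
        """Per-replicate mean heterozygosity over the selected loci."""
        if self.config.n_selected == 0:
            raise ValueError("no selected loci in this run")
        f = self.freqs[:, : self.config.n_selected]
        return (2.0 * f * (1.0 - f)).mean(axis=1)

    def neutral_pi(self) -> np.ndarray:
        f = self.freqs[:, self.config.n_selected]
        return 2.0 * f * (1.0 - f)

    def summary(self) -> dict:
        out = {"regime": self.config.regime, "s": self.config.s, "n_reps": len(self.freqs)}
        npi = self.neutral_pi()
        out["neutral_pi"] = float(npi.mean())
        out["neutral_pi_se"] = float(npi.std(ddof=1) / np.sqrt(npi.size))
        if self.config.n_selected:
            spi = self.selected_pi()
            out["selected_pi"] = float(spi.mean())
            out["selected_pi_se"] = float(spi.std(ddof=1) / np.sqrt(spi.size))
        return out


# ---------------------------------------------------------------------------
# random LD structure
# ---------------------------------------------------------------------------

def lkj_correlation(d: int, rng: np.random.Generator, eta: float = 1.0, size: int = 1) -> np.ndarray:
    """Batch of random correlation matrices via the C-vine construction.

    Partial correlations are Beta-distributed; ``eta = 1`` is the
    uniform (LKJ) distribution over correlation matrices.
    Returns an array of shape (size, d, d).
    """
    P = np.zeros((size, d, d))
    S = np.tile(np.eye(d), (size, 1, 1))
    for k_row in range(d - 1):
        beta_par = eta + (d - 1 - k_row) / 2.0
        for i in range(k_row + 1, d):
            P[:, k_row, i] = 2.0 * rng.beta(beta_par, beta_par, size=size) - 1.0
            p = P[:, k_row, i].copy()
            for ell in range(k_row - 1, -1, -1):
                p = (
                    p * np.sqrt((1 - P[:, ell, i] ** 2) * (1 - P[:, ell, k_row] ** 2))
                    + P[:, ell, i] * P[:, ell, k_row]
                )
            S[:, k_row, i] = p
            S[:, i, k_row] = p
    return S


def random_ld_structure(
    n_loci: int,
    freqs: np.ndarray,
    seed: int | np.random.Generator = 0,
    eta: float = 1.0,
):
    """Random pairwise LD (D) among loci, feasibility-clipped.

    Draws a random correlation matrix and converts correlations to
    two-locus D via ``D_ij = rho_ij * sqrt(p_i q_i p_j q_j)``, clipping
    each value to the feasible range so that all four haplotype
    frequencies stay in [0, 1].  Returns ``(D, corr, n_clipped)``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = np.asarray(freqs, dtype=float)
    if p.shape != (n_loci,):
        raise ValueError("freqs must have length n_loci")
    corr = lkj_correlation(n_loci, rng, eta=eta, size=1)[0]
    q = 1.0 - p
    sd = np.sqrt(p * q)
    D = corr * np.outer(sd, sd)
    lo = np.maximum(-np.outer(p, p), -np.outer(q, q))
    hi = np.minimum(np.outer(p, q), np.outer(q, p))
    clipped = (D < lo) | (D > hi)
    np.fill_diagonal(clipped, False)
    D = np.clip(D, lo, hi)
    np.fill_diagonal(D, p * q)
    return D, corr, int(clipped.sum() // 2)


def haplotypes_from_freq_ld(p: float, q: float, D: float) -> np.ndarray:
    """Two-locus haplotype frequencies (AB, Ab, aB, ab) from marginal
    frequencies and the disequilibrium coefficient D."""
    h = np.array(
        [p * q + D, p * (1 - q) - D, (1 - p) * q - D, (1 - p) * (1 - q) + D], dtype=float
    )
    if (h < -1e-12).any() or (h > 1 + 1e-12).any():
        raise ValueError(f"D={D} infeasible for p={p}, q={q}")
    return np.clip(h, 0.0, 1.0)


# ---------------------------------------------------------------------------
# deterministic single-locus recursions (drift-off mode)
# ---------------------------------------------------------------------------

def selection_recursion(p: float, w_focal: float, w_other: float) -> float:
    """One generation of genic selection: p' = p w1 / (p w1 + q w2)."""
    q = 1.0 - p
    return p * w_focal / (p * w_focal + q * w_other)


def deterministic_step(p: float, regime: str, s: float, generation: int = 0) -> float:
    """One deterministic generation under a regime (antagonistic genic
    fitness 1+s / 1-s; spatial averages the two deme recursions)."""
    if regime == "neutral" or s == 0:
        return p
    if regime == "constant_A":
        return selection_recursion(p, 1 + s, 1 - s)
    if regime == "constant_B":
        return selection_recursion(p, 1 - s, 1 + s)
    if regime == "temporal":
        if generation % 2 == 0:
            return selection_recursion(p, 1 + s, 1 - s)
        return selection_recursion(p, 1 - s, 1 + s)
    if regime == "spatial":
        pa = selection_recursion(p, 1 + s, 1 - s)
        pb = selection_recursion(p, 1 - s, 1 + s)
        return 0.5 * (pa + pb)
    raise ValueError(f"unknown regime {regime!r}")


def deterministic_trajectory(p0: float, regime: str, s: float, generations: int) -> np.ndarray:
    traj = np.empty(generations + 1)
    traj[0] = p0
    p = p0
    for g in range(generations):
        p = deterministic_step(p, regime, s, g)
        traj[g + 1] = p
    return traj


# ---------------------------------------------------------------------------
# stochastic simulation
# ---------------------------------------------------------------------------

def _draw_init_freqs(cfg: SimConfig, rng: np.random.Generator, size: int) -> np.ndarray:
    kind = cfg.init_dist[0]
    L = cfg.n_selected + 1
    if kind == "beta":
        return rng.beta(cfg.init_dist[1], cfg.init_dist[1], size=(size, L))
    if kind == "uniform":
        return rng.uniform(cfg.init_dist[1], cfg.init_dist[2], size=(size, L))
    if kind == "fixed":
        return np.full((size, L), float(cfg.init_dist[1]))
    raise ValueError(f"unknown init_dist {cfg.init_dist!r}")


def _init_haplotypes(cfg: SimConfig, rng: np.random.Generator, size: int) -> np.ndarray:
    """Bit-packed founding haplotypes for ``size`` replicates."""
    L = cfg.n_selected + 1
    n2 = 2 * cfg.N
    p = _draw_init_freqs(cfg, rng, size)
    if cfg.init_dist[0] == "fixed" and cfg.ld_eta is None:
        # exact founding counts: round(2N p) copies per locus, placed at random
        k = int(round(n2 * float(cfg.init_dist[1])))
        bits = np.zeros((size, n2, 64), dtype=bool)
        ranks = rng.random((size, n2, L)).argsort(axis=1)
        bits[:, :, :L] = ranks < k
        return np.packbits(bits, axis=2, bitorder="little").view(np.uint64)[:, :, 0]
    thr = norm.ppf(np.clip(p, 1e-12, 1 - 1e-12)).astype(np.float32)
    if cfg.ld_eta is not None and L > 1:
        corr = lkj_correlation(L, rng, eta=cfg.ld_eta, size=size)
        chol = np.linalg.cholesky(corr + 1e-10 * np.eye(L)).astype(np.float32)
        z = rng.standard_normal((size, n2, L), dtype=np.float32) @ chol.transpose(0, 2, 1)
    else:
        z = rng.standard_normal((size, n2, L), dtype=np.float32)
    bits = np.zeros((size, n2, 64), dtype=bool)
    bits[:, :, :L] = z < thr[:, None, :]
    return np.packbits(bits, axis=2, bitorder="little").view(np.uint64)[:, :, 0]


def run_simulation(cfg: SimConfig, chunk_size: int = 256) -> SimResult:
    """Simulate ``cfg.n_reps`` independent replicates of one treatment."""
    rng = np.random.default_rng(cfg.seed)
    n_sel = cfg.n_selected
    lr = cfg.fitness_scale * np.log((1 + cfg.s) / (1 - cfg.s)) if cfg.s > 0 else 0.0
    k = np.arange(2 * n_sel + 1, dtype=float)
    wpos = np.exp(lr * (k - n_sel))
    wneg = np.exp(-lr * (k - n_sel))
    # with s = 0 every regime is plain drift; use the neutral path so the
    # trajectory is bit-identical across regime labels
    regime = REGIME_CODES["neutral"] if cfg.s == 0 else REGIME_CODES[cfg.regime]
    freqs = np.empty((cfg.n_reps, n_sel + 1), dtype=np.float64)
    done = 0
    while done < cfg.n_reps:
        m = min(chunk_size, cfg.n_reps - done)
        init = _init_haplotypes(cfg, rng, m)
        seeds = rng.integers(0, 2**31 - 1, size=m).astype(np.int64)
        out = np.empty((m, n_sel + 1), dtype=np.float64)
        run_chunk(init, seeds, n_sel, regime, cfg.generations, wpos, wneg, cfg.r_neutral, out)
        freqs[done : done + m] = out
        done += m
    return SimResult(cfg, freqs)


def effective_recombination(r_nearest: float, n_selected: int) -> float:
    """Harmonic-mean recombination distance of the neutral site to the
    selected loci (nearest at ``r_nearest``, the rest unlinked)."""
    return n_selected / (1.0 / r_nearest + (n_selected - 1) / 0.5)


def neutral_linkage_profile(
    s: float,
    regimes=("constant_A", "constant_B", "temporal", "spatial", "neutral"),
    r_values=(0.0005, 0.005, 0.05, 0.5),
    n_reps: int = 2000,
    seed: int = 0,
    **cfg_kwargs,
) -> pd.DataFrame:
    """Neutral-site diversity as a function of linkage to selected loci.

    Runs each regime at each neutral-site recombination distance and
    reports mean neutral pi with its SE, together with the harmonic-mean
    effective distance used as the x-axis of linkage profiles.
    """
    rows = []
    for regime in regimes:
        for i, r in enumerate(r_values):
            cfg = SimConfig(
                regime=regime, s=s, r_neutral=r, n_reps=n_reps,
                seed=seed + 1000 * i + 17 * REGIME_CODES[regime], **cfg_kwargs,
            )
            res = run_simulation(cfg)
            npi = res.neutral_pi()
            rows.append(
                {
                    "regime": regime,
                    "s": s,
                    "r_neutral": r,
                    "r_effective": effective_recombination(r, cfg.n_selected),
                    "log10_r": np.log10(effective_recombination(r, cfg.n_selected)),
                    "neutral_pi": float(npi.mean()),
                    "se": float(npi.std(ddof=1) / np.sqrt(npi.size)),
                }
            )
    return pd.DataFrame(rows)
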