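"""Biallelic reduction of sync sites and the SNP screens.

Two screens are used downstream.  The differentiation screen ("alpha"
sites) keeps sites with at least 5-fold coverage in the two ancestors and
the ten constant-regime populations and initial diversity
``pi_ini = 2 p_ini (1 - p_ini) > 0.05``, with ``p_ini`` the minor-allele
frequency pooling read counts across both ancestors.  The diversity
screen ("chi" sites) requires 15-fold ancestral and 10-fold treatment
coverage, the same diversity floor computed from the mean of the two
ancestral frequencies, and drops sites whose across-population median
coverage exceeds twice the global median (a repetitive-region guard).

Ancestral differentiation ``d = |p_AC - p_AS|`` stratifies sites into
putatively neutral (d < 0.3), intermediate, and putatively differentially
selected (d > 0.7) classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from evoregime.sync_io import PopulationManifest, SiteCounts, SyncTable

# sync count order is A,T,C,G; tie-breaks use alphabetical base order A<C<G<T
_SYNC_BASE_IDX = {"A": 0, "T": 1, "C": 2, "G": 3}
_TIE_PRIORITY = np.array([0, 3, 1, 2])  # rank of sync index in A<C<G<T order
_BASES = np.array(["A", "T", "C", "G"])


@dataclass
class ScreenConfig:
    alpha_min_coverage: int = 5
    alpha_min_pi_ini: float = 0.05
    chi_min_ancestor_coverage: int = 15
    chi_min_treatment_coverage: int = 10
    chi_min_pi_ini: float = 0.05
    chi_median_factor: float = 2.0
    high_pi_threshold: float = 0.4
    d_low: float = 0.3
    d_high: float = 0.7

    def __post_init__(self):
        if self.d_low >= self.d_high:
            raise ValueError("d_low must be < d_high")
        for name in ("alpha_min_coverage", "alpha_min_pi_ini", "chi_min_ancestor_coverage",
                     "chi_min_treatment_coverage", "chi_median_factor", "high_pi_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


class BiallelicTable:
    """Two-allele reduction of a sync table.

    Attributes
    ----------
    minor_count : (n_sites, n_pops) reads carrying the minor allele
    allelic_cov : (n_sites, n_pops) reads carrying major or minor allele
    major_idx, minor_idx : sync base indices (0=A,1=T,2=C,3=G)
    """

    def __init__(self, chrom, pos, major_idx, minor_idx, minor_count, allelic_cov,
                 total_cov, manifest: PopulationManifest):
        self.chrom = np.asarray(chrom, dtype=object)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.major_idx = np.asarray(major_idx, dtype=np.int8)
        self.minor_idx = np.asarray(minor_idx, dtype=np.int8)
        self.minor_count = np.asarray(minor_count, dtype=np.int64)
        self.allelic_cov = np.asarray(allelic_cov, dtype=np.int64)
        self.total_cov = np.asarray(total_cov, dtype=np.int64)
        self.manifest = manifest

    def __len__(self):
        return len(self.pos)

    @property
    def major(self):
        return _BASES[self.major_idx]

    @property
    def minor(self):
        return _BASES[self.minor_idx]

    def freqs(self) -> np.ndarray:
        """(n_sites, n_pops) minor-allele frequencies; NaN where no allelic reads."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.allelic_cov > 0, self.minor_count / self.allelic_cov, np.nan)

    # ancestral summaries -------------------------------------------------
    def _anc_freq(self, name: str) -> np.ndarray:
        i = self.manifest.index(name)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.allelic_cov[:, i] > 0, self.minor_count[:, i] / self.allelic_cov[:, i], np.nan
            )

    @property
    def p_as(self) -> np.ndarray:
        return self._anc_freq("AS")

    @property
    def p_ac(self) -> np.ndarray:
        return self._anc_freq("AC")

    @property
    def p_ini(self) -> np.ndarray:
        return 0.5 * (self.p_as + self.p_ac)

    @property
    def pi_ini(self) -> np.ndarray:
        p = self.p_ini
        return 2.0 * p * (1.0 - p)

    @property
    def d(self) -> np.ndarray:
        return np.abs(self.p_ac - self.p_as)

    def pooled_ancestral_p(self) -> np.ndarray:
        """Minor frequency pooling AS+AC read counts (the alpha-screen p_ini)."""
        idx = self.manifest.indices(["AS", "AC"])
        mc = self.minor_count[:, idx].sum(axis=1)
        ac = self.allelic_cov[:, idx].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(ac > 0, mc / ac, np.nan)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos": self.pos,
                "major": self.major,
                "minor": self.minor,
                "p_AS": self.p_as,
                "p_AC": self.p_ac,
                "p_ini": self.p_ini,
                "pi_ini": self.pi_ini,
                "d": self.d,
            }
        )


def reduce_biallelic(site_or_table, manifest: PopulationManifest | None = None):
    """Reduce site(s) to the two most common A/C/G/T alleles.

    Major and minor allele are the two bases with the largest read counts
    summed over all populations; ties break in base order A<C<G<T.
    Frequencies use major+minor reads as denominator (N, deletions and any
    third allele are excluded).  A single :class:`SiteCounts` reduces to a
    one-row table, or ``None`` when fewer than two bases are observed.
    """
    if isinstance(site_or_table, SiteCounts):
        table = SyncTable.from_sites([site_or_table], manifest)
        out = reduce_biallelic(table)
        return out if len(out) else None
    table = site_or_table
    manifest = manifest or table.manifest
    base_counts = table.counts[:, :, :4]  # drop N and del columns
    pooled = base_counts.sum(axis=1)  # (n_sites, 4)
    # order by (count desc, tie priority asc): stable argsort on composite key
    key = pooled * 8 - _TIE_PRIORITY[None, :]
    order = np.argsort(-key, axis=1, kind="stable")
    major = order[:, 0]
    minor = order[:, 1]
    n_observed = (pooled > 0).sum(axis=1)
    keep = n_observed >= 2
    major_ct = np.take_along_axis(base_counts, major[:, None, None], axis=2)[:, :, 0]
    minor_ct = np.take_along_axis(base_counts, minor[:, None, None], axis=2)[:, :, 0]
    allelic = major_ct + minor_ct
    return BiallelicTable(
        table.chrom[keep],
        table.pos[keep],
        major[keep],
        minor[keep],
        minor_ct[keep],
        allelic[keep],
        table.coverage[keep],
        manifest,
    )


def pi_site(freqs: Sequence[float]) -> float:
    """Per-site nucleotide diversity ``1 - sum(f^2)`` over the 5 allele
    classes (A, G, C, T, deletion)."""
    f = np.asarray(freqs, dtype=float)
    if f.ndim != 1 or f.shape[0] != 5:
        raise ValueError("expected a 5-vector of allele frequencies (A,G,C,T,del)")
    if (f < 0).any() or (f > 1).any():
        raise ValueError("frequencies must lie in [0,1]")
    if f.sum() > 1.0 + 1e-9:
        raise ValueError(f"frequencies sum to {f.sum():.6f} > 1")
    return float(1.0 - np.dot(f, f))


def _check_populations(manifest: PopulationManifest, names: Sequence[str]):
    for n in names:
        manifest.index(n)  # raises KeyError on a missing population


def screen_alpha(
    bi: BiallelicTable, cfg: ScreenConfig | None = None, coverage: np.ndarray | None = None
) -> np.ndarray:
    """Differentiation-scan screen over AS, AC and the ten constant-regime
    populations: coverage floor plus pooled-ancestor diversity floor."""
    cfg = cfg or ScreenConfig()
    m = bi.manifest
    names = ["AS", "AC"] + m.treatment("Salt") + m.treatment("Cad")
    if len(names) != 12:
        raise KeyError("alpha screen requires AS, AC and 5 Salt + 5 Cad populations")
    _check_populations(m, names)
    cov = bi.total_cov if coverage is None else coverage
    cols = m.indices(names)
    cov_ok = (cov[:, cols] >= cfg.alpha_min_coverage).all(axis=1)
    p = bi.pooled_ancestral_p()
    with np.errstate(invalid="ignore"):
        pi_ok = 2.0 * p * (1.0 - p) > cfg.alpha_min_pi_ini
    return cov_ok & np.nan_to_num(pi_ok, nan=False)


def screen_chi(
    bi: BiallelicTable,
    cfg: ScreenConfig | None = None,
    coverage: np.ndarray | None = None,
    local_median: np.ndarray | None = None,
    global_median: float | None = None,
) -> np.ndarray:
    """Diversity-analysis screen over the 22 evolving populations.

    The local median is the per-site median coverage across AC, AS and the
    20 treatment populations; the global median is the median of the local
    medians over the screened table.
    """
    cfg = cfg or ScreenConfig()
    m = bi.manifest
    anc = ["AS", "AC"]
    treat = [n for t in ("Salt", "Cad", "Temp", "Spatial") for n in m.treatment(t)]
    if len(treat) != 20:
        raise KeyError("chi screen requires the 20 treatment populations")
    _check_populations(m, anc + treat)
    cov = bi.total_cov if coverage is None else coverage
    anc_ok = (cov[:, m.indices(anc)] >= cfg.chi_min_ancestor_coverage).all(axis=1)
    tr_ok = (cov[:, m.indices(treat)] >= cfg.chi_min_treatment_coverage).all(axis=1)
    if local_median is None:
        local_median = np.median(cov[:, m.indices(anc + treat)], axis=1)
    if global_median is None:
        global_median = float(np.median(local_median))
    med_ok = local_median <= cfg.chi_median_factor * global_median
    pi = bi.pi_ini
    with np.errstate(invalid="ignore"):
        pi_ok = pi > cfg.chi_min_pi_ini
    return anc_ok & tr_ok & med_ok & np.nan_to_num(pi_ok, nan=False)


def stratify_d(
    d: np.ndarray, cfg: ScreenConfig | None = None, bin_width: float = 0.1
) -> pd.DataFrame:
    """Partition sites by ancestral differentiation.

    Returns a frame with a ``stratum`` column (``low``/``mid``/``high``;
    boundary values fall in ``mid``) and a ``bin`` column of equal-width
    bins over [0,1] for profile curves.
    """
    cfg = cfg or ScreenConfig()
    d = np.asarray(d, dtype=float)
    stratum = np.where(d < cfg.d_low, "low", np.where(d > cfg.d_high, "high", "mid"))
    nbins = int(np.ceil(1.0 / bin_width))
    bins = np.minimum((d / bin_width).astype(int), nbins - 1)
    return pd.DataFrame({"d": d, "stratum": stratum, "bin": bins})
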