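"""Nucleotide diversity and among-replicate F_ST under unequal coverage.

Windowed pi follows the Pool-seq convention: per-site heterozygosity
``1 - sum(f^2)`` from read counts, corrected for the two sampling stages
(reads from the pool, pool from the population) by the unbiased factors
``c/(c-1)`` and ``n/(n-1)`` with ``c`` the read depth and ``n`` the pool
size in chromosomes, averaged over qualifying positions of 10 kb windows.

F_ST among the replicate populations of a treatment is Nei's fixation
index computed as a ratio of averages, ``1 - mean(H_S)/mean(H_T)``.
Because unequal read depth inflates apparent differentiation, a
coverage-matched estimate resamples, at every site, an equal number of
reads for the i-th-ranked population of each treatment (rank by depth,
take the across-treatment minimum) and averages F_ST over resampling
repeats.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# per-site pi with pool-sequencing correction
# ---------------------------------------------------------------------------

def corrected_site_pi(counts6: np.ndarray, pool_size: int = 140, min_count: int = 2) -> np.ndarray:
    """Unbiased per-site pi from sync count rows (A,T,C,G,N,del).

    N reads are ambiguous and excluded.  Alleles supported by fewer than
    ``min_count`` reads are treated as sequencing noise (site contribution
    0 unless two alleles remain).  The raw ``1 - sum(f^2)`` is scaled by
    ``c/(c-1) * n/(n-1)`` to unbias the two-stage binomial sampling.
    """
    if pool_size < 2:
        raise ValueError("pool_size must be >= 2")
    c6 = np.atleast_2d(np.asarray(counts6, dtype=np.int64))
    alleles = np.concatenate([c6[:, :4], c6[:, 5:6]], axis=1)  # A,T,C,G,del
    alleles = np.where(alleles >= min_count, alleles, 0)
    cov = alleles.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = alleles / cov[:, None]
        raw = 1.0 - np.nansum(f * f, axis=1)
        corr = raw * cov / np.maximum(cov - 1, 1) * pool_size / (pool_size - 1)
    snp = (alleles > 0).sum(axis=1) >= 2
    return np.where(snp & (cov > 1), corr, 0.0)


def window_pi(
    chrom: np.ndarray,
    pos: np.ndarray,
    counts6: np.ndarray,
    window: int = 10_000,
    min_count: int = 2,
    min_coverage: int = 4,
    max_coverage: int = 400,
    pool_size: int = 140,
    min_fraction: float = 0.6,
    corrected: bool = True,
) -> pd.DataFrame:
    """Non-overlapping window pi for one population.

    Positions absent from the input count as uncovered.  A position
    qualifies when its (non-N) read depth lies in
    ``[min_coverage, max_coverage]``; window pi is the mean per-site pi
    over qualifying positions, and a window is valid when at least
    ``min_fraction`` of its positions qualify.
    """
    chrom = np.asarray(chrom, dtype=object)
    pos = np.asarray(pos, dtype=np.int64)
    c6 = np.asarray(counts6, dtype=np.int64)
    cov = c6[:, :4].sum(axis=1) + c6[:, 5]
    ok = (cov >= min_coverage) & (cov <= max_coverage)
    if corrected:
        site_pi = corrected_site_pi(c6, pool_size=pool_size, min_count=min_count)
    else:
        alle = np.concatenate([c6[:, :4], c6[:, 5:6]], axis=1)
        alle = np.where(alle >= min_count, alle, 0)
        tot = alle.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = alle / tot[:, None]
        site_pi = np.where(tot > 0, 1.0 - np.nansum(f * f, axis=1), 0.0)
    df = pd.DataFrame(
        {
            "chrom": chrom,
            "win": (pos - 1) // window,
            "ok": ok,
            "pi": np.where(ok, site_pi, 0.0),
        }
    )
    g = df.groupby(["chrom", "win"], sort=True).agg(
        n_qual=("ok", "sum"), pi_sum=("pi", "sum")
    ).reset_index()
    g["start"] = g["win"] * window + 1
    g["end"] = (g["win"] + 1) * window
    g["fraction_covered"] = g["n_qual"] / window
    with np.errstate(invalid="ignore", divide="ignore"):
        g["pi"] = np.where(g["n_qual"] > 0, g["pi_sum"] / g["n_qual"], np.nan)
    g["valid"] = g["fraction_covered"] >= min_fraction
    return g[["chrom", "start", "end", "pi", "n_qual", "fraction_covered", "valid"]]


# ---------------------------------------------------------------------------
# stratified diversity comparisons
# ---------------------------------------------------------------------------

def pi_by_stratum(site_pi: np.ndarray, strata: np.ndarray) -> pd.DataFrame:
    """Mean pi per stratum with SE across replicate populations.

    ``site_pi`` is (n_sites, n_replicates); the replicate mean is taken
    over sites within a stratum first, then averaged across replicates
    (SE = SD of replicate means / sqrt(n_replicates)).  Empty strata are
    flagged undefined rather than reported as zero.
    """
    site_pi = np.atleast_2d(np.asarray(site_pi, dtype=float))
    strata = np.asarray(strata)
    rows = []
    for s in pd.unique(strata):
        mask = strata == s
        if mask.sum() == 0:
            rows.append({"stratum": s, "mean_pi": np.nan, "se": np.nan, "n_sites": 0,
                         "defined": False})
            continue
        rep_means = site_pi[mask].mean(axis=0)
        n_rep = rep_means.size
        se = rep_means.std(ddof=1) / np.sqrt(n_rep) if n_rep > 1 else np.nan
        rows.append(
            {
                "stratum": s,
                "mean_pi": float(rep_means.mean()),
                "se": float(se),
                "n_sites": int(mask.sum()),
                "defined": True,
            }
        )
    return pd.DataFrame(rows)


def anova_tukey(groups: dict[str, np.ndarray]):
    """One-way fixed-effects ANOVA plus Tukey HSD pairwise comparisons.

    ``groups`` maps treatment label to replicate values.  Returns
    ``(F, p, df_between, df_within, tukey_frame)``.  A zero within-group
    mean square is reported as ``F = inf`` with p below machine precision.
    """
    labels = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    for k, a in zip(labels, arrays):
        if a.size < 2:
            raise ValueError(f"group {k!r} needs at least 2 values")
    df_b = len(arrays) - 1
    df_w = sum(a.size for a in arrays) - len(arrays)
    grand = np.concatenate(arrays).mean()
    ss_b = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_w = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if ss_w == 0.0:
        if ss_b == 0.0:
            f_stat, p = 0.0, 1.0
        else:
            f_stat, p = np.inf, 0.0
    else:
        f_stat = (ss_b / df_b) / (ss_w / df_w)
        p = float(stats.f.sf(f_stat, df_b, df_w))
    rows = []
    if ss_w > 0:
        hsd = stats.tukey_hsd(*arrays)
        for i in range(len(arrays)):
            for j in range(i + 1, len(arrays)):
                rows.append(
                    {
                        "group1": labels[i],
                        "group2": labels[j],
                        "diff": arrays[i].mean() - arrays[j].mean(),
                        "p_adj": float(hsd.pvalue[i, j]),
                    }
                )
    tukey = pd.DataFrame(rows, columns=["group1", "group2", "diff", "p_adj"])
    return float(f_stat), float(p), df_b, df_w, tukey


# ---------------------------------------------------------------------------
# Nei F_ST
# ---------------------------------------------------------------------------

def heterozygosities(freqs: np.ndarray):
    """Within- and total expected heterozygosity per site.

    ``freqs`` is (n_sites, k) allele frequencies of k replicate
    populations.  H_S is the mean of ``2 p (1-p)`` across populations;
    H_T uses the unweighted mean frequency.
    """
    f = np.atleast_2d(np.asarray(freqs, dtype=float))
    hs = (2.0 * f * (1.0 - f)).mean(axis=1)
    pbar = f.mean(axis=1)
    ht = 2.0 * pbar * (1.0 - pbar)
    return hs, ht


def fst_nei(hs: np.ndarray, ht: np.ndarray, ratio_of_averages: bool = True) -> float:
    """Nei's mean F_ST over sites: ``1 - mean(H_S) / mean(H_T)``.

    Sites with ``H_T = 0`` carry no information and are excluded from
    both means.  ``ratio_of_averages=False`` gives the mean of per-site
    ratios instead (sensitivity variant).
    """
    hs = np.atleast_1d(np.asarray(hs, dtype=float))
    ht = np.atleast_1d(np.asarray(ht, dtype=float))
    ok = ht > 0
    if not ok.any():
        raise ValueError("all sites have H_T = 0; F_ST undefined")
    if ratio_of_averages:
        return float(1.0 - hs[ok].mean() / ht[ok].mean())
    return float(np.mean(1.0 - hs[ok] / ht[ok]))


def coverage_matched_fst(
    treatments: dict[str, tuple[np.ndarray, np.ndarray]],
    repeats: int = 10,
    seed: int | np.random.Generator = 0,
    ratio_of_averages: bool = True,
) -> pd.DataFrame:
    """Coverage-matched F_ST per treatment.

    ``treatments`` maps label to ``(minor_counts, coverages)`` arrays of
    shape (n_sites, k).  Per site, the k populations of each treatment
    are ranked by coverage; the i-th ranked population of every treatment
    is subsampled (without replacement) to the across-treatment minimum
    coverage of rank i.  F_ST is recomputed per repeat from the resampled
    frequencies and averaged.  Sites where any matched coverage is zero
    are skipped.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = list(treatments)
    minors = {t: np.atleast_2d(np.asarray(treatments[t][0], np.int64)) for t in labels}
    covs = {t: np.atleast_2d(np.asarray(treatments[t][1], np.int64)) for t in labels}
    n_sites = next(iter(minors.values())).shape[0]
    # rank populations by coverage (descending) within treatment per site
    order = {t: np.argsort(-covs[t], axis=1, kind="stable") for t in labels}
    cov_ranked = {t: np.take_along_axis(covs[t], order[t], axis=1) for t in labels}
    minor_ranked = {t: np.take_along_axis(minors[t], order[t], axis=1) for t in labels}
    n_match = np.minimum.reduce([cov_ranked[t] for t in labels])  # (n_sites, k)
    usable = (n_match > 0).all(axis=1)
    n_used = int(usable.sum())
    rows = []
    for t in labels:
        cov_t = cov_ranked[t][usable]
        min_t = minor_ranked[t][usable]
        n_t = n_match[usable]
        fsts, hs_means, ht_means = [], [], []
        for _ in range(repeats):
            sub = rng.hypergeometric(min_t, cov_t - min_t, n_t)
            f = sub / n_t
            hs, ht = heterozygosities(f)
            ok = ht > 0
            if not ok.any():
                continue
            fsts.append(fst_nei(hs, ht, ratio_of_averages))
            hs_means.append(hs[ok].mean())
            ht_means.append(ht[ok].mean())
        rows.append(
            {
                "treatment": t,
                "fst": float(np.mean(fsts)) if fsts else np.nan,
                "mean_hs": float(np.mean(hs_means)) if hs_means else np.nan,
                "mean_ht": float(np.mean(ht_means)) if ht_means else np.nan,
                "n_sites": n_used,
                "repeats": repeats,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# genomic regions
# ---------------------------------------------------------------------------

#: approximately recombinationally independent regions (1-based inclusive)
REGIONS = {
    "2L": (1, 7_307_159, "2L-left"),
    "2R": (10_368_692, None, "2R-right"),
    "3L": (1, 7_753_553, "3L-left"),
    "3R": (17_055_561, None, "3R-right"),
    "X": (1, None, "X"),
}


def assign_region(chrom: str, pos: int) -> str:
    """Map a coordinate to one of the five regions, or ``none``."""
    if chrom not in REGIONS:
        raise KeyError(f"unknown chromosome arm {chrom!r}")
    lo, hi, label = REGIONS[chrom]
    if pos >= lo and (hi is None or pos <= hi):
        return label
    return "none"


def x_autosome_contrast(region_fst: pd.DataFrame) -> dict:
    """Paired t-test of X vs mean-autosome F_ST across treatments.

    ``region_fst`` needs columns ``treatment``, ``region``, ``fst``.
    """
    x_vals, auto_vals = [], []
    for t, sub in region_fst.groupby("treatment"):
        x = sub.loc[sub["region"] == "X", "fst"]
        a = sub.loc[sub["region"] != "X", "fst"]
        if len(x) == 1 and len(a) >= 1:
            x_vals.append(float(x.iloc[0]))
            auto_vals.append(float(a.mean()))
    if len(x_vals) < 2:
        raise ValueError("need at least 2 treatments with X and autosome values")
    diffs = np.asarray(x_vals) - np.asarray(auto_vals)
    sd = diffs.std(ddof=1)
    if sd == 0:
        degenerate = True
        t_stat = 0.0 if diffs.mean() == 0 else np.inf * np.sign(diffs.mean())
        p = 1.0 if diffs.mean() == 0 else 0.0
    else:
        degenerate = False
        t_stat = diffs.mean() / (sd / np.sqrt(diffs.size))
        p = float(2 * stats.t.sf(abs(t_stat), diffs.size - 1))
    return {
        "t": float(t_stat),
        "df": diffs.size - 1,
        "p": p,
        "mean_x": float(np.mean(x_vals)),
        "mean_autosome": float(np.mean(auto_vals)),
        "degenerate": degenerate,
    }
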