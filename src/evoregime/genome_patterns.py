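"""Genome-scale diagnostics around the differentiation scan.

These operations probe whether differentiated sites behave like direct
selection targets or like passengers of linked selection: annotation-class
enrichment across significance bins, clustering of significant sites
against a permutation null, the decay of between-group F_ST with distance
from focal sites, inversion frequencies from marker SNPs, an ad hoc
conditional-neutrality classification, and the standardized
allele-frequency correlation between treatments.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from evoregime.differentiation import by_adjust


def enrichment_by_bin(
    neglogq: np.ndarray, is_class_a: np.ndarray, n_bins: int = 11
) -> pd.DataFrame:
    """Class-A/class-B count ratio per -log10(q) bin, standardized to 1.

    Bins are equal width over the observed -log q range.  The ratio of a
    bin with no class-B sites is undefined (flagged) and excluded from
    the standardizing mean.
    """
    x = np.asarray(neglogq, dtype=float)
    a = np.asarray(is_class_a, dtype=bool)
    if x.size == 0:
        raise ValueError("no sites")
    lo, hi = x.min(), x.max()
    width = (hi - lo) / n_bins or 1.0
    idx = np.minimum(((x - lo) / width).astype(int), n_bins - 1)
    rows = []
    for b in range(n_bins):
        m = idx == b
        n_a, n_b = int((m & a).sum()), int((m & ~a).sum())
        ratio = n_a / n_b if n_b > 0 else np.nan
        rows.append({"bin": b, "lo": lo + b * width, "hi": lo + (b + 1) * width,
                     "n_a": n_a, "n_b": n_b, "ratio": ratio, "defined": n_b > 0})
    df = pd.DataFrame(rows)
    mean_ratio = df.loc[df["defined"], "ratio"].mean()
    df["standardized"] = df["ratio"] / mean_ratio
    return df


def beta_clustering(
    beta_pos: np.ndarray,
    alpha_pos: np.ndarray,
    window_lengths=(50, 100, 500, 1000, 5000, 10_000, 50_000),
    n_focal: int = 5000,
    n_perm: int = 100,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Fraction of significant sites among screened sites near significant
    sites, versus a label-permutation null.

    Positions are within one chromosome (or globally unique).  For each
    window length L, windows of length L are centred on up to ``n_focal``
    randomly chosen significant ("beta") sites; the focal site itself is
    excluded.  The observed mean fraction is compared with the mean and
    95% band of ``n_perm`` random reassignments of the beta labels over
    the screened ("alpha") positions.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    alpha = np.sort(np.asarray(alpha_pos, dtype=np.int64))
    beta = np.sort(np.asarray(beta_pos, dtype=np.int64))
    if beta.size == 0:
        raise ValueError("no significant sites")
    if not np.isin(beta, alpha).all():
        raise ValueError("beta positions must be a subset of alpha positions")
    is_beta = np.isin(alpha, beta)

    def mean_fraction(labels: np.ndarray, focal: np.ndarray, half: float):
        lo = np.searchsorted(alpha, focal - half, side="left")
        hi = np.searchsorted(alpha, focal + half, side="right")
        cum = np.concatenate([[0], np.cumsum(labels)])
        n_in = hi - lo
        b_in = cum[hi] - cum[lo]
        # exclude the focal site (always a beta under the true labelling)
        f_idx = np.searchsorted(alpha, focal)
        b_in = b_in - labels[f_idx]
        n_in = n_in - 1
        ok = n_in > 0
        if not ok.any():
            return np.nan, 0
        return float((b_in[ok] / n_in[ok]).mean()), int(ok.sum())

    rows = []
    for L in window_lengths:
        half = L / 2
        k = min(n_focal, beta.size)
        focal = rng.choice(beta, size=k, replace=False)
        obs, usable = mean_fraction(is_beta, focal, half)
        null = []
        for _ in range(n_perm):
            perm = np.zeros(alpha.size, dtype=np.int64)
            perm[rng.choice(alpha.size, size=beta.size, replace=False)] = 1
            pfocal = rng.choice(alpha[perm.astype(bool)], size=k, replace=False)
            val, _ = mean_fraction(perm, pfocal, half)
            null.append(val)
        null = np.asarray(null, dtype=float)
        rows.append(
            {
                "window": L,
                "observed": obs,
                "usable_focal": usable,
                "perm_mean": float(np.nanmean(null)),
                "perm_lo": float(np.nanpercentile(null, 2.5)),
                "perm_hi": float(np.nanpercentile(null, 97.5)),
            }
        )
    return pd.DataFrame(rows)


def fst_decay(
    focal_pos: np.ndarray,
    site_pos: np.ndarray,
    site_fst: np.ndarray,
    weights: np.ndarray | None = None,
    window: int = 50,
    max_dist: int = 2000,
    min_weight: float = 0.0,
) -> pd.DataFrame:
    """Weighted mean F_ST in distance windows away from focal sites.

    Non-overlapping ``window``-bp bins run to ``max_dist`` on both sides
    (distances folded).  The focal site itself is excluded from the first
    bin; bins whose summed weight is ``<= min_weight`` are dropped for a
    focal site.  Results are averaged across focal sites per bin.
    """
    focal = np.asarray(focal_pos, dtype=np.int64)
    pos = np.asarray(site_pos, dtype=np.int64)
    fst = np.asarray(site_fst, dtype=float)
    w = np.ones_like(fst) if weights is None else np.asarray(weights, dtype=float)
    order = np.argsort(pos)
    pos, fst, w = pos[order], fst[order], w[order]
    n_bins = max_dist // window
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins)
    for f in focal:
        lo = np.searchsorted(pos, f - max_dist, side="left")
        hi = np.searchsorted(pos, f + max_dist, side="right")
        d = np.abs(pos[lo:hi] - f)
        keep = d < max_dist
        d, fs, ws = d[keep], fst[lo:hi][keep], w[lo:hi][keep]
        not_focal = ~((pos[lo:hi][keep] == f))
        d, fs, ws = d[not_focal], fs[not_focal], ws[not_focal]
        b = d // window
        wsum = np.bincount(b, weights=ws, minlength=n_bins)
        fsum = np.bincount(b, weights=ws * fs, minlength=n_bins)
        ok = wsum > min_weight
        sums[ok] += fsum[ok] / wsum[ok]
        counts[ok] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_fst = np.where(counts > 0, sums / counts, np.nan)
    return pd.DataFrame(
        {
            "dist_lo": np.arange(n_bins) * window,
            "dist_hi": (np.arange(n_bins) + 1) * window,
            "mean_fst": mean_fst,
            "n_windows": counts.astype(int),
        }
    )


def inversion_frequency(marker_counts: np.ndarray, marker_cov: np.ndarray) -> float:
    """Coverage-weighted inversion frequency from marker SNPs.

    Equals total inversion-allele reads over total reads across markers,
    i.e. the coverage-weighted mean of marker frequencies.  NaN when no
    marker has coverage.
    """
    cts = np.asarray(marker_counts, dtype=float)
    cov = np.asarray(marker_cov, dtype=float)
    if cov.sum() <= 0:
        return float("nan")
    return float(cts.sum() / cov.sum())


def classify_conditional_neutrality(
    p_ga: np.ndarray,
    p_ac: np.ndarray,
    p_as: np.ndarray,
    p_cad: np.ndarray,
    p_salt: np.ndarray,
    threshold: float = 0.1,
) -> np.ndarray:
    """Ad hoc conditional-neutrality labels for differentiated sites.

    A site looks neutral in cadmium when the cadmium-adapted ancestor
    stayed near the grand ancestor (``|p_AC - p_GA| < 0.1``) and the Cad
    treatment mean stayed near the initial frequency
    (``|p_Cad - p_ini| < 0.1`` with ``p_ini = (p_AC + p_AS)/2``);
    symmetrically for salt.  Returns labels in
    ``{CN-in-cad, CN-in-salt, both, neither}``.
    """
    p_ga, p_ac, p_as = map(np.atleast_1d, (p_ga, p_ac, p_as))
    p_cad, p_salt = map(np.atleast_1d, (p_cad, p_salt))
    p_ini = 0.5 * (p_ac + p_as)
    cn_cad = (np.abs(p_ac - p_ga) < threshold) & (np.abs(p_cad - p_ini) < threshold)
    cn_salt = (np.abs(p_as - p_ga) < threshold) & (np.abs(p_salt - p_ini) < threshold)
    out = np.where(
        cn_cad & cn_salt, "both", np.where(cn_cad, "CN-in-cad", np.where(cn_salt, "CN-in-salt", "neither"))
    )
    return out


def standardized_correlation(
    freq_a: np.ndarray,
    freq_b: np.ndarray,
    selected: np.ndarray,
    control: np.ndarray,
) -> dict:
    """Difference of Pearson correlations: selected minus control sites.

    ``freq_a``/``freq_b`` are treatment-mean allele frequencies per site
    (fixed allele orientation).  A raw between-treatment correlation
    arises from variation in initial frequency alone; subtracting the
    correlation over non-differentiated control sites isolates the
    selection signal.
    """
    fa, fb = np.asarray(freq_a, float), np.asarray(freq_b, float)
    sel = np.asarray(selected)
    ctl = np.asarray(control)
    if sel.dtype == bool:
        sel = np.flatnonzero(sel)
    if ctl.dtype == bool:
        ctl = np.flatnonzero(ctl)
    if sel.size < 3 or ctl.size < 3:
        raise ValueError("need at least 3 selected and 3 control sites")
    out = {}
    for name, idx in (("selected", sel), ("control", ctl)):
        x, y = fa[idx], fb[idx]
        if np.std(x) == 0 or np.std(y) == 0:
            out[f"r_{name}"] = np.nan
        else:
            out[f"r_{name}"] = float(stats.pearsonr(x, y)[0])
    out["diff_cor"] = out["r_selected"] - out["r_control"]
    return out


def match_control_sites(
    candidate_idx: np.ndarray,
    selected_idx: np.ndarray,
    pi_ini: np.ndarray,
    rng: np.random.Generator,
    n_strata: int = 10,
) -> np.ndarray:
    """Sample control sites matching the selected sites' initial-diversity
    distribution by stratified sampling."""
    edges = np.linspace(0, 0.5 + 1e-9, n_strata + 1)
    sel_bins = np.digitize(pi_ini[selected_idx], edges) - 1
    cand_bins = np.digitize(pi_ini[candidate_idx], edges) - 1
    chosen = []
    for b in range(n_strata):
        need = int((sel_bins == b).sum())
        pool = candidate_idx[cand_bins == b]
        if need == 0 or pool.size == 0:
            continue
        chosen.append(rng.choice(pool, size=min(need, pool.size), replace=False))
    if not chosen:
        return np.empty(0, dtype=np.int64)
    return np.concatenate(chosen)


def fisher_screen(
    minor_as: np.ndarray,
    cov_as: np.ndarray,
    minor_ac: np.ndarray,
    cov_ac: np.ndarray,
    q_cutoff: float = 0.001,
) -> pd.DataFrame:
    """Two-sided Fisher exact test of AS vs AC allele counts per site,
    BY-adjusted; flags sites with q below the cutoff as ancestrally
    differentiated ("selected") candidates."""
    m_as = np.atleast_1d(np.asarray(minor_as, np.int64))
    c_as = np.atleast_1d(np.asarray(cov_as, np.int64))
    m_ac = np.atleast_1d(np.asarray(minor_ac, np.int64))
    c_ac = np.atleast_1d(np.asarray(cov_ac, np.int64))
    p = np.ones(m_as.size)
    for i in range(m_as.size):
        tab = [[m_as[i], c_as[i] - m_as[i]], [m_ac[i], c_ac[i] - m_ac[i]]]
        if c_as[i] == 0 or c_ac[i] == 0:
            continue
        p[i] = stats.fisher_exact(tab, alternative="two-sided")[1]
    q = by_adjust(p)
    return pd.DataFrame({"p": p, "q": q, "selected": q < q_cutoff})
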