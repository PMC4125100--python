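"""Cochran-Mantel-Haenszel differentiation scan between treatment groups.

Replicate populations of the two groups are paired and each pair
contributes one 2x2 stratum (minor/major read counts x group) to a CMH
test.  Because the replicate pairing is arbitrary, the test is repeated
under five rotational pairings; an optional ancestor pair is pinned as a
fixed stratum in every pairing.  Per-site p-values are combined as the
geometric mean over the five pairings and converted to q-values with the
Benjamini-Yekutieli step-up procedure (valid under arbitrary dependence).

A site is called differentiated (a "beta-site") either when the combined
q-value passes the FDR cutoff (rule ``combined``) or when all five
per-pairing q-values pass it (rule ``per-pairing``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

P_FLOOR = 1e-320  # avoid log(0) when combining extreme p-values


@dataclass
class PairingScheme:
    """Five bijections between the replicate lists of two groups.

    ``pairings[m]`` is a list of (i, j) column-index pairs; when
    ``ancestors`` is set the pair (0, 0) is pinned in every pairing and
    replicate indices start at 1.
    """

    pairings: list = field(default_factory=list)

    @classmethod
    def rotational(cls, n_replicates: int = 5, ancestors: bool = False) -> "PairingScheme":
        off = 1 if ancestors else 0
        pairings = []
        for m in range(n_replicates):
            pairs = [(0, 0)] if ancestors else []
            pairs += [(off + i, off + (i + m) % n_replicates) for i in range(n_replicates)]
            pairings.append(pairs)
        return cls(pairings)

    def validate(self, n1: int, n2: int) -> None:
        seen = set()
        for pairs in self.pairings:
            key = tuple(sorted(pairs))
            if key in seen:
                raise ValueError("pairings must be distinct")
            seen.add(key)
            if sorted(i for i, _ in pairs) != list(range(n1)) or sorted(
                j for _, j in pairs
            ) != list(range(n2)):
                raise ValueError("each pairing must be a complete bijection")


def cmh_test(tables, continuity_correction: bool = False):
    """CMH chi-square statistic (1 df) and upper-tail p for K 2x2 strata.

    ``tables`` is a (K, 2, 2) array.  Strata with a zero row or column
    margin carry no information and are dropped; if all strata are
    degenerate the test returns ``(0.0, 1.0)``.
    """
    t = np.asarray(tables, dtype=float)
    if t.ndim == 2:
        t = t[None]
    a, b, c, d = t[:, 0, 0], t[:, 0, 1], t[:, 1, 0], t[:, 1, 1]
    n = a + b + c + d
    ok = (a + b > 0) & (c + d > 0) & (a + c > 0) & (b + d > 0) & (n > 1)
    if not ok.any():
        return 0.0, 1.0
    a, b, c, d, n = a[ok], b[ok], c[ok], d[ok], n[ok]
    e = (a + b) * (a + c) / n
    v = (a + b) * (c + d) * (a + c) * (b + d) / (n * n * (n - 1))
    num = abs((a - e).sum())
    if continuity_correction:
        num = max(num - 0.5, 0.0)
    vs = v.sum()
    if vs == 0:
        return 0.0, 1.0
    stat = num**2 / vs
    return float(stat), float(stats.chi2.sf(stat, 1))


def _cmh_bulk(minor1, cov1, minor2, cov2, pairs):
    """Vectorised CMH over sites: one stratum per (i, j) pair.

    ``minor*``/``cov*`` are (n_sites, n_pops) minor-allele counts and
    allelic coverages of the two groups.
    """
    num = np.zeros(minor1.shape[0])
    var = np.zeros(minor1.shape[0])
    for i, j in pairs:
        a = minor1[:, i].astype(float)
        b = (cov1[:, i] - minor1[:, i]).astype(float)
        c = minor2[:, j].astype(float)
        d = (cov2[:, j] - minor2[:, j]).astype(float)
        n = a + b + c + d
        ok = (a + b > 0) & (c + d > 0) & (a + c > 0) & (b + d > 0) & (n > 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            e = (a + b) * (a + c) / n
            v = (a + b) * (c + d) * (a + c) * (b + d) / (n * n * (n - 1))
        num += np.where(ok, a - e, 0.0)
        var += np.where(ok, v, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.where(var > 0, num**2 / var, 0.0)
    return stat, stats.chi2.sf(stat, 1)


def by_adjust(pvalues) -> np.ndarray:
    """Benjamini-Yekutieli q-values, returned in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    m = p.size
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m * c_m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def geometric_mean_p(p_matrix: np.ndarray) -> np.ndarray:
    """Row-wise geometric mean of p-values, floored at ``P_FLOOR``."""
    p = np.maximum(np.asarray(p_matrix, dtype=float), P_FLOOR)
    return np.exp(np.log(p).mean(axis=1))


def scan_pair(
    minor1: np.ndarray,
    cov1: np.ndarray,
    minor2: np.ndarray,
    cov2: np.ndarray,
    scheme: PairingScheme | None = None,
    rule: str = "combined",
    fdr: float = 1e-5,
) -> pd.DataFrame:
    """Run the five-pairing CMH scan between two groups of populations.

    Group arrays hold per-site minor-allele read counts and allelic
    coverages, one column per population (column 0 is the ancestor when
    the scheme pins ancestors).  Returns per-site p-values for the five
    pairings, the combined p, BY q-values and the beta call.
    """
    minor1, cov1 = np.atleast_2d(minor1), np.atleast_2d(cov1)
    minor2, cov2 = np.atleast_2d(minor2), np.atleast_2d(cov2)
    if scheme is None:
        ancestors = minor1.shape[1] == 6
        scheme = PairingScheme.rotational(5, ancestors=ancestors)
    scheme.validate(minor1.shape[1], minor2.shape[1])
    pmat = np.column_stack(
        [_cmh_bulk(minor1, cov1, minor2, cov2, pairs)[1] for pairs in scheme.pairings]
    )
    p_comb = geometric_mean_p(pmat)
    q_comb = by_adjust(p_comb)
    q_pair = np.column_stack([by_adjust(pmat[:, m]) for m in range(pmat.shape[1])])
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = np.where(cov1 > 0, minor1 / cov1, np.nan)
        f2 = np.where(cov2 > 0, minor2 / cov2, np.nan)
    dp = np.abs(np.nanmean(f1, axis=1) - np.nanmean(f2, axis=1))
    out = pd.DataFrame(
        {f"p_{m + 1}": pmat[:, m] for m in range(pmat.shape[1])}
        | {f"q_{m + 1}": q_pair[:, m] for m in range(pmat.shape[1])}
    )
    out["p_comb"] = p_comb
    out["q"] = q_comb
    out["dp"] = dp
    out["beta"] = call_beta(out, rule=rule, cutoff=fdr)
    return out


def call_beta(results: pd.DataFrame, rule: str = "combined", cutoff: float = 1e-5) -> np.ndarray:
    """Flag differentiated sites.

    ``combined``: the BY q of the combined (geometric-mean) p passes the
    cutoff.  ``per-pairing``: every one of the five per-pairing BY
    q-values passes it.
    """
    if len(results) == 0:
        return np.zeros(0, dtype=bool)
    if rule == "combined":
        return (results["q"].to_numpy() <= cutoff)
    if rule == "per-pairing":
        qcols = [c for c in results.columns if c.startswith("q_")]
        return (results[qcols].to_numpy() <= cutoff).all(axis=1)
    raise ValueError(f"unknown beta-calling rule {rule!r}")


def pseudo_treatment_null(
    minor_cad: np.ndarray,
    cov_cad: np.ndarray,
    minor_salt: np.ndarray,
    cov_salt: np.ndarray,
    n_combinations: int = 15,
    seed: int | np.random.Generator = 0,
    rule: str = "combined",
    fdr: float = 1e-5,
) -> pd.DataFrame:
    """False-positive control: scans between random half/half relabelings.

    Each combination assigns half of the cadmium and half of the salt
    populations to pseudo-treatment A and the rest to B, then runs the
    identical five-pairing scan A vs B.  Returns the per-combination
    beta-site counts.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    kc, ks = minor_cad.shape[1], minor_salt.shape[1]
    if kc < 2 or ks < 2:
        raise ValueError("need at least 2 populations per environment")
    rows = []
    for it in range(n_combinations):
        # half of each environment to A; alternate which environment
        # contributes the extra population so group sizes stay equal
        nc_a = kc // 2 + (it % 2 if kc % 2 else 0)
        ns_a = (kc + ks) // 2 - nc_a
        cad_a = rng.permutation(kc)[:nc_a]
        salt_a = rng.permutation(ks)[:ns_a]
        cad_b = np.setdiff1d(np.arange(kc), cad_a)
        salt_b = np.setdiff1d(np.arange(ks), salt_a)
        m_a = np.column_stack([minor_cad[:, cad_a], minor_salt[:, salt_a]])
        c_a = np.column_stack([cov_cad[:, cad_a], cov_salt[:, salt_a]])
        m_b = np.column_stack([minor_cad[:, cad_b], minor_salt[:, salt_b]])
        c_b = np.column_stack([cov_cad[:, cad_b], cov_salt[:, salt_b]])
        k = min(m_a.shape[1], m_b.shape[1])
        scheme = PairingScheme.rotational(k, ancestors=False)
        res = scan_pair(m_a[:, :k], c_a[:, :k], m_b[:, :k], c_b[:, :k], scheme, rule, fdr)
        rows.append(
            {
                "combination": it,
                "cad_in_A": ",".join(map(str, sorted(cad_a))),
                "salt_in_A": ",".join(map(str, sorted(salt_a))),
                "n_beta": int(res["beta"].sum()),
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["mean_beta"] = float(out["n_beta"].mean())
    out.attrs["max_beta"] = int(out["n_beta"].max())
    return out


def window_differentiation(
    results: pd.DataFrame, chrom: np.ndarray, pos: np.ndarray, window: int = 5000
) -> pd.DataFrame:
    """Non-overlapping window summary of a scan.

    Windows are 1-based ``[k*window + 1, (k+1)*window]``; windows without
    sites are omitted.  Reports the mean -log10 q, mean |allele-frequency
    difference| and site count.
    """
    df = pd.DataFrame(
        {
            "chrom": np.asarray(chrom),
            "win": (np.asarray(pos) - 1) // window,
            "neglogq": -np.log10(np.maximum(results["q"].to_numpy(), P_FLOOR)),
            "dp": results["dp"].to_numpy(),
        }
    )
    g = df.groupby(["chrom", "win"], sort=True).agg(
        n=("neglogq", "size"), mean_neglogq=("neglogq", "mean"), mean_dp=("dp", "mean")
    )
    g = g.reset_index()
    g["start"] = g["win"] * window + 1
    g["end"] = (g["win"] + 1) * window
    return g[["chrom", "start", "end", "n", "mean_neglogq", "mean_dp"]]
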