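"""Numba Wright-Fisher kernel for the multilocus regime simulator.

Genomes are bit-packed: one uint64 word per haplotype holds up to 40
selected loci (bits 0..n_sel-1) plus one neutral site (bit n_sel).
Selected loci segregate independently (they model widely separated
targets); the neutral site co-segregates with selected locus 0 except
for a crossover with probability ``r_neutral`` per meiosis.

Selection is fecundity-weighted Wright-Fisher sampling: each offspring
draws two parents with probability proportional to
``exp(eff * (k - n_sel))`` where ``k`` counts favoured-allele copies
across the diploid genome and ``eff`` is the per-copy log-fitness of the
current environment.  Parents are drawn with Vose's alias method.  The
spatial regime shuffles adults into two resident demes of N/2, applies
opposite environments within demes, and takes exactly half of the next
generation from each deme (soft selection).
"""

import numpy as np
from numba import njit

REGIME_CODES = {"constant_A": 0, "constant_B": 1, "temporal": 2, "spatial": 3, "neutral": 4}

_M1 = np.uint64(0x5555555555555555)
_M2 = np.uint64(0x3333333333333333)
_M4 = np.uint64(0x0F0F0F0F0F0F0F0F)
_H01 = np.uint64(0x0101010101010101)


@njit(inline="always", cache=True)
def _popcount(x):
    x = x - ((x >> np.uint64(1)) & _M1)
    x = (x & _M2) + ((x >> np.uint64(2)) & _M2)
    x = (x + (x >> np.uint64(4))) & _M4
    return np.uint64((x * _H01) >> np.uint64(56))


@njit(inline="always", cache=True)
def _gamete(h1, h2, n_sel, r_neutral, full_bound):
    if n_sel == 0:
        mask = np.uint64(np.random.randint(0, 2))
    elif r_neutral >= 0.5:
        # neutral site unlinked: all loci assort freely, one draw
        mask = np.uint64(np.random.randint(0, full_bound))
    else:
        mask = np.uint64(np.random.randint(0, full_bound >> 1))
        nbit = mask & np.uint64(1)  # neutral site follows selected locus 0 ...
        if np.random.random() < r_neutral:  # ... unless a crossover separates them
            nbit ^= np.uint64(1)
        mask |= nbit << np.uint64(n_sel)
    return (h1 & ~mask) | (h2 & mask)


@njit(cache=True)
def _build_alias(w, n, alias, prob, small, large):
    """Vose alias tables for O(1) categorical sampling."""
    tot = 0.0
    for i in range(n):
        tot += w[i]
    ns = 0
    nl = 0
    for i in range(n):
        prob[i] = w[i] * n / tot
        if prob[i] < 1.0:
            small[ns] = i
            ns += 1
        else:
            large[nl] = i
            nl += 1
    while ns > 0 and nl > 0:
        ns -= 1
        s = small[ns]
        nl -= 1
        l = large[nl]
        alias[s] = l
        prob[l] = prob[l] + prob[s] - 1.0
        if prob[l] < 1.0:
            small[ns] = l
            ns += 1
        else:
            large[nl] = l
            nl += 1
    while nl > 0:
        nl -= 1
        prob[large[nl]] = 1.0
        alias[large[nl]] = large[nl]
    while ns > 0:
        ns -= 1
        prob[small[ns]] = 1.0
        alias[small[ns]] = small[ns]


@njit(inline="always", cache=True)
def _alias_draw(alias, prob, n):
    i = np.random.randint(0, n)
    if np.random.random() < prob[i]:
        return i
    return alias[i]


@njit(cache=True)
def _run_rep(haps, n_sel, regime, n_gen, wpos, wneg, r_neutral, seed):
    """Evolve one replicate in place."""
    np.random.seed(seed)
    n2 = haps.shape[0]
    N = n2 // 2
    half = N // 2
    selmask = (np.uint64(1) << np.uint64(n_sel)) - np.uint64(1)
    full_bound = np.int64(1) << (n_sel + 1)
    new = np.empty(n2, dtype=np.uint64)
    k = np.empty(N, dtype=np.int64)
    w = np.empty(N, dtype=np.float64)
    alias = np.empty(N, dtype=np.int64)
    prob = np.empty(N, dtype=np.float64)
    small = np.empty(N, dtype=np.int64)
    large = np.empty(N, dtype=np.int64)
    idx = np.empty(N, dtype=np.int64)
    for g in range(n_gen):
        neutral_gen = regime == 4 or n_sel == 0
        if not neutral_gen:
            for i in range(N):
                k[i] = _popcount(haps[2 * i] & selmask) + _popcount(haps[2 * i + 1] & selmask)
        if regime == 3 and not neutral_gen:
            for i in range(N):
                idx[i] = i
            for i in range(N - 1, 0, -1):
                j = np.random.randint(0, i + 1)
                t = idx[i]
                idx[i] = idx[j]
                idx[j] = t
            for deme in range(2):
                for i in range(half):
                    a = idx[deme * half + i]
                    w[i] = wpos[k[a]] if deme == 0 else wneg[k[a]]
                _build_alias(w, half, alias, prob, small, large)
                for j in range(half):
                    o = deme * half + j
                    for h in range(2):
                        p = idx[deme * half + _alias_draw(alias, prob, half)]
                        new[2 * o + h] = _gamete(
                            haps[2 * p], haps[2 * p + 1], n_sel, r_neutral, full_bound
                        )
            haps[:] = new
            continue
        if neutral_gen:
            for j in range(n2):
                p = np.random.randint(0, N)
                new[j] = _gamete(haps[2 * p], haps[2 * p + 1], n_sel, r_neutral, full_bound)
            haps[:] = new
            continue
        use_pos = regime == 0 or (regime == 2 and g % 2 == 0)
        for i in range(N):
            w[i] = wpos[k[i]] if use_pos else wneg[k[i]]
        _build_alias(w, N, alias, prob, small, large)
        for j in range(n2):
            p = _alias_draw(alias, prob, N)
            new[j] = _gamete(haps[2 * p], haps[2 * p + 1], n_sel, r_neutral, full_bound)
        haps[:] = new


@njit(cache=True)
def run_chunk(init_haps, seeds, n_sel, regime, n_gen, wpos, wneg, r_neutral, out_freqs):
    """Run a chunk of replicates; writes final per-locus frequencies."""
    n_loci = n_sel + 1
    n2 = init_haps.shape[1]
    for r in range(init_haps.shape[0]):
        haps = init_haps[r].copy()
        _run_rep(haps, n_sel, regime, n_gen, wpos, wneg, r_neutral, seeds[r])
        for j in range(n_loci):
            bit = np.uint64(1) << np.uint64(j)
            c = 0
            for i in range(n2):
                if haps[i] & bit:
                    c += 1
            out_freqs[r, j] = c / n2
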