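"""Numba kernels for whole-genome individual-based Wright-Fisher dynamics.

Genomes are bit-packed per haplotype into one uint64 row spanning all
chromosome arms; arm ``a`` owns words ``arm_word_lo[a] .. arm_word_hi[a]``
(each arm padded to whole words).  Selected sites are listed by global
word index, bit mask, and per-environment log-fitness of the alternate
allele.  Meioses draw a Poisson number of crossovers per arm (the map
length is the sex-averaged one: Drosophila males are achiasmatic) placed
uniformly over the arm's site index.
"""

import numpy as np
from numba import njit


@njit(inline="always", cache=True)
def _fill_bits(mask, lo, hi):
    """Set site bits [lo, hi) in an arm-local word array."""
    if hi <= lo:
        return
    w_lo = lo >> 6
    w_hi = (hi - 1) >> 6
    ones = np.uint64(0xFFFFFFFFFFFFFFFF)
    if w_lo == w_hi:
        width = hi - lo
        m = (ones >> np.uint64(64 - width)) << np.uint64(lo & 63)
        mask[w_lo] |= m
        return
    mask[w_lo] |= ones << np.uint64(lo & 63)
    for w in range(w_lo + 1, w_hi):
        mask[w] = ones
    tail = ((hi - 1) & 63) + 1
    mask[w_hi] |= ones >> np.uint64(64 - tail)


@njit(cache=True)
def _gamete(haps, parent, out, arm_word_lo, arm_word_hi, arm_n_sites, arm_maplen, scratch):
    """Write one recombinant gamete of ``parent`` into ``out``."""
    h1 = 2 * parent
    h2 = h1 + 1
    for a in range(arm_word_lo.shape[0]):
        wlo, whi = arm_word_lo[a], arm_word_hi[a]
        nw = whi - wlo
        cur = np.random.randint(0, 2)  # independent assortment per arm
        ncx = np.random.poisson(arm_maplen[a])
        if ncx == 0:
            src = h1 if cur == 0 else h2
            for w in range(nw):
                out[wlo + w] = haps[src, wlo + w]
            continue
        # crossover boundaries as site indices, sorted
        b = np.empty(ncx, dtype=np.int64)
        for c in range(ncx):
            b[c] = 1 + np.random.randint(0, arm_n_sites[a] - 1) if arm_n_sites[a] > 1 else 0
        b.sort()
        for w in range(nw):
            scratch[w] = np.uint64(0)
        # scratch = take-from-h2 mask, built segment by segment
        prev = 0
        for c in range(ncx):
            if cur == 1:
                _fill_bits(scratch, prev, b[c])
            prev = b[c]
            cur = 1 - cur
        if cur == 1:
            _fill_bits(scratch, prev, arm_n_sites[a])
        for w in range(nw):
            m = scratch[w]
            out[wlo + w] = (haps[h1, wlo + w] & ~m) | (haps[h2, wlo + w] & m)


@njit(cache=True)
def _log_fitness(haps, sel_word, sel_mask, sel_g, logw):
    """Per-individual log fitness summed over selected sites."""
    N = haps.shape[0] // 2
    for i in range(N):
        acc = 0.0
        for t in range(sel_word.shape[0]):
            w = sel_word[t]
            m = sel_mask[t]
            g = sel_g[t]
            if haps[2 * i, w] & m:
                acc += g
            if haps[2 * i + 1, w] & m:
                acc += g
        logw[i] = acc


@njit(inline="always", cache=True)
def _draw(cum, n, tot):
    u = np.random.random() * tot
    lo = 0
    hi = n - 1
    while lo < hi:
        mid = (lo + hi) // 2
        if cum[mid] < u:
            lo = mid + 1
        else:
            hi = mid
    return lo


@njit(cache=True)
def wf_generation(
    haps, new, arm_word_lo, arm_word_hi, arm_n_sites, arm_maplen,
    sel_word, sel_mask, sel_gA, sel_gB, env, scratch, logw, cum, idx,
):
    """One Wright-Fisher generation.

    ``env``: 0 = environment A, 1 = environment B, 2 = spatial split
    (resident demes of N/2, A then B, equal contributions), 3 = neutral.
    """
    N = haps.shape[0] // 2
    if env == 3 or sel_word.shape[0] == 0:
        for j in range(N):
            p1 = np.random.randint(0, N)
            p2 = np.random.randint(0, N)
            _gamete(haps, p1, new[2 * j], arm_word_lo, arm_word_hi, arm_n_sites, arm_maplen, scratch)
            _gamete(haps, p2, new[2 * j + 1], arm_word_lo, arm_word_hi, arm_n_sites, arm_maplen, scratch)
        return
    if env == 2:
        half = N // 2
        for i in range(N):
            idx[i] = i
        for i in range(N - 1, 0, -1):
            j = np.random.randint(0, i + 1)
            t = idx[i]
            idx[i] = idx[j]
            idx[j] = t
        for deme in range(2):
            g_arr = sel_gA if deme == 0 else sel_gB
            _log_fitness_subset(haps, sel_word, sel_mask, g_arr, logw, idx, deme * half, half)
            mx = logw[0]
            for i in range(1, half):
                if logw[i] > mx:
                    mx = logw[i]
            tot = 0.0
            for i in range(half):
                tot += np.exp(logw[i] - mx)
                cum[i] = tot
            for j in range(half):
                o = deme * half + j
                for h in range(2):
                    p = idx[deme * half + _draw(cum, half, tot)]
                    _gamete(haps, p, new[2 * o + h], arm_word_lo, arm_word_hi, arm_n_sites, arm_maplen, scratch)
        return
    g_arr = sel_gA if env == 0 else sel_gB
    _log_fitness(haps, sel_word, sel_mask, g_arr, logw)
    mx = logw[0]
    for i in range(1, N):
        if logw[i] > mx:
            mx = logw[i]
    tot = 0.0
    for i in range(N):
        tot += np.exp(logw[i] - mx)
        cum[i] = tot
    for j in range(N):
        for h in range(2):
            p = _draw(cum, N, tot)
            _gamete(haps, p, new[2 * j + h], arm_word_lo, arm_word_hi, arm_n_sites, arm_maplen, scratch)


@njit(cache=True)
def _log_fitness_subset(haps, sel_word, sel_mask, sel_g, logw, idx, off, n):
    for i in range(n):
        a = idx[off + i]
        acc = 0.0
        for t in range(sel_word.shape[0]):
            w = sel_word[t]
            m = sel_mask[t]
            if haps[2 * a, w] & m:
                acc += sel_g[t]
            if haps[2 * a + 1, w] & m:
                acc += sel_g[t]
        logw[i] = acc


@njit(cache=True)
def evolve(
    haps, n_gen, regime, arm_word_lo, arm_word_hi, arm_n_sites, arm_maplen,
    sel_word, sel_mask, sel_gA, sel_gB, seed, start_gen=0,
):
    """Evolve a population ``n_gen`` generations under a regime code:
    0 constant A, 1 constant B, 2 temporal (A first), 3 spatial, 4 neutral."""
    np.random.seed(seed)
    N = haps.shape[0] // 2
    wmax = 0
    for a in range(arm_word_lo.shape[0]):
        if arm_word_hi[a] - arm_word_lo[a] > wmax:
            wmax = arm_word_hi[a] - arm_word_lo[a]
    scratch = np.empty(wmax, dtype=np.uint64)
    logw = np.empty(N, dtype=np.float64)
    cum = np.empty(N, dtype=np.float64)
    idx = np.empty(N, dtype=np.int64)
    new = np.empty_like(haps)
    for g in range(start_gen, start_gen + n_gen):
        if regime == 0:
            env = 0
        elif regime == 1:
            env = 1
        elif regime == 2:
            env = 0 if g % 2 == 0 else 1
        elif regime == 3:
            env = 2
        else:
            env = 3
        wf_generation(
            haps, new, arm_word_lo, arm_word_hi, arm_n_sites, arm_maplen,
            sel_word, sel_mask, sel_gA, sel_gB, env, scratch, logw, cum, idx,
        )
        haps[:] = new


@njit(cache=True)
def found_cross(src1, src2, out, arm_word_lo, arm_word_hi, arm_n_sites, arm_maplen, seed):
    """Found a population: individual i = (gamete from src1, gamete from src2)."""
    np.random.seed(seed)
    N = out.shape[0] // 2
    n1 = src1.shape[0] // 2
    n2 = src2.shape[0] // 2
    wmax = 0
    for a in range(arm_word_lo.shape[0]):
        if arm_word_hi[a] - arm_word_lo[a] > wmax:
            wmax = arm_word_hi[a] - arm_word_lo[a]
    scratch = np.empty(wmax, dtype=np.uint64)
    for i in range(N):
        _gamete(src1, np.random.randint(0, n1), out[2 * i], arm_word_lo, arm_word_hi, arm_n_sites, arm_maplen, scratch)
        _gamete(src2, np.random.randint(0, n2), out[2 * i + 1], arm_word_lo, arm_word_hi, arm_n_sites, arm_maplen, scratch)
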