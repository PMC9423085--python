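"""Independent reference implementations used only to check the library.

Each oracle is a deliberately different route to the same quantity: scalar
loop-based transcriptions of the textbook formulas, exhaustive enumeration,
or direct tallying.  They never call the library code they verify.
"""

from __future__ import annotations

import itertools
from collections import Counter
from math import comb, log, pi as PI, sqrt

import numpy as np


# ---------------------------------------------------------------------------
# Weir-Cockerham (1984) variance components, scalar per-site transcription

def wc_fst_site(genos_a, genos_b):
    """(a, b, c) for one site from two lists of dosage codes (-1 missing)."""
    pops = []
    for genos in (genos_a, genos_b):
        g = [x for x in genos if x != -1]
        n = len(g)
        if n < 2:
            return (float("nan"),) * 3
        p = sum(g) / (2.0 * n)
        h = sum(1 for x in g if x == 1) / n
        pops.append((n, p, h))
    r = 2
    n_bar = sum(n for n, _, _ in pops) / r
    n_c = (r * n_bar - sum(n * n for n, _, _ in pops) / (r * n_bar)) / (r - 1)
    p_bar = sum(n * p for n, p, _ in pops) / (r * n_bar)
    s2 = sum(n * (p - p_bar) ** 2 for n, p, _ in pops) / ((r - 1) * n_bar)
    h_bar = sum(n * h for n, _, h in pops) / (r * n_bar)
    a = (n_bar / n_c) * (
        s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - (r - 1) / r * s2 - (2 * n_bar - 1) / (4 * n_bar) * h_bar
    )
    c = h_bar / 2
    return a, b, c


# ---------------------------------------------------------------------------
# Tajima's D, scalar transcription with pairwise-difference pi

def tajimas_d_direct(allele_vectors):
    """D from a list of per-site allele vectors (0/1 entries, one per
    sampled chromosome; all sites same n).  pi is computed by explicit
    enumeration of chromosome pairs."""
    n = len(allele_vectors[0])
    seg = [v for v in allele_vectors if 0 < sum(v) < n]
    S = len(seg)
    if S < 3:
        return float("nan")
    pairs = list(itertools.combinations(range(n), 2))
    diffs = 0
    for v in seg:
        for i, j in pairs:
            if v[i] != v[j]:
                diffs += 1
    pi = diffs / len(pairs)
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (pi - S / a1) / sqrt(e1 * S + e2 * S * (S - 1))


# ---------------------------------------------------------------------------
# H12 tally oracle

def h12_tally(haplotypes):
    """H12 from a list of hashable haplotypes by direct tallying."""
    counts = Counter(haplotypes)
    freqs = sorted((c / len(haplotypes) for c in counts.values()), reverse=True)
    top2 = sum(freqs[:2])
    return top2**2 + sum(f**2 for f in freqs[2:])


# ---------------------------------------------------------------------------
# Viterbi brute force: exhaustive enumeration over all 3^T state paths

def viterbi_brute(z, log_init, log_trans, means, sd):
    z = np.asarray(z, dtype=float)
    T = len(z)
    best_score, best_path = -np.inf, None
    log_em = np.array(
        [
            [-0.5 * ((x - m) / sd) ** 2 - log(sd * sqrt(2 * PI)) for m in means]
            for x in z
        ]
    )
    for path in itertools.product(range(3), repeat=T):
        s = log_init[path[0]] + log_em[0][path[0]]
        for t in range(1, T):
            s += log_trans[path[t - 1]][path[t]] + log_em[t][path[t]]
        if s > best_score:
            best_score, best_path = s, path
    return np.array(best_path)


# ---------------------------------------------------------------------------
# Rarefaction by exhaustive subset enumeration

def richness_enumerate(allele_counts, g):
    """Expected number of distinct alleles in a subsample of g gene copies,
    averaged over all subsets of the multiset given by allele_counts."""
    copies = []
    for allele, count in enumerate(allele_counts):
        copies.extend([allele] * count)
    subsets = list(itertools.combinations(range(len(copies)), g))
    total = 0
    for sub in subsets:
        total += len({copies[i] for i in sub})
    return total / len(subsets)


def private_enumerate(focal_counts, other_counts_list, g):
    """Expected number of alleles present in a focal g-subsample and absent
    from independent g-subsamples of every other cluster, by exhaustive
    enumeration of all subsample combinations."""

    def copies_of(counts):
        out = []
        for allele, count in enumerate(counts):
            out.extend([allele] * count)
        return out

    focal = copies_of(focal_counts)
    others = [copies_of(c) for c in other_counts_list]
    f_subs = list(itertools.combinations(range(len(focal)), g))
    o_subs = [list(itertools.combinations(range(len(o)), g)) for o in others]
    total = 0.0
    n_combos = 0
    for fs in f_subs:
        present = {focal[i] for i in fs}
        for combo in itertools.product(*o_subs):
            seen_elsewhere = set()
            for other, sub in zip(others, combo):
                seen_elsewhere.update(other[i] for i in sub)
            total += len(present - seen_elsewhere)
            n_combos += 1
    return total / n_combos
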