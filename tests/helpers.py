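"""Independent brute-force oracles used by the test suite.

Everything here deliberately avoids the package's vectorised code paths:
likelihoods are computed by direct enumeration, the Hardy-Weinberg exact
test by rational arithmetic, and the FDR step-up by its textbook
definition.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np


def brute_config_probs(p, rr_cm, rr_cf, rr_star=1.0, rr_m=None):
    """Normalised probabilities of the 16 configurations by direct summation."""
    probs = {}
    for m_nt, m_t, f_nt, f_t in itertools.product((0, 1), repeat=4):
        s = m_nt + m_t + f_nt + f_t
        w = p**s * (1 - p) ** (4 - s) * rr_cm**m_t * rr_cf**f_t * rr_star ** (m_t * f_t)
        if rr_m is not None:
            w *= rr_m ** (m_nt + m_t)
        probs[(m_nt, m_t, f_nt, f_t)] = w
    z = sum(probs.values())
    return {k: v / z for k, v in probs.items()}


def brute_family_loglik(mother, father, child, p, rr_cm, rr_cf, rr_star=1.0, rr_m=None):
    """Observed-data log-likelihood of one family by 16-term enumeration."""
    probs = brute_config_probs(p, rr_cm, rr_cf, rr_star, rr_m)
    total = 0.0
    for (m_nt, m_t, f_nt, f_t), pr in probs.items():
        if mother is not None and m_nt + m_t != mother:
            continue
        if father is not None and f_nt + f_t != father:
            continue
        if m_t + f_t != child:
            continue
        total += pr
    return math.log(total)


def brute_window_loglik(mother, father, child, freqs, rr_cm, rr_cf):
    """Haplotype-window family log-likelihood by 8**4-style enumeration.

    ``mother``/``father``/``child`` are per-SNP dosage tuples (parents may
    be None); ``freqs``, ``rr_cm``, ``rr_cf`` are per-haplotype vectors of
    length 2**k, haplotypes indexed by bit pattern (SNP 0 high bit).
    """
    H = len(freqs)
    k = int(round(math.log2(H)))
    bits = [tuple((h >> (k - 1 - s)) & 1 for s in range(k)) for h in range(H)]

    def matches(geno, h_a, h_b):
        if geno is None:
            return True
        return all(
            g is None or g < 0 or bits[h_a][s] + bits[h_b][s] == g for s, g in enumerate(geno)
        )

    num = z = 0.0
    for h1, h2, h3, h4 in itertools.product(range(H), repeat=4):
        w = freqs[h1] * freqs[h2] * freqs[h3] * freqs[h4] * rr_cm[h2] * rr_cf[h4]
        z += w
        if matches(mother, h1, h2) and matches(father, h3, h4) and matches(child, h2, h4):
            num += w
    return math.log(num) - math.log(z)


def brute_quadruple_count(mother, father, child):
    """Number of compatible haplotype quadruples by exhaustive filtering."""
    k = len(child)
    H = 2**k
    bits = [tuple((h >> (k - 1 - s)) & 1 for s in range(k)) for h in range(H)]

    def matches(geno, h_a, h_b):
        if geno is None:
            return True
        return all(g is None or bits[h_a][s] + bits[h_b][s] == g for s, g in enumerate(geno))

    return sum(
        1
        for h1, h2, h3, h4 in itertools.product(range(H), repeat=4)
        if matches(mother, h1, h2) and matches(father, h3, h4) and matches(child, h2, h4)
    )


def brute_hwe_exact(n0, n1, n2):
    """Exact conditional HWE p-value in rational arithmetic."""
    n = n0 + n1 + n2
    n_a = 2 * min(n0, n2) + n1
    denom = math.comb(2 * n, n_a)
    probs = {}
    for het in range(n1 % 2, n_a + 1, 2):
        homr = (n_a - het) // 2
        homc = n - het - homr
        probs[het] = Fraction(
            math.factorial(n) * 2**het,
            math.factorial(homr) * math.factorial(het) * math.factorial(homc) * denom,
        )
    p_obs = probs[n1]
    return float(sum(v for v in probs.values() if v <= p_obs))


def brute_bh(pvals):
    """Benjamini-Hochberg step-up adjusted values, textbook definition."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def units_to_patterns(units):
    """Tally (mother, father, child) genotype patterns of single-SNP units."""
    out = {}
    for u in units:
        key = (u.mother, u.father, u.child)
        out[key] = out.get(key, 0) + 1
    return out
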