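"""Independent reference implementations used to check the package.

Everything here is deliberately naive: exhaustive scans over raw exon
tuples, grid quadrature, label-permutation sampling and combinatorial
enumeration.  None of it shares code paths with the package internals it
verifies.
"""

from __future__ import annotations

import itertools
from typing import Iterable

import numpy as np
from scipy.integrate import simpson
from scipy.special import betaln


# -- brute-force splicing-event classifier ----------------------------------

def _introns(exons):
    return [(exons[i][1] + 1, exons[i + 1][0] - 1)
            for i in range(len(exons) - 1)]


def brute_force_pair(exons_a, exons_b, strand):
    """Every five-class event definition tested against every combination.

    Returns signatures (etype, anchor_left, anchor_right, inclusion_exons,
    exclusion_exons) with the same canonical inclusion orientation the
    package uses.
    """
    found = set()
    for ex_x, ex_y in ((exons_a, exons_b), (exons_b, exons_a)):
        # RI: consecutive exon pair in x, single covering exon in y
        for i in range(len(ex_x) - 1):
            (a, b), (c, d) = ex_x[i], ex_x[i + 1]
            for (s, e) in ex_y:
                if s == a and e == d:
                    found.add(("RI", b, c, ((b + 1, c - 1),), ()))
        # SE: junction b->e in x, >= 1 consecutive exons strictly between in y
        for i in range(len(ex_x) - 1):
            b = ex_x[i][1]
            e = ex_x[i + 1][0]
            for j in range(len(ex_y)):
                for k in range(j + 2, len(ex_y)):
                    if ex_y[j][1] == b and ex_y[k][0] == e:
                        skipped = tuple(ex_y[j + 1:k])
                        found.add(("SE", b, e, skipped, ()))
    # A5/A3: intron pairs across transcripts sharing exactly one boundary
    for (s1, e1) in _introns(exons_a):
        for (s2, e2) in _introns(exons_b):
            if (s1, e1) == (s2, e2):
                continue
            if s1 == s2 and e1 != e2:
                down1 = [x for x in exons_a if x[0] == e1 + 1]
                down2 = [x for x in exons_b if x[0] == e2 + 1]
                if down1 and down2 and down1[0][1] == down2[0][1]:
                    g = down1[0][1]
                    etype = "A3" if strand == "+" else "A5"
                    lo, hi = min(e1, e2), max(e1, e2)
                    found.add((etype, s1 - 1, g,
                               ((lo + 1, g),), ((hi + 1, g),)))
            if e1 == e2 and s1 != s2:
                up1 = [x for x in exons_a if x[1] == s1 - 1]
                up2 = [x for x in exons_b if x[1] == s2 - 1]
                if up1 and up2 and up1[0][0] == up2[0][0]:
                    h = up1[0][0]
                    etype = "A5" if strand == "+" else "A3"
                    lo, hi = min(s1, s2), max(s1, s2)
                    found.add((etype, h, e1 + 1,
                               ((h, hi - 1),), ((h, lo - 1),)))
    # MXE: consecutive triples with shared flanks, disjoint exclusive middles
    for i in range(len(exons_a) - 2):
        b = exons_a[i][1]
        m1 = exons_a[i + 1]
        e = exons_a[i + 2][0]
        for j in range(len(exons_b) - 2):
            if exons_b[j][1] != b or exons_b[j + 2][0] != e:
                continue
            m2 = exons_b[j + 1]
            if m1 == m2:
                continue
            if not (m1[1] < m2[0] or m2[1] < m1[0]):
                continue
            if m1 in exons_b or m2 in exons_a:
                continue
            l1, l2 = m1[1] - m1[0], m2[1] - m2[0]
            inc, exc = (m1, m2) if (l1, -m1[0]) > (l2, -m2[0]) else (m2, m1)
            found.add(("MXE", b, e, (inc,), (exc,)))
    return found


def brute_force_gene(gene):
    """Five-class event signatures for a GeneModel, by exhaustive pair scan."""
    chains = []
    for t in gene.transcripts:
        chain = tuple((e.start, e.end) for e in t.exons)
        if chain not in chains:
            chains.append(chain)
    found = set()
    for ca, cb in itertools.combinations(chains, 2):
        found |= brute_force_pair(ca, cb, gene.strand)
    return found


# -- numeric Bayes-factor integration ----------------------------------------

def numeric_log_marginal(i: int, e: int, n_points: int = 2049) -> float:
    """log Integral_0^1 p^i (1-p)^e dp by Simpson quadrature."""
    p = np.linspace(0.0, 1.0, n_points)
    vals = np.power(p, i) * np.power(1.0 - p, e)
    return float(np.log(simpson(vals, x=p)))


def numeric_log_bf(c1, c2, n_points: int = 2049) -> float:
    """log BF by separate grid integration of the three marginal likelihoods."""
    (i1, e1), (i2, e2) = c1, c2
    return (numeric_log_marginal(i1, e1, n_points)
            + numeric_log_marginal(i2, e2, n_points)
            - numeric_log_marginal(i1 + i2, e1 + e2, n_points))


def max_bf_relative_error(max_total: int = 50, n_points: int = 2049) -> float:
    """max |closed-form BF / numeric BF - 1| over all count pairs.

    Covers every (i1, e1), (i2, e2) with i + e <= max_total per condition,
    vectorised via a quadrature table of the marginal integrals.
    """
    p = np.linspace(0.0, 1.0, n_points)
    # numeric log-integral table for all (I, E) with I + E <= 2 * max_total
    big = 2 * max_total
    lognum = np.full((big + 1, big + 1), np.nan)
    logcl = np.full((big + 1, big + 1), np.nan)
    for total in range(big + 1):
        i_vals = np.arange(total + 1)
        e_vals = total - i_vals
        vals = (np.power(p[None, :], i_vals[:, None])
                * np.power(1.0 - p[None, :], e_vals[:, None]))
        lognum[i_vals, e_vals] = np.log(simpson(vals, x=p, axis=1))
        logcl[i_vals, e_vals] = betaln(i_vals + 1, e_vals + 1)
    combos = np.array([(i, t - i) for t in range(max_total + 1)
                       for i in range(t + 1)])
    ci, ce = combos[:, 0], combos[:, 1]
    ln1 = lognum[ci, ce]
    lc1 = logcl[ci, ce]
    pooled_i = ci[:, None] + ci[None, :]
    pooled_e = ce[:, None] + ce[None, :]
    log_bf_num = ln1[:, None] + ln1[None, :] - lognum[pooled_i, pooled_e]
    log_bf_cl = lc1[:, None] + lc1[None, :] - logcl[pooled_i, pooled_e]
    return float(np.max(np.abs(np.expm1(log_bf_cl - log_bf_num))))


# -- permutation and enumeration oracles for the enrichment statistics -------

def permutation_chi2_p(a, b, c, d, n_perm: int = 10_000, seed: int = 0):
    """Monte-Carlo label-permutation mid-p for a 2x2 table, with standard error.

    Permuting category labels with fixed margins makes the first cell
    hypergeometric.  The permutation distribution of the Pearson statistic is
    discrete with a probability atom at the observed value, so the mid-p
    (ties counted half) is the quantity a continuous asymptotic tail p
    estimates.
    """
    rng = np.random.default_rng(seed)
    n = a + b + c + d
    row1, col1 = a + b, a + c

    def stat(a_cell):
        obs = np.stack([a_cell, row1 - a_cell,
                        col1 - a_cell, n - row1 - col1 + a_cell])
        exp = np.array([row1 * col1, row1 * (n - col1),
                        (n - row1) * col1, (n - row1) * (n - col1)]) / n
        return ((obs - exp[:, None]) ** 2 / exp[:, None]).sum(axis=0)

    observed = stat(np.array([a]))[0]
    draws = stat(rng.hypergeometric(col1, n - col1, row1, size=n_perm))
    p_ge = float(np.mean(draws >= observed - 1e-9))
    p_gt = float(np.mean(draws > observed + 1e-9))
    p = 0.5 * (p_ge + p_gt)
    se = float(np.sqrt(max(p_ge * (1 - p_ge), 1.0 / n_perm) / n_perm))
    return p, se


def exact_hypergeom_upper_p(universe: int, annotated: int, study: int,
                            k: int) -> float:
    """P(X >= k) by enumerating every possible study draw (tiny universes)."""
    hits = 0
    total = 0
    members = list(range(universe))
    for draw in itertools.combinations(members, study):
        total += 1
        if sum(1 for g in draw if g < annotated) >= k:
            hits += 1
    return hits / total


def bh_stepup(p_values: Iterable[float]) -> list[float]:
    """Benjamini-Hochberg adjusted values by the literal step-up recursion."""
    p = list(p_values)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * m / rank)
        q[i] = prev
    return q
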