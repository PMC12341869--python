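"""Independent brute-force oracles used to check the package implementations.

Everything here is deliberately written from first principles (plain Python
loops, exact arithmetic where possible) and must not import the code paths
it validates.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations, permutations
from math import factorial


def wc_oracle(male_genos, female_genos):
    """Two-group Weir-Cockerham variance components from raw genotypes.

    Inputs are lists of genotype codes (0/1/2) for the complete genotypes of
    each group.  Returns (a, b, c, fst, fis); None where undefined.
    Straight transcription of the published two-allele, r-group variance
    component formulas with r = 2, evaluated with scalar arithmetic.
    """
    groups = [list(male_genos), list(female_genos)]
    r = len(groups)
    ns = [len(g) for g in groups]
    if any(n < 2 for n in ns):
        return None, None, None, None, None
    ps = [sum(g) / (2 * n) for g, n in zip(groups, ns)]
    hs = [sum(1 for x in g if x == 1) / n for g, n in zip(groups, ns)]

    nbar = sum(ns) / r
    nc = (r * nbar - sum(n * n for n in ns) / (r * nbar)) / (r - 1)
    pbar = sum(n * p for n, p in zip(ns, ps)) / (r * nbar)
    s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, ps)) / ((r - 1) * nbar)
    hbar = sum(n * h for n, h in zip(ns, hs)) / (r * nbar)

    a = (nbar / nc) * (
        s2 - 1 / (nbar - 1) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar)
        - (r - 1) / r * s2
        - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2

    fst = a / (a + b + c) if (a + b + c) != 0 else None
    fis = 1 - c / (b + c) if (b + c) != 0 else None
    return a, b, c, fst, fis


def fisher_oracle(table) -> float:
    """Two-sided Fisher exact p by explicit enumeration of all 2x2 tables
    with the observed margins, using exact rational table probabilities."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    n = r1 + r2

    def table_prob(x: int) -> Fraction:
        # cell layout: [[x, r1-x], [c1-x, r2-(c1-x)]]
        cells = [x, r1 - x, c1 - x, r2 - c1 + x]
        if any(v < 0 for v in cells):
            return Fraction(0)
        num = (
            factorial(r1) * factorial(r2) * factorial(c1) * factorial(c2)
        )
        den = factorial(n)
        for v in cells:
            den *= factorial(v)
        return Fraction(num, den)

    p_obs = table_prob(a)
    total = Fraction(0)
    for x in range(0, min(r1, c1) + 1):
        p = table_prob(x)
        if p > 0 and p <= p_obs:
            total += p
    return float(total)


def _log_table_prob(table3x3) -> float:
    from math import lgamma

    n = sum(sum(row) for row in table3x3)
    rows = [sum(row) for row in table3x3]
    cols = [sum(col) for col in zip(*table3x3)]
    lp = -lgamma(n + 1)
    for v in rows:
        lp += lgamma(v + 1)
    for v in cols:
        lp += lgamma(v + 1)
    for row in table3x3:
        for v in row:
            lp -= lgamma(v + 1)
    return lp


def ld_enum_oracle(x, y) -> float:
    """Exact probability-test p for genotypic independence: enumerate every
    permutation of y among individuals and count those producing a joint
    genotype table at most as probable as the observed one."""
    x = list(x)
    y = list(y)
    assert len(x) <= 8, "enumeration oracle limited to 8 individuals"

    def joint(ys):
        t = [[0] * 3 for _ in range(3)]
        for xi, yi in zip(x, ys):
            t[xi][yi] += 1
        return t

    obs_lp = _log_table_prob(joint(y))
    hits = 0
    total = 0
    for perm in permutations(y):
        if _log_table_prob(joint(perm)) <= obs_lp + 1e-9:
            hits += 1
        total += 1
    return hits / total


def depth_perm_oracle(depths, is_male) -> float:
    """Exhaustive two-sided permutation p for |mean male - mean female| of
    normalized depths, over all label assignments."""
    n = len(depths)
    n_m = sum(is_male)
    obs_m = sum(d for d, m in zip(depths, is_male) if m) / n_m
    obs_f = sum(d for d, m in zip(depths, is_male) if not m) / (n - n_m)
    obs = abs(obs_m - obs_f)
    tol = 1e-12 * (1 + obs)
    hits = total = 0
    for male_idx in combinations(range(n), n_m):
        ms = set(male_idx)
        mm = sum(depths[i] for i in ms) / n_m
        mf = sum(depths[i] for i in range(n) if i not in ms) / (n - n_m)
        if abs(mm - mf) >= obs - tol:
            hits += 1
        total += 1
    return hits / total
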