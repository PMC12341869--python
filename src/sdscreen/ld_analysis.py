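"""Pairwise genotypic LD: composite (dosage-correlation) r-squared and a
Monte-Carlo exact test of genotypic disequilibrium.

r-squared is the squared Pearson correlation of genotype codes over
complete pairs — no phasing required, which matters because X/Y phase is
unknown.  The exact test permutes one locus's genotypes among individuals
and uses the conditional probability of the two-locus genotype contingency
table (given its margins) as the test statistic, rejecting for improbable
tables; a probability test in the Fisher sense.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma

import numpy as np

from .io_formats import MISSING, GenotypeMatrix

_LOG_TOL = 1e-9


@dataclass
class ExactTestResult:
    p_value: float
    std_error: float
    n_permutations: int


@dataclass
class LDResult:
    locus_i: int
    locus_j: int
    r2: float
    p_value: float
    n_pairs: int


@dataclass
class LDMatrixSummary:
    results: list[LDResult]
    sig_level: float
    max_sig_distance_bp: int  # max |pos_i - pos_j| among pairs with p < sig_level
    n_significant: int


def _complete_pairs(g_i: np.ndarray, g_j: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    g_i = np.asarray(g_i)
    g_j = np.asarray(g_j)
    ok = (g_i != MISSING) & (g_j != MISSING)
    return g_i[ok].astype(float), g_j[ok].astype(float)


def genotypic_r2(g_i: np.ndarray, g_j: np.ndarray) -> float:
    """Squared dosage correlation over complete genotype pairs.

    NaN if fewer than two complete pairs or either locus is monomorphic
    among them (correlation undefined).
    """
    x, y = _complete_pairs(g_i, g_j)
    if x.size < 2 or np.all(x == x[0]) or np.all(y == y[0]):
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def _log_table_prob(table: np.ndarray) -> float:
    """log conditional probability of a contingency table given its margins."""
    n = table.sum()
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    lp = -lgamma(n + 1)
    lp += sum(lgamma(v + 1) for v in rows)
    lp += sum(lgamma(v + 1) for v in cols)
    lp -= sum(lgamma(v + 1) for v in table.ravel())
    return lp


def _joint_table(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    t = np.zeros((3, 3), dtype=np.int64)
    np.add.at(t, (x.astype(int), y.astype(int)), 1)
    return t


def ld_exact_test(
    g_i: np.ndarray,
    g_j: np.ndarray,
    iterations: int = 10_000,
    batches: int = 10,
    seed: int | None = None,
) -> ExactTestResult:
    """Monte-Carlo probability test for independence of two-locus genotypes.

    *iterations* is the total number of permutations, split evenly across
    *batches*; the standard error is estimated from between-batch variance.
    Degenerate tables (a single genotype class at either locus) give p = 1.
    Deterministic for a fixed seed.
    """
    x, y = _complete_pairs(g_i, g_j)
    if x.size == 0 or np.all(x == x[0]) or np.all(y == y[0]):
        return ExactTestResult(1.0, 0.0, 0)

    obs_lp = _log_table_prob(_joint_table(x, y))
    rng = np.random.default_rng(seed)
    per_batch = max(1, iterations // batches)
    total = per_batch * batches
    n = x.size
    xi = x.astype(np.int64)
    yi = y.astype(np.int64)
    # margins are permutation-invariant, so only the -sum(lgamma(t_ij + 1))
    # term varies; compare that part against the observed table's
    lgamma_tab = np.array([lgamma(v + 1) for v in range(n + 1)])
    obs_var = -lgamma_tab[_joint_table(x, y).ravel()].sum()
    batch_hits = np.zeros(batches, dtype=np.int64)
    for b in range(batches):
        # per_batch random permutations of y at once, via argsort of uniforms
        order = np.argsort(rng.random((per_batch, n)), axis=1)
        codes = xi[None, :] * 3 + yi[order]
        offs = codes + 9 * np.arange(per_batch)[:, None]
        counts = np.bincount(offs.ravel(), minlength=9 * per_batch).reshape(
            per_batch, 9
        )
        var = -lgamma_tab[counts].sum(axis=1)
        batch_hits[b] = int(np.sum(var <= obs_var + _LOG_TOL))

    n_extreme = int(batch_hits.sum())
    p = (1 + n_extreme) / (1 + total)
    batch_p = batch_hits / per_batch
    se = float(batch_p.std(ddof=1) / np.sqrt(batches)) if batches > 1 else float(
        np.sqrt(p * (1 - p) / total)
    )
    return ExactTestResult(float(p), se, total)


def ld_matrix(
    G: GenotypeMatrix,
    region_indices: list[int],
    sig_level: float = 0.01,
    iterations: int = 10_000,
    batches: int = 10,
    seed: int | None = None,
) -> LDMatrixSummary:
    """All pairwise LD results for SNPs of one chromosomal region."""
    chroms = {G.loci[i].chrom for i in region_indices}
    if len(chroms) > 1:
        raise ValueError(f"region spans multiple chromosomes: {sorted(chroms)}")
    ss = np.random.SeedSequence(seed)
    results: list[LDResult] = []
    max_dist = 0
    n_sig = 0
    idx = list(region_indices)
    children = ss.spawn(len(idx) * (len(idx) - 1) // 2)
    k = 0
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            i, j = idx[a], idx[b]
            g_i = G.genotypes[:, i]
            g_j = G.genotypes[:, j]
            r2 = genotypic_r2(g_i, g_j)
            test = ld_exact_test(
                g_i, g_j, iterations=iterations, batches=batches,
                seed=children[k],
            )
            k += 1
            ok = (g_i != MISSING) & (g_j != MISSING)
            results.append(
                LDResult(i, j, r2, test.p_value, int(ok.sum()))
            )
            if test.p_value < sig_level:
                n_sig += 1
                dist = abs(G.loci[i].pos - G.loci[j].pos)
                max_dist = max(max_dist, dist)
    return LDMatrixSummary(results, sig_level, max_dist, n_sig)
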