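"""Per-locus allele frequencies, MAF filtering and Weir-Cockerham F-statistics.

The two "populations" are the sexes.  Estimators are the Weir & Cockerham
(1984) variance components a (among groups), b (among individuals within
groups) and c (within individuals), from which

    fst = a / (a + b + c)        fis = 1 - c / (b + c)

Loci where either sex has fewer than two complete genotypes, or where the
relevant denominator is zero (monomorphic complete-case data), carry NaN
("UNDEFINED") and are never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError
from .io_formats import MISSING, GenotypeMatrix, SexMap

UNDEFINED = float("nan")


@dataclass
class LocusStats:
    """Per-SNP between-sex statistics; NaN fields mean UNDEFINED."""

    index: int
    p_m: float
    p_f: float
    n_m: int
    n_f: int
    ho_m: float
    ho_f: float
    a: float
    b: float
    c: float
    fst: float
    fis: float
    maf: float


def _sex_split(G: GenotypeMatrix, sexes: SexMap) -> tuple[np.ndarray, np.ndarray]:
    is_male = sexes.is_male_array(G.sample_ids)
    return G.genotypes[is_male], G.genotypes[~is_male]


def _group_summaries(geno: np.ndarray):
    """Per-locus complete-genotype count, alt-allele freq and het proportion."""
    ok = geno != MISSING
    n = ok.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt = np.where(ok, geno, 0).sum(axis=0)
        p = np.where(n > 0, alt / (2 * n), np.nan)
        het = np.where(ok, geno == 1, False).sum(axis=0)
        h = np.where(n > 0, het / n, np.nan)
    return n, p, h


def pooled_maf(G: GenotypeMatrix) -> np.ndarray:
    """Minor-allele frequency over all non-missing genotypes, per locus."""
    ok = G.genotypes != MISSING
    n = ok.sum(axis=0)
    alt = np.where(ok, G.genotypes, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / (2 * n), np.nan)
    return np.minimum(p, 1.0 - p)


def maf_filter(G: GenotypeMatrix, min_maf: float) -> GenotypeMatrix:
    """Retain loci whose pooled minor-allele frequency is >= *min_maf*."""
    if not 0.0 <= min_maf <= 0.5:
        raise ConfigError(f"min_maf must be in [0, 0.5], got {min_maf}")
    maf = pooled_maf(G)
    keep = np.flatnonzero(np.nan_to_num(maf, nan=-1.0) >= min_maf)
    return G.subset_loci(keep)


def wc_components(
    n1: np.ndarray, p1: np.ndarray, h1: np.ndarray,
    n2: np.ndarray, p2: np.ndarray, h2: np.ndarray,
):
    """Vectorised Weir-Cockerham (1984) a, b, c for two groups.

    Inputs are per-locus arrays of complete-genotype counts, alt-allele
    frequencies and observed heterozygote proportions for each group.
    Returns (a, b, c) with NaN where either group has n < 2.
    """
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    r = 2.0
    valid = (n1 >= 2) & (n2 >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_tot = n1 + n2
        nbar = n_tot / r
        nc = (n_tot - (n1**2 + n2**2) / n_tot) / (r - 1.0)
        pbar = (n1 * p1 + n2 * p2) / n_tot
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
        hbar = (n1 * h1 + n2 * h2) / n_tot
        a = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1.0))
            * (pbar * (1.0 - pbar) - ((r - 1.0) / r) * s2 - hbar / 4.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1.0 - pbar)
            - ((r - 1.0) / r) * s2
            - ((2.0 * nbar - 1.0) / (4.0 * nbar)) * hbar
        )
        c = hbar / 2.0
    a = np.where(valid, a, np.nan)
    b = np.where(valid, b, np.nan)
    c = np.where(valid, c, np.nan)
    return a, b, c


def wc_fst_fis(G: GenotypeMatrix, sexes: SexMap) -> list[LocusStats]:
    """Per-locus Weir-Cockerham F_ST and F_IS with sexes as the two groups."""
    males, females = _sex_split(G, sexes)
    n_m, p_m, h_m = _group_summaries(males)
    n_f, p_f, h_f = _group_summaries(females)
    a, b, c = wc_components(n_m, p_m, h_m, n_f, p_f, h_f)
    with np.errstate(invalid="ignore", divide="ignore"):
        denom_t = a + b + c
        denom_s = b + c
        fst = np.where(denom_t != 0, a / denom_t, np.nan)
        fis = np.where(denom_s != 0, 1.0 - c / denom_s, np.nan)
    maf = pooled_maf(G)
    return [
        LocusStats(
            index=j,
            p_m=float(p_m[j]),
            p_f=float(p_f[j]),
            n_m=int(n_m[j]),
            n_f=int(n_f[j]),
            ho_m=float(h_m[j]),
            ho_f=float(h_f[j]),
            a=float(a[j]),
            b=float(b[j]),
            c=float(c[j]),
            fst=float(fst[j]),
            fis=float(fis[j]),
            maf=float(maf[j]),
        )
        for j in range(G.n_loci)
    ]


def per_sex_heterozygosity(
    G: GenotypeMatrix, sexes: SexMap
) -> tuple[np.ndarray, np.ndarray]:
    """Observed heterozygote proportion among complete genotypes, per sex."""
    males, females = _sex_split(G, sexes)
    _, _, h_m = _group_summaries(males)
    _, _, h_f = _group_summaries(females)
    return h_m, h_f


def expected_sd_values(system: str) -> tuple[float, float, float, float]:
    """Theoretical (fst, fis, common-allele freq, sex-limited-allele freq)
    at a fully sex-linked locus in a balanced sample.

    Identical for XY and ZW systems (the heterogametic sex swaps; magnitudes
    do not).
    """
    if system not in ("XY", "ZW"):
        raise ValueError(f"unknown SD system {system!r}; expected 'XY' or 'ZW'")
    return (0.5, -1.0, 0.75, 0.25)
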