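"""Synthetic genotype datasets with a sex-linked block in neutral background.

The model: a diploid population with n_males XY (or ZW females) and
n_females XX.  Inside a recombination-suppressed block, sex-linked SNPs
carry the X-type allele (REF) on every X haplotype and the Y-type allele
(ALT) on the single shared Y haplotype — so at zero error the heterogametic
sex is uniformly heterozygous and the homogametic sex homozygous reference,
giving pooled allele frequencies 0.75 (X) / 0.25 (Y) in a balanced sample.
Background SNPs are unlinked neutral sites: alt frequency drawn from a Beta
distribution, genotypes binomial(2, q) regardless of sex.

A guaranteed core of ``n_fully_linked`` consecutive SNPs sits at the centre
of the block; every other block SNP is sex-linked with probability
``partial_linkage`` and background-like otherwise (the imperfect-association
regime).  Genotyping error then flips genotypes uniformly to another code,
and missingness is applied last.  Everything is deterministic under seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ConfigError
from .io_formats import FEMALE, MALE, MISSING, GenotypeMatrix, Locus, SexMap

VCF_QUAL = 60.0  # fixed passing QUAL for simulated records


@dataclass
class SimConfig:
    n_males: int = 5
    n_females: int = 5
    chrom: str = "chr1"
    chrom_length_bp: int = 10_000_000
    snp_density: float = 2.2  # SNPs per kb
    sd_block: tuple[int, int] | None = (4_000_000, 6_000_000)
    n_fully_linked: int = 50
    partial_linkage: float = 0.2
    bg_alpha: float = 0.5
    bg_beta: float = 0.5
    error_rate: float = 0.01
    missing_rate: float = 0.0
    system: str = "XY"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_males < 1 or self.n_females < 1:
            raise ConfigError("need at least one individual of each sex")
        if self.snp_density <= 0:
            raise ConfigError("snp_density must be positive")
        for rate in (self.partial_linkage, self.error_rate, self.missing_rate):
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"rates must be in [0, 1], got {rate}")
        if self.system not in ("XY", "ZW"):
            raise ConfigError(f"system must be XY or ZW, got {self.system!r}")
        if self.sd_block is not None:
            start, end = self.sd_block
            if not (1 <= start < end <= self.chrom_length_bp):
                raise ConfigError(
                    f"sd_block {self.sd_block} outside chromosome "
                    f"[1, {self.chrom_length_bp}]"
                )


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset, for parameter-recovery tests."""

    chrom: str
    block_start: int | None
    block_end: int | None
    system: str
    positions: np.ndarray
    sex_linked: np.ndarray  # bool per SNP: carries the X/Y (Z/W) divergence
    in_block: np.ndarray  # bool per SNP: lies inside the sd_block

    def to_dict(self) -> dict:
        return {
            "chrom": self.chrom,
            "block_start": self.block_start,
            "block_end": self.block_end,
            "system": self.system,
            "positions": self.positions.tolist(),
            "sex_linked": self.sex_linked.astype(int).tolist(),
            "in_block": self.in_block.astype(int).tolist(),
        }


def _draw_positions(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    if n > length:
        raise ConfigError(f"cannot place {n} SNPs on a {length} bp chromosome")
    pos = 1 + np.floor(np.sort(rng.random(n)) * length).astype(np.int64)
    # enforce strictly increasing positions (collisions are rare at low density)
    for _ in range(64):
        bad = np.flatnonzero(np.diff(pos) <= 0)
        if bad.size == 0:
            break
        pos[bad + 1] = pos[bad] + 1
    if pos[-1] > length:
        raise ConfigError("SNP density too high for chromosome length")
    return pos


def simulate_population(cfg: SimConfig) -> tuple[GenotypeMatrix, SexMap, SimTruth]:
    """Generate (genotypes, sex map, truth) for one simulated chromosome."""
    rng = np.random.default_rng(cfg.seed)
    n_ind = cfg.n_males + cfg.n_females
    n_snps = int(round(cfg.snp_density * cfg.chrom_length_bp / 1000.0))
    if n_snps < 1:
        raise ConfigError("configuration yields zero SNPs")
    pos = _draw_positions(rng, n_snps, cfg.chrom_length_bp)

    in_block = np.zeros(n_snps, dtype=bool)
    sex_linked = np.zeros(n_snps, dtype=bool)
    if cfg.sd_block is not None:
        start, end = cfg.sd_block
        in_block = (pos >= start) & (pos <= end)
        block_idx = np.flatnonzero(in_block)
        if cfg.n_fully_linked > 0:
            if block_idx.size == 0:
                raise ConfigError("sd_block contains no SNPs at this density")
            if block_idx.size < cfg.n_fully_linked:
                raise ConfigError(
                    f"sd_block holds {block_idx.size} SNPs, fewer than "
                    f"n_fully_linked={cfg.n_fully_linked}"
                )
            # guaranteed contiguous core at the centre of the block
            lo = (block_idx.size - cfg.n_fully_linked) // 2
            core = block_idx[lo : lo + cfg.n_fully_linked]
            sex_linked[core] = True
        rest = block_idx[~sex_linked[block_idx]]
        sex_linked[rest] = rng.random(rest.size) < cfg.partial_linkage

    # heterogametic sex: first n_males rows for XY, females for ZW
    sample_ids = [f"M{i+1}" for i in range(cfg.n_males)] + [
        f"F{i+1}" for i in range(cfg.n_females)
    ]
    is_hetero = np.array(
        [cfg.system == "XY"] * cfg.n_males + [cfg.system == "ZW"] * cfg.n_females
    )

    geno = np.empty((n_ind, n_snps), dtype=np.int8)
    bg = ~sex_linked
    q = rng.beta(cfg.bg_alpha, cfg.bg_beta, size=int(bg.sum()))
    geno[:, bg] = rng.binomial(2, q, size=(n_ind, q.size)).astype(np.int8)
    geno[:, sex_linked] = np.where(is_hetero, 1, 0)[:, None]

    if cfg.error_rate > 0:
        err = rng.random(geno.shape) < cfg.error_rate
        shift = rng.integers(1, 3, size=geno.shape, dtype=np.int8)
        geno = np.where(err, (geno + shift) % 3, geno).astype(np.int8)
    if cfg.missing_rate > 0:
        miss = rng.random(geno.shape) < cfg.missing_rate
        geno[miss] = MISSING

    loci = [
        Locus(cfg.chrom, int(p), "A", "C", VCF_QUAL) for p in pos
    ]
    G = GenotypeMatrix(sample_ids, loci, geno)
    sexes = SexMap(
        {s: MALE for s in sample_ids[: cfg.n_males]}
        | {s: FEMALE for s in sample_ids[cfg.n_males :]}
    )
    block = cfg.sd_block or (None, None)
    truth = SimTruth(
        chrom=cfg.chrom,
        block_start=block[0],
        block_end=block[1],
        system=cfg.system,
        positions=pos,
        sex_linked=sex_linked,
        in_block=in_block,
    )
    return G, sexes, truth


def write_vcf(G: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF 4.2 with GT per sample.

    Round-trips through io_formats.read_vcf for QUAL values exactly
    representable in float32 (cyvcf2 stores QUAL as float32).
    """
    path = Path(path)
    chrom_max: dict[str, int] = {}
    for loc in G.loci:
        chrom_max[loc.chrom] = max(chrom_max.get(loc.chrom, 0), loc.pos)
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=sdscreen-simulate\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom, length in chrom_max.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.sample_ids)
            + "\n"
        )
        for j, loc in enumerate(G.loci):
            gts = "\t".join(gt_strings[int(g)] for g in G.genotypes[:, j])
            qual = f"{loc.qual:g}"
            fh.write(
                f"{loc.chrom}\t{loc.pos}\t.\t{loc.ref}\t{loc.alt}\t{qual}\t"
                f".\t.\tGT\t{gts}\n"
            )


def write_sex_map(sexes: SexMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tsex\n")
        for sample, sex in sexes.mapping.items():
            fh.write(f"{sample}\t{sex}\n")


def write_truth(truth: SimTruth, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2)
        fh.write("\n")
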