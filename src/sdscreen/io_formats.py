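"""Input/output: VCF genotypes, sex maps and tabular screen reports.

Genotypes are held as an ``n_samples x n_loci`` integer matrix with codes
0 (hom-ref), 1 (het), 2 (hom-alt) and :data:`MISSING` (-1).  Positions are
1-based throughout, as in VCF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .errors import ConfigError, FormatError

MISSING: int = -1

MALE = "male"
FEMALE = "female"

_SEX_ALIASES = {
    "m": MALE,
    "male": MALE,
    "f": FEMALE,
    "female": FEMALE,
}


@dataclass(frozen=True)
class Locus:
    """A biallelic SNP: 1-based position plus REF/ALT single bases."""

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise FormatError(f"locus position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise FormatError(
                f"ref and alt alleles identical at {self.chrom}:{self.pos}"
            )


@dataclass
class VcfLoadReport:
    """Counts of records seen and dropped while loading a VCF."""

    n_records: int = 0
    n_retained: int = 0
    n_multiallelic: int = 0
    n_indel: int = 0
    n_low_qual: int = 0


@dataclass
class GenotypeMatrix:
    """Samples x biallelic loci with diploid genotype codes.

    ``genotypes[i, j]`` is the genotype of sample *i* at locus *j*:
    0 = hom-ref, 1 = het, 2 = hom-alt, MISSING = -1 (includes half-calls).
    """

    sample_ids: list[str]
    loci: list[Locus]
    genotypes: np.ndarray
    load_report: VcfLoadReport | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        n_s, n_l = len(self.sample_ids), len(self.loci)
        if self.genotypes.shape != (n_s, n_l):
            raise FormatError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{n_s} samples x {n_l} loci"
            )
        if len(set(self.sample_ids)) != n_s:
            raise FormatError("duplicate sample ids")
        allowed = {0, 1, 2, MISSING}
        codes = set(np.unique(self.genotypes).tolist())
        if not codes <= allowed:
            raise FormatError(f"invalid genotype codes: {sorted(codes - allowed)}")
        self._check_sorted()

    def _check_sorted(self) -> None:
        seen_chroms: dict[str, int] = {}
        prev_chrom = None
        prev_pos = 0
        for loc in self.loci:
            if loc.chrom != prev_chrom:
                if loc.chrom in seen_chroms:
                    raise FormatError(
                        f"loci not grouped by chromosome: {loc.chrom} reappears"
                    )
                seen_chroms[loc.chrom] = 1
                prev_chrom, prev_pos = loc.chrom, loc.pos
                continue
            if loc.pos == prev_pos:
                raise FormatError(f"duplicated locus {loc.chrom}:{loc.pos}")
            if loc.pos < prev_pos:
                raise FormatError(
                    f"loci not sorted by position at {loc.chrom}:{loc.pos}"
                )
            prev_pos = loc.pos

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.loci == other.loci
            and np.array_equal(self.genotypes, other.genotypes)
        )

    def subset_loci(self, indices: Iterable[int]) -> "GenotypeMatrix":
        idx = np.asarray(list(indices), dtype=int)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            loci=[self.loci[i] for i in idx],
            genotypes=self.genotypes[:, idx],
        )


@dataclass
class SexMap:
    """sample_id -> {male, female}."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        bad = {s for s in self.mapping.values()} - {MALE, FEMALE}
        if bad:
            raise FormatError(f"unknown sex labels: {sorted(bad)}")

    def sex_of(self, sample_id: str) -> str:
        return self.mapping[sample_id]

    def is_male_array(self, sample_ids: list[str]) -> np.ndarray:
        """Boolean mask over *sample_ids*; errors on samples missing a sex."""
        missing = [s for s in sample_ids if s not in self.mapping]
        if missing:
            raise ConfigError(
                f"samples without sex assignment: {', '.join(missing[:5])}"
            )
        return np.array([self.mapping[s] == MALE for s in sample_ids])

    def counts(self) -> tuple[int, int]:
        vals = list(self.mapping.values())
        return vals.count(MALE), vals.count(FEMALE)


def read_vcf(path: str | Path, min_qual: float = 20.0) -> GenotypeMatrix:
    """Load biallelic SNPs with QUAL >= *min_qual* from a VCF.

    Multiallelic records and indels are dropped and counted in the attached
    :class:`VcfLoadReport`; records with QUAL strictly below the threshold
    (or missing QUAL when the threshold is positive) are likewise dropped.
    Half-called genotypes become MISSING; phase separators are ignored.
    """
    if min_qual < 0:
        raise ConfigError(f"min_qual must be >= 0, got {min_qual}")
    path = Path(path)
    if not path.exists():
        raise OSError(f"VCF not found: {path}")
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare Exceptions on bad files
        raise OSError(f"cannot read VCF {path}: {exc}") from exc

    samples = list(vcf.samples)
    if not samples:
        raise FormatError(f"VCF {path} has no sample columns")

    report = VcfLoadReport()
    loci: list[Locus] = []
    columns: list[np.ndarray] = []
    for var in vcf:
        report.n_records += 1
        if len(var.ALT) != 1:
            report.n_multiallelic += 1
            continue
        ref, alt = var.REF, var.ALT[0]
        if len(ref) != 1 or len(alt) != 1:
            report.n_indel += 1
            continue
        qual = var.QUAL
        if qual is None or qual < min_qual:
            if qual is None and min_qual == 0:
                qual = 0.0
            else:
                report.n_low_qual += 1
                continue
        codes = np.full(len(samples), MISSING, dtype=np.int8)
        for i, gt in enumerate(var.genotypes):
            a0, a1 = gt[0], gt[1]
            if a0 >= 0 and a1 >= 0:
                codes[i] = a0 + a1
        loci.append(Locus(var.CHROM, var.POS, ref, alt, float(qual)))
        columns.append(codes)
        report.n_retained += 1

    geno = (
        np.column_stack(columns)
        if columns
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(samples, loci, geno, load_report=report)


def read_sex_map(path: str | Path) -> SexMap:
    """Parse a two-column TSV (sample_id, sex); accepts M/F/male/female."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for line_no, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(
                    f"{path}:{line_no}: expected 2 tab-separated columns"
                )
            sample, sex_raw = parts[0], parts[1]
            if sample.lower() == "sample_id" and line_no == 1:
                continue  # optional header
            sex = _SEX_ALIASES.get(sex_raw.strip().lower())
            if sex is None:
                raise FormatError(
                    f"{path}:{line_no}: unknown sex label {sex_raw!r} "
                    f"for sample {sample!r}"
                )
            if sample in mapping:
                raise FormatError(f"{path}:{line_no}: duplicate sample {sample!r}")
            mapping[sample] = sex
    return SexMap(mapping)


_WINDOW_COLUMNS = [
    "chrom",
    "start",
    "end",
    "n_snps",
    "n_defined",
    "mean_fst",
    "mean_fis",
    "low_confidence",
]
_REGION_COLUMNS = [
    "chrom",
    "start",
    "end",
    "span_bp",
    "n_snps",
    "mean_fst",
    "mean_fis",
    "classification",
    "passes_span",
]


def write_screen_report(windows, regions, window_path, region_path) -> None:
    """Write window and candidate-region TSVs (deterministic formatting)."""
    wrows = [
        {
            "chrom": w.chrom,
            "start": w.start_pos,
            "end": w.end_pos,
            "n_snps": len(w.snp_indices),
            "n_defined": w.n_defined,
            "mean_fst": w.mean_fst,
            "mean_fis": w.mean_fis,
            "low_confidence": w.low_confidence,
        }
        for w in windows
    ]
    rrows = [
        {
            "chrom": r.chrom,
            "start": r.start_pos,
            "end": r.end_pos,
            "span_bp": r.span_bp,
            "n_snps": len(r.snp_indices),
            "mean_fst": r.mean_fst,
            "mean_fis": r.mean_fis,
            "classification": r.classification,
            "passes_span": r.passes_span,
        }
        for r in regions
    ]
    pd.DataFrame(wrows, columns=_WINDOW_COLUMNS).to_csv(
        window_path, sep="\t", index=False, float_format="%.6g"
    )
    pd.DataFrame(rrows, columns=_REGION_COLUMNS).to_csv(
        region_path, sep="\t", index=False, float_format="%.6g"
    )


def write_locus_stats(stats, loci: list[Locus], path) -> None:
    """Per-SNP statistics TSV: chrom, pos, p_m, p_f, ho_m, ho_f, fst, fis, maf."""
    rows = [
        {
            "chrom": loci[s.index].chrom,
            "pos": loci[s.index].pos,
            "p_m": s.p_m,
            "p_f": s.p_f,
            "ho_m": s.ho_m,
            "ho_f": s.ho_f,
            "fst": s.fst,
            "fis": s.fis,
            "maf": s.maf,
        }
        for s in stats
    ]
    cols = ["chrom", "pos", "p_m", "p_f", "ho_m", "ho_f", "fst", "fis", "maf"]
    pd.DataFrame(rows, columns=cols).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )
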