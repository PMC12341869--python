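"""Sliding-window averaging, dual-threshold candidate calling and XY/ZW calls.

Windows are SNP-count based (k consecutive usable SNPs, shifted one SNP at
a time) and never span chromosomes.  Spans are inclusive base-pair
intervals: span_bp = last SNP position - first SNP position + 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .io_formats import Locus
from .popgen_stats import LocusStats


@dataclass
class ScreenConfig:
    window_k: int = 10
    shift: int = 1
    fst_min: float = 0.3
    fis_max: float = -0.5
    min_span_bp: int = 1000
    het_margin: float = 0.2  # XY/ZW classification margin on mean Ho difference

    def __post_init__(self) -> None:
        if self.window_k < 2:
            raise ConfigError(f"window_k must be >= 2, got {self.window_k}")
        if self.shift != 1:
            raise ConfigError("only shift=1 is supported")
        if not 0.0 < self.fst_min < 1.0:
            raise ConfigError(f"fst_min must be in (0, 1), got {self.fst_min}")
        if self.fis_max >= 0:
            raise ConfigError(f"fis_max must be negative, got {self.fis_max}")
        if self.min_span_bp < 0:
            raise ConfigError("min_span_bp must be >= 0")


@dataclass
class WindowStats:
    chrom: str
    start_pos: int
    end_pos: int
    snp_indices: list[int]
    mean_fst: float
    mean_fis: float
    n_defined: int
    low_confidence: bool = False


@dataclass
class CandidateRegion:
    chrom: str
    start_pos: int
    end_pos: int
    span_bp: int
    snp_indices: list[int] = field(repr=False)
    mean_fst: float = float("nan")
    mean_fis: float = float("nan")
    classification: str = "ambiguous"
    passes_span: bool = False


def sliding_windows(
    stats: list[LocusStats], loci: list[Locus], cfg: ScreenConfig
) -> list[WindowStats]:
    """All k-SNP windows (1-SNP shift) per chromosome.

    Means are over per-SNP values that are defined (non-NaN); windows with
    fewer than half their SNPs defined are flagged low_confidence.
    """
    if len(stats) != len(loci):
        raise ConfigError("stats and loci must be parallel lists")
    k = cfg.window_k
    fst = np.array([s.fst for s in stats])
    fis = np.array([s.fis for s in stats])
    chroms = [loc.chrom for loc in loci]
    pos = np.array([loc.pos for loc in loci])

    windows: list[WindowStats] = []
    start = 0
    n = len(loci)
    while start < n:
        chrom = chroms[start]
        end = start
        while end < n and chroms[end] == chrom:
            end += 1
        for i in range(start, end - k + 1):
            sl = slice(i, i + k)
            w_fst, w_fis = fst[sl], fis[sl]
            defined = ~np.isnan(w_fst)
            n_def = int(defined.sum())
            mean_fst = float(np.nanmean(w_fst)) if n_def else float("nan")
            fis_def = int((~np.isnan(w_fis)).sum())
            mean_fis = float(np.nanmean(w_fis)) if fis_def else float("nan")
            windows.append(
                WindowStats(
                    chrom=chrom,
                    start_pos=int(pos[i]),
                    end_pos=int(pos[i + k - 1]),
                    snp_indices=list(range(i, i + k)),
                    mean_fst=mean_fst,
                    mean_fis=mean_fis,
                    n_defined=n_def,
                    low_confidence=n_def < k / 2,
                )
            )
        start = end
    return windows


def _passes(w: WindowStats, cfg: ScreenConfig) -> bool:
    return (
        not np.isnan(w.mean_fst)
        and not np.isnan(w.mean_fis)
        and w.mean_fst >= cfg.fst_min
        and w.mean_fis <= cfg.fis_max
    )


def call_candidates(
    windows: list[WindowStats],
    stats: list[LocusStats],
    cfg: ScreenConfig,
) -> list[CandidateRegion]:
    """Merge threshold-passing windows that share SNPs into candidate regions.

    Regions spanning strictly more than min_span_bp get passes_span=True;
    shorter regions are retained (flagged) rather than discarded, so they can
    still be inspected.  Region means are over the union of member SNPs.
    """
    fst = np.array([s.fst for s in stats])
    fis = np.array([s.fis for s in stats])

    regions: list[CandidateRegion] = []
    current: list[WindowStats] = []

    def flush() -> None:
        if not current:
            return
        idx = sorted({i for w in current for i in w.snp_indices})
        r_fst = fst[idx]
        r_fis = fis[idx]
        start = current[0].start_pos
        end = current[-1].end_pos
        span = end - start + 1
        regions.append(
            CandidateRegion(
                chrom=current[0].chrom,
                start_pos=start,
                end_pos=end,
                span_bp=span,
                snp_indices=idx,
                mean_fst=float(np.nanmean(r_fst)) if np.any(~np.isnan(r_fst)) else float("nan"),
                mean_fis=float(np.nanmean(r_fis)) if np.any(~np.isnan(r_fis)) else float("nan"),
                passes_span=span > cfg.min_span_bp,
            )
        )
        current.clear()

    for w in windows:
        if not _passes(w, cfg):
            continue
        if current and (
            w.chrom != current[-1].chrom
            or w.snp_indices[0] > current[-1].snp_indices[-1] + 1
        ):
            flush()
        current.append(w)
    flush()
    return regions


def classify_system(
    region: CandidateRegion,
    ho_m: np.ndarray,
    ho_f: np.ndarray,
    margin: float = 0.2,
) -> str:
    """XY if males are clearly the more heterozygous sex over the region,
    ZW if females are; otherwise ambiguous."""
    idx = region.snp_indices
    m = float(np.nanmean(ho_m[idx]))
    f = float(np.nanmean(ho_f[idx]))
    if np.isnan(m) or np.isnan(f):
        return "ambiguous"
    if m - f > margin:
        return "XY"
    if f - m > margin:
        return "ZW"
    return "ambiguous"
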