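"""End-to-end screen: VCF -> MAF filter -> F-statistics -> windows ->
candidate regions -> XY/ZW calls -> LD over the top region, with a JSON
manifest recording parameters, seed and per-stage SNP counts."""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io_formats, ld_analysis, popgen_stats, window_screen
from .errors import ConfigError
from .window_screen import ScreenConfig

log = logging.getLogger("sdscreen")


@dataclass
class RunConfig:
    vcf_path: str
    sex_map_path: str
    outdir: str
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    min_qual: float = 20.0
    min_maf: float = 0.2
    ld_max_snps: int = 40  # cap on SNPs used for the top-region LD matrix
    ld_iterations: int = 2000
    ld_sig_level: float = 0.01
    seed: int = 0


@dataclass
class ScreenResult:
    stats: list
    windows: list
    regions: list
    ld_summary: ld_analysis.LDMatrixSummary | None
    manifest: dict


def run_screen(cfg: RunConfig) -> ScreenResult:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    G = io_formats.read_vcf(cfg.vcf_path, min_qual=cfg.min_qual)
    report = G.load_report
    log.info(
        "loaded %d/%d records (%d multiallelic, %d indel, %d low-QUAL dropped)",
        report.n_retained, report.n_records, report.n_multiallelic,
        report.n_indel, report.n_low_qual,
    )
    sexes = io_formats.read_sex_map(cfg.sex_map_path)
    n_m, n_f = sexes.counts()
    if n_m < 2 or n_f < 2:
        raise ConfigError(f"need >=2 samples per sex; got {n_m} males, {n_f} females")

    G_maf = popgen_stats.maf_filter(G, cfg.min_maf)
    log.info("MAF >= %.3g filter: %d -> %d SNPs", cfg.min_maf, G.n_loci, G_maf.n_loci)

    stats = popgen_stats.wc_fst_fis(G_maf, sexes)
    ho_m, ho_f = popgen_stats.per_sex_heterozygosity(G_maf, sexes)

    windows = window_screen.sliding_windows(stats, G_maf.loci, cfg.screen)
    regions = window_screen.call_candidates(windows, stats, cfg.screen)
    for region in regions:
        region.classification = window_screen.classify_system(
            region, ho_m, ho_f, margin=cfg.screen.het_margin
        )
    log.info(
        "%d windows -> %d candidate regions (%d pass the span rule)",
        len(windows), len(regions), sum(r.passes_span for r in regions),
    )

    ld_summary = None
    passing = [r for r in regions if r.passes_span]
    if passing:
        top = max(passing, key=lambda r: r.mean_fst)
        idx = top.snp_indices
        if len(idx) > cfg.ld_max_snps:
            sel = np.linspace(0, len(idx) - 1, cfg.ld_max_snps).astype(int)
            idx = [idx[i] for i in sel]
        ld_summary = ld_analysis.ld_matrix(
            G_maf, idx, sig_level=cfg.ld_sig_level,
            iterations=cfg.ld_iterations, seed=cfg.seed,
        )
        _write_ld_tsv(ld_summary, G_maf, outdir / "ld_top_region.tsv")

    io_formats.write_locus_stats(stats, G_maf.loci, outdir / "locus_stats.tsv")
    io_formats.write_screen_report(
        windows, regions, outdir / "windows.tsv", outdir / "regions.tsv"
    )

    manifest = {
        "parameters": {
            "min_qual": cfg.min_qual,
            "min_maf": cfg.min_maf,
            "seed": cfg.seed,
            "screen": dataclasses.asdict(cfg.screen),
            "ld": {
                "max_snps": cfg.ld_max_snps,
                "iterations": cfg.ld_iterations,
                "sig_level": cfg.ld_sig_level,
            },
        },
        "counts": {
            "vcf_records": report.n_records,
            "snps_after_qual": report.n_retained,
            "snps_after_maf": G_maf.n_loci,
            "windows": len(windows),
            "regions": len(regions),
            "regions_passing_span": sum(r.passes_span for r in regions),
        },
        "samples": {"males": n_m, "females": n_f},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return ScreenResult(stats, windows, regions, ld_summary, manifest)


def _write_ld_tsv(summary, G, path) -> None:
    import pandas as pd

    rows = [
        {
            "chrom": G.loci[r.locus_i].chrom,
            "pos_i": G.loci[r.locus_i].pos,
            "pos_j": G.loci[r.locus_j].pos,
            "r2": r.r2,
            "p": r.p_value,
            "n": r.n_pairs,
        }
        for r in summary.results
    ]
    pd.DataFrame(rows, columns=["chrom", "pos_i", "pos_j", "r2", "p", "n"]).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )
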