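"""Sex-linked duplication check from normalized read depth over a gene.

A male-specific duplication would roughly double male read depth over the
gene; we compare library-size-normalized depths between sexes with a
two-sided label-permutation test (exhaustive when the number of label
assignments is small, Monte Carlo otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .errors import ConfigError, FormatError
from .io_formats import FEMALE, MALE

_ENUM_LIMIT = 20_000  # exhaustive permutation when C(n, n_m) is below this

_COLUMNS = ["sample_id", "sex", "gene_id", "read_count", "library_size"]


@dataclass
class DepthTestResult:
    ratio: float  # male / female mean normalized depth; NaN if undefined
    p_value: float
    exhaustive: bool
    n_male: int
    n_female: int
    ratio_ci: tuple[float, float] | None = None  # bootstrap percentile interval


def read_depth_table(path) -> pd.DataFrame:
    """TSV with columns sample_id, sex, gene_id, read_count, library_size."""
    df = pd.read_csv(path, sep="\t")
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"depth table missing columns: {sorted(missing)}")
    df["sex"] = df["sex"].str.strip().str.lower().map(
        {"m": MALE, "male": MALE, "f": FEMALE, "female": FEMALE}
    )
    if df["sex"].isna().any():
        raise FormatError("depth table contains unknown sex labels")
    if (df["read_count"] < 0).any():
        raise FormatError("negative read counts")
    if (df["library_size"] <= 0).any():
        raise FormatError("library sizes must be positive")
    if (df["read_count"] > df["library_size"]).any():
        raise FormatError("read_count exceeds library_size")
    return df


def depth_ratio_test(
    table: pd.DataFrame,
    gene_id: str,
    iterations: int = 10_000,
    seed: int | None = None,
    bootstrap: int = 2000,
) -> DepthTestResult:
    """Male/female normalized-depth ratio and permutation p-value for *gene_id*.

    The test statistic is |mean male - mean female| of count/library_size;
    labels are permuted over samples.  All C(n, n_male) assignments are
    enumerated exactly when feasible, so small designs need no Monte Carlo.
    """
    sub = table[table["gene_id"] == gene_id]
    if sub.empty:
        raise ConfigError(f"gene {gene_id!r} not present in depth table")
    depths = (sub["read_count"] / sub["library_size"]).to_numpy(dtype=float)
    is_male = (sub["sex"] == MALE).to_numpy()
    n_m, n_f = int(is_male.sum()), int((~is_male).sum())
    if n_m < 2 or n_f < 2:
        raise ConfigError(
            f"need >=2 samples per sex for {gene_id!r}; got {n_m} males, {n_f} females"
        )

    mean_m = depths[is_male].mean()
    mean_f = depths[~is_male].mean()
    ratio = float("nan") if mean_f == 0 else float(mean_m / mean_f)
    obs = abs(mean_m - mean_f)
    tol = 1e-12 * (1.0 + obs)

    n = depths.size
    rng = np.random.default_rng(seed)
    if comb(n, n_m) <= _ENUM_LIMIT:
        hits = 0
        total = 0
        for male_idx in combinations(range(n), n_m):
            mask = np.zeros(n, dtype=bool)
            mask[list(male_idx)] = True
            stat = abs(depths[mask].mean() - depths[~mask].mean())
            if stat >= obs - tol:
                hits += 1
            total += 1
        p = hits / total
        exhaustive = True
    else:
        hits = 0
        for _ in range(iterations):
            mask = np.zeros(n, dtype=bool)
            mask[rng.choice(n, size=n_m, replace=False)] = True
            stat = abs(depths[mask].mean() - depths[~mask].mean())
            if stat >= obs - tol:
                hits += 1
        p = (1 + hits) / (1 + iterations)
        exhaustive = False

    ci = None
    if bootstrap and mean_f > 0:
        boots = np.empty(bootstrap)
        dm, df_ = depths[is_male], depths[~is_male]
        for b in range(bootstrap):
            bm = rng.choice(dm, size=n_m, replace=True).mean()
            bf = rng.choice(df_, size=n_f, replace=True).mean()
            boots[b] = np.inf if bf == 0 else bm / bf
        finite = boots[np.isfinite(boots)]
        if finite.size:
            ci = (
                float(np.percentile(finite, 2.5)),
                float(np.percentile(finite, 97.5)),
            )
    return DepthTestResult(ratio, float(p), exhaustive, n_m, n_f, ci)
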