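"""Strain phenotype-table ingestion and descriptive statistics.

Phenotype tables follow the Mouse Phenome Database layout: one row per
strain with the trait mean, its standard deviation and the number of
animals measured.  Latency traits are in seconds, plasma drug levels in
ng/ml.

Two analyses operate on these tables: a non-parametric screen
(Spearman's rho with Benjamini-Hochberg adjustment across the batch of
pairs tested together), robust to the non-normal, outlier-prone latency
distributions; and a confirmatory two-group comparison on the log10
scale whose difference and 95% CI are back-transformed to a fold change.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "read_phenotype_table",
    "write_phenotype_table",
    "correlate_traits",
    "fold_change_ci",
    "FoldChangeResult",
]

REQUIRED_COLUMNS = ("strain", "mean", "sd", "n")


def read_phenotype_table(path: str | Path) -> pd.DataFrame:
    """Read an MPD-style TSV (strain, mean, sd, n); validates the layout."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns: {missing}")
    if df["strain"].duplicated().any():
        dups = df.loc[df["strain"].duplicated(), "strain"].tolist()
        raise ValueError(f"duplicate strains: {dups}")
    if (df["n"] < 1).any() or (df["sd"] < 0).any():
        raise ValueError("require n >= 1 and sd >= 0")
    return df


def write_phenotype_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def correlate_traits(
    tables: Mapping[str, pd.DataFrame],
    pairs: Sequence[tuple[str, str]] | None = None,
    min_shared: int = 4,
) -> pd.DataFrame:
    """Spearman correlations between trait tables, BH-adjusted across the batch.

    ``tables`` maps a trait name to its phenotype table; ``pairs`` selects
    which (a, b) combinations to test (default: all unordered pairs).
    Correlation uses the strains shared by the two tables; fewer than
    ``min_shared`` shared strains is an error.  Returns a DataFrame with
    columns (a, b, n, rho, p, p_adj); p_adj is Benjamini-Hochberg over
    exactly the pairs tested in this call.
    """
    names = list(tables)
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    rows = []
    for a, b in pairs:
        ta = tables[a].set_index("strain")["mean"]
        tb = tables[b].set_index("strain")["mean"]
        shared = ta.index.intersection(tb.index)
        if len(shared) < min_shared:
            raise ValueError(
                f"pair ({a}, {b}): only {len(shared)} shared strains, "
                f"need >= {min_shared}"
            )
        rho, p = stats.spearmanr(ta.loc[shared], tb.loc[shared])
        rows.append({"a": a, "b": b, "n": len(shared),
                     "rho": float(rho), "p": float(p)})
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


@dataclass(frozen=True)
class FoldChangeResult:
    fold_change: float
    ci_low: float
    ci_high: float
    t: float
    p: float
    df: float


def fold_change_ci(
    group_x: Sequence[float],
    group_y: Sequence[float],
    alpha: float = 0.05,
    equal_var: bool = True,
) -> FoldChangeResult:
    """Two-sample t-test on log10 values, back-transformed to a fold change.

    Reports Y relative to X: the difference mean(log10 Y) - mean(log10 X)
    and its CI are mapped through 10**x, so fold_change > 1 means Y above
    X.  Pooled-variance t by default; ``equal_var=False`` gives Welch.
    All measurements must be positive.
    """
    x = np.asarray(group_x, dtype=float)
    y = np.asarray(group_y, dtype=float)
    for name, arr in (("X", x), ("Y", y)):
        if arr.size < 2:
            raise ValueError(f"group {name} needs >= 2 values")
        if (arr <= 0).any():
            bad = arr[arr <= 0][0]
            raise ValueError(f"group {name} has non-positive value {bad!r}")
    lx, ly = np.log10(x), np.log10(y)
    res = stats.ttest_ind(ly, lx, equal_var=equal_var)
    diff = ly.mean() - lx.mean()
    dof = float(res.df)
    se = abs(diff / res.statistic) if res.statistic != 0 else _pooled_se(
        lx, ly, equal_var
    )
    tcrit = stats.t.ppf(1 - alpha / 2, dof)
    return FoldChangeResult(
        fold_change=float(10 ** diff),
        ci_low=float(10 ** (diff - tcrit * se)),
        ci_high=float(10 ** (diff + tcrit * se)),
        t=float(res.statistic),
        p=float(res.pvalue),
        df=dof,
    )


def _pooled_se(lx: np.ndarray, ly: np.ndarray, equal_var: bool) -> float:
    nx, ny = lx.size, ly.size
    if equal_var:
        sp2 = ((nx - 1) * lx.var(ddof=1) + (ny - 1) * ly.var(ddof=1)) / (nx + ny - 2)
        return float(np.sqrt(sp2 * (1 / nx + 1 / ny)))
    return float(np.sqrt(lx.var(ddof=1) / nx + ly.var(ddof=1) / ny))
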