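"""Stability of gene rankings under random strain deletion.

Each resampling iteration removes 1, 2 or 3 strains (the count and the
strains both drawn uniformly) from the phenotyped panel and reruns the
mapping scan.  Subsets identical to a previously drawn one are discarded
and redrawn, so the iterations cover distinct panels.  Per gene, the
p-values across iterations are summarised by a robustness score

    score = sum_i -log10(p_i)

where an iteration in which the gene's p exceeded the reporting cutoff
(default 0.01) — or in which the gene did not appear at all — contributes
-log10(cutoff).  With 100 iterations and cutoff 0.01 the floor is 200.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RobustnessResult",
    "resample_panels",
    "robustness_score",
    "rank_by_robustness",
    "run_robustness",
]

DELETION_CHOICES = (1, 2, 3)


@dataclass(frozen=True)
class RobustnessResult:
    gene: str
    score: float
    n_iterations: int
    n_hits: int          # iterations with p <= cutoff
    best_p: float


def _n_distinct_subsets(n: int) -> int:
    return sum(math.comb(n, d) for d in DELETION_CHOICES)


def resample_panels(
    strains: Sequence[str],
    n_iterations: int = 100,
    seed: int | None = None,
) -> list[tuple[str, ...]]:
    """Draw ``n_iterations`` distinct strain subsets, deleting 1-3 strains each.

    Duplicated draws are disregarded and redrawn.  Fully reproducible from
    ``seed``.  Raises if fewer distinct subsets exist than requested,
    reporting the attainable count.
    """
    strains = list(strains)
    n = len(strains)
    if n < 5:
        raise ValueError("need at least 5 strains to delete up to 3")
    attainable = _n_distinct_subsets(n)
    if attainable < n_iterations:
        raise ValueError(
            f"only {attainable} distinct subsets exist for {n} strains; "
            f"cannot draw {n_iterations}"
        )
    rng = np.random.default_rng(seed)
    seen: set[frozenset[str]] = set()
    subsets: list[tuple[str, ...]] = []
    while len(subsets) < n_iterations:
        d = int(rng.choice(DELETION_CHOICES))
        drop = set(rng.choice(n, size=d, replace=False).tolist())
        kept = tuple(s for i, s in enumerate(strains) if i not in drop)
        key = frozenset(kept)
        if key in seen:
            continue
        seen.add(key)
        subsets.append(kept)
    return subsets


def robustness_score(
    p_values: Sequence[float | None],
    cutoff: float = 0.01,
    p_floor: float = 1e-300,
) -> float:
    """Sum of -log10(p_i) with censoring at the cutoff.

    ``None`` marks an iteration where the gene was censored/absent; it and
    any p above the cutoff contribute -log10(cutoff).  p = 0 is capped at
    ``p_floor`` to keep the score finite.
    """
    if not 0.0 < cutoff < 1.0:
        raise ValueError("cutoff must be in (0, 1)")
    total = 0.0
    for p in p_values:
        if p is None or p > cutoff:
            p = cutoff
        elif p <= 0.0:
            p = p_floor
        total += -math.log10(p)
    return total


def rank_by_robustness(results: Sequence[RobustnessResult]) -> list[RobustnessResult]:
    """Descending score; ties broken by gene symbol."""
    return sorted(results, key=lambda r: (-r.score, r.gene))


def run_robustness(
    strains: Sequence[str],
    scan: Callable[[Sequence[str]], dict[str, float]],
    n_iterations: int = 100,
    cutoff: float = 0.01,
    seed: int | None = None,
) -> list[RobustnessResult]:
    """Resample panels, rerun the scan on each, score and rank the genes.

    ``scan(subset)`` must return {gene: p} for one strain subset; only
    entries with p <= cutoff matter (the rest are censored anyway, which
    mirrors recording results at the cutoff).
    """
    subsets = resample_panels(strains, n_iterations=n_iterations, seed=seed)
    per_gene: dict[str, dict[int, float]] = {}
    for i, subset in enumerate(subsets):
        for gene, p in scan(subset).items():
            per_gene.setdefault(gene, {})[i] = p
    results = []
    for gene, hits in per_gene.items():
        ps: list[float | None] = [hits.get(i) for i in range(len(subsets))]
        score = robustness_score(ps, cutoff=cutoff)
        observed = [p for p in ps if p is not None]
        results.append(
            RobustnessResult(
                gene=gene,
                score=score,
                n_iterations=len(subsets),
                n_hits=sum(1 for p in observed if p <= cutoff),
                best_p=min(observed) if observed else float("nan"),
            )
        )
    return rank_by_robustness(results)


def robustness_to_frame(results: Sequence[RobustnessResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
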