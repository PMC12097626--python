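"""Indicator (multi-level pattern) analysis of families and FEs.

The statistic is the group-equalized IndVal: for unit u and group g,
A_g (specificity) is group g's share of the across-group sum of mean
cumulative occurrences, B_g (sensitivity/fidelity) the fraction of g's
samples where the unit occurs, and stat = sqrt(A_g * B_g).  Each unit is
associated with its best-scoring site-group combination (for two islands
these are the single islands); significance comes from permuting sample
labels and recomputing the best combination's statistic, with the
add-one p convention.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from mesofish.io import ValidationError

log = logging.getLogger("mesofish")


@dataclass
class IndicatorResult:
    unit: str
    groups: tuple[str, ...]
    A: float
    B: float
    stat: float
    p: float

    @property
    def significant(self) -> bool:
        return self.p < 0.05


def indval_g(values: np.ndarray, labels: np.ndarray
             ) -> dict[str, tuple[float, float, float]]:
    """Group-equalized IndVal components for one unit.

    Returns {group: (A, B, stat)}.  Undefined (raises) when the unit is
    absent everywhere.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    means = np.array([values[labels == g].mean() for g in groups])
    total = means.sum()
    if total == 0:
        raise ValidationError("unit absent from every sample")
    out = {}
    for g, m in zip(groups, means):
        A = m / total
        B = float((values[labels == g] > 0).mean())
        out[str(g)] = (float(A), B, float(np.sqrt(A * B)))
    return out


def _combo_stats(X: np.ndarray, codes: np.ndarray, n_groups: int,
                 combos: Sequence[tuple[int, ...]]) -> np.ndarray:
    """stat matrix (combos x units) for a label assignment."""
    means = np.stack([X[codes == g].mean(axis=0) for g in range(n_groups)])
    pres = np.stack([(X[codes == g] > 0).sum(axis=0)
                     for g in range(n_groups)])
    sizes = np.array([(codes == g).sum() for g in range(n_groups)])
    total = means.sum(axis=0)
    stats = np.zeros((len(combos), X.shape[1]))
    with np.errstate(invalid="ignore", divide="ignore"):
        for c, combo in enumerate(combos):
            sel = list(combo)
            A = means[sel].sum(axis=0) / total
            B = pres[sel].sum(axis=0) / sizes[sel].sum()
            stats[c] = np.sqrt(np.where(total > 0, A, 0.0) * B)
    return stats


def multilevel_pattern(matrix: pd.DataFrame, grouping: Mapping[str, str],
                       n_perm: int = 999, seed: int = 0
                       ) -> list[IndicatorResult]:
    """Associate each unit with its best site-group combination and test it.

    ``matrix`` is sample x unit (cumulative occurrence counts or
    presences); candidate combinations are all non-empty proper subsets
    of the groups.  Units absent everywhere are skipped with a log line.
    """
    missing = [s for s in matrix.index if s not in grouping]
    if missing:
        raise ValidationError(f"samples without group label: {missing[:5]}")
    labels = np.asarray([grouping[s] for s in matrix.index])
    groups, codes = np.unique(labels, return_inverse=True)
    k = len(groups)
    if k < 2:
        raise ValidationError("need at least two groups")
    combos = [c for r in range(1, k)
              for c in itertools.combinations(range(k), r)]
    X = matrix.to_numpy(dtype=float)
    present = X.sum(axis=0) > 0
    for unit in matrix.columns[~present]:
        log.info("unit %r absent everywhere; skipped", unit)
    X = X[:, present]
    units = list(matrix.columns[present])
    if not units:
        return []

    obs = _combo_stats(X, codes, k, combos)
    best = obs.argmax(axis=0)
    best_stat = obs[best, np.arange(len(units))]
    rng = np.random.default_rng(seed)
    hits = np.zeros(len(units))
    for _ in range(n_perm):
        perm = _combo_stats(X, rng.permutation(codes), k, combos)
        hits += perm.max(axis=0) >= best_stat - 1e-12
    pvals = (1 + hits) / (1 + n_perm)

    # A and B reported for the winning combination
    means = np.stack([X[codes == g].mean(axis=0) for g in range(k)])
    pres = np.stack([(X[codes == g] > 0).sum(axis=0) for g in range(k)])
    sizes = np.array([(codes == g).sum() for g in range(k)])
    total = means.sum(axis=0)
    results = []
    for u, unit in enumerate(units):
        combo = combos[best[u]]
        sel = list(combo)
        A = float(means[sel, u].sum() / total[u])
        B = float(pres[sel, u].sum() / sizes[sel].sum())
        results.append(IndicatorResult(
            unit=str(unit), groups=tuple(str(groups[g]) for g in combo),
            A=A, B=B, stat=float(best_stat[u]), p=float(pvals[u])))
    return results


def results_frame(results: Sequence[IndicatorResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "unit": r.unit, "groups": "+".join(r.groups), "A": r.A, "B": r.B,
        "stat": r.stat, "p": r.p, "significant": r.significant,
    } for r in results])
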