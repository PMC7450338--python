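"""Multi-run evaluation metrics, the Wilcoxon rank-sum comparison, and
competition-ranking tables for comparing feature-selection algorithms.

Metrics follow the usual wrapper-FS reporting protocol: each of N runs
yields an average cross-validation accuracy and a selected-subset size;
aggregates are the mean/min/max of each across runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np
from scipy.stats import norm, rankdata


@dataclass
class RunMetrics:
    """Aggregate accuracy and subset-size statistics over N runs."""

    avg_acc: float
    min_acc: float
    max_acc: float
    avg_nfeat: float
    min_nfeat: float
    max_nfeat: float
    n_runs: int


def fold_accuracy(tp: int, tn: int, fp: int, fn: int) -> float:
    """Classification accuracy of one fold from its confusion counts."""
    counts = (tp, tn, fp, fn)
    if any(c < 0 for c in counts):
        raise ValueError(f"confusion counts must be non-negative; got {counts}")
    total = sum(counts)
    if total == 0:
        raise ValueError("empty fold: confusion counts sum to zero")
    return (tp + tn) / total


def aggregate_metrics(per_run_acc: Sequence[float], per_run_nfeat: Sequence[int]) -> RunMetrics:
    """Mean/min/max of per-run accuracy and selected-feature counts."""
    acc = np.asarray(per_run_acc, dtype=float)
    nfeat = np.asarray(per_run_nfeat, dtype=float)
    if acc.size == 0 or acc.size != nfeat.size:
        raise ValueError("need equal-length, non-empty per-run metric lists")
    return RunMetrics(
        avg_acc=float(acc.mean()),
        min_acc=float(acc.min()),
        max_acc=float(acc.max()),
        avg_nfeat=float(nfeat.mean()),
        min_nfeat=float(nfeat.min()),
        max_nfeat=float(nfeat.max()),
        n_runs=int(acc.size),
    )


def _rank_sum_normal_z(w: float, n: int, m: int, ranks: np.ndarray) -> float:
    """Continuity- and tie-corrected normal approximation of the rank-sum z."""
    total = n + m
    mu = n * (total + 1) / 2.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (total * (total - 1))
    var = n * m / 12.0 * ((total + 1) - tie_term)
    if var <= 0:
        return 0.0
    dev = w - mu
    correction = 0.5 * np.sign(dev)
    return float((dev - correction) / np.sqrt(var))


def wilcoxon_rank_sum(sample_a: Sequence[float], sample_b: Sequence[float]):
    """Two-sided Wilcoxon rank-sum test.

    Returns ``(p, h, z)``: p-value, significance indicator at the 5% level,
    and the normal-approximation z statistic.  For ``min(n, m) <= 8`` the
    p-value comes from exact enumeration of all rank assignments (midranks
    under ties); otherwise from the normal approximation with midranks, tie
    correction and continuity correction.  Two identical flat samples give
    ``(1, 0, 0)``.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = a.size, b.size
    combined = np.concatenate([a, b])
    if np.all(combined == combined[0]):
        return 1.0, 0, 0.0
    ranks = rankdata(combined)
    w = float(ranks[:n].sum())
    z = _rank_sum_normal_z(w, n, m, ranks)
    if min(n, m) <= 8:
        total = n + m
        mu = n * (total + 1) / 2.0
        dev = abs(w - mu)
        count = sum(
            1
            for idx in combinations(range(total), n)
            if abs(ranks[list(idx)].sum() - mu) >= dev - 1e-12
        )
        p = count / comb(total, n)
    else:
        p = float(2.0 * norm.sf(abs(z)))
    p = min(p, 1.0)
    return p, int(p < 0.05), z


def competition_ranks(values: np.ndarray, higher_is_better: bool) -> np.ndarray:
    """Competition ("1224") ranks: ties share the best rank, next is skipped."""
    v = np.asarray(values, dtype=float)
    return rankdata(-v if higher_is_better else v, method="min").astype(int)


@dataclass
class RankingResult:
    """Per-cell ranks plus the aggregated ranking of the compared algorithms."""

    ranks: np.ndarray  # (n_alg, n_measures, n_datasets)
    rank_sums: np.ndarray  # (n_alg, n_measures) sum over datasets
    overall_ranks: np.ndarray  # (n_alg, n_measures) competition rank of the sums
    total_sums: np.ndarray  # (n_alg,) sum of rank sums over measures
    final_ranks: np.ndarray  # (n_alg,) competition rank of the totals


def rank_algorithms(
    score_table: np.ndarray, directions: Sequence[str]
) -> RankingResult:
    """Rank algorithms per (measure, dataset) and aggregate.

    ``score_table`` has shape (algorithms, measures, datasets);
    ``directions[j]`` is ``"higher"`` or ``"lower"`` — whether larger values
    of measure j are better.  Ranking is competition style throughout; the
    final ranks order algorithms by ascending total rank sum.
    """
    table = np.asarray(score_table, dtype=float)
    if table.ndim != 3:
        raise ValueError("score_table must be (algorithms, measures, datasets)")
    if not np.isfinite(table).all():
        raise ValueError("score_table contains missing cells")
    n_alg, n_meas, n_data = table.shape
    if len(directions) != n_meas:
        raise ValueError("one direction per measure required")
    ranks = np.empty_like(table, dtype=int)
    for j, direction in enumerate(directions):
        if direction not in ("higher", "lower"):
            raise ValueError(f"direction must be 'higher' or 'lower'; got {direction!r}")
        for k in range(n_data):
            ranks[:, j, k] = competition_ranks(table[:, j, k], direction == "higher")
    rank_sums = ranks.sum(axis=2)
    overall = np.empty_like(rank_sums)
    for j in range(n_meas):
        overall[:, j] = competition_ranks(rank_sums[:, j], higher_is_better=False)
    totals = rank_sums.sum(axis=1)
    final = competition_ranks(totals, higher_is_better=False)
    return RankingResult(ranks, rank_sums, overall, totals, final)
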