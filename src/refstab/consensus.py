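"""Geometric-mean consensus ranking and the optimal reference-gene number.

Different stability algorithms rarely agree exactly; the comprehensive
ranking takes, per gene, the geometric mean of its ranks across algorithms
(lower = more stable) and re-ranks on that.  The companion rule reads the
geNorm pairwise-variation series: the smallest n with V_n below a threshold
(0.15 by convention) is the number of reference genes worth combining.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = ["ConsensusRanking", "OptimalRgNumber", "consensus_rank", "optimal_rg_number"]


@dataclass
class ConsensusRanking:
    genes: list[str]
    geo_mean_rank: dict[str, float]
    final_rank: dict[str, float]
    contributing_methods: list[str]
    most_stable_pair: tuple[str, str]
    least_stable: str

    def ordering(self) -> list[str]:
        return sorted(self.genes, key=lambda g: (self.final_rank[g], g))


@dataclass
class OptimalRgNumber:
    n_optimal: int
    v_series: list[tuple[int, float]]
    threshold: float
    satisfied: bool


def consensus_rank(
    rankings: Sequence[Mapping[str, float]] | Mapping[str, Mapping[str, float]],
) -> ConsensusRanking:
    """Aggregate per-algorithm rank maps by their per-gene geometric mean.

    Accepts a list of ``{gene: rank}`` maps or a ``{method: {gene: rank}}``
    mapping (method names are then recorded).  All maps must cover the same
    gene set.  Fractional (average-tie) ranks are accepted unchanged.
    """
    if isinstance(rankings, Mapping):
        methods = list(rankings.keys())
        maps = [rankings[name] for name in methods]
    else:
        maps = list(rankings)
        methods = [f"method_{i + 1}" for i in range(len(maps))]
    if len(maps) < 2:
        raise ValueError("consensus needs at least 2 rank maps")
    genes = list(maps[0].keys())
    gene_set = set(genes)
    for name, rk in zip(methods, maps):
        if set(rk.keys()) != gene_set:
            diff = sorted(gene_set.symmetric_difference(rk.keys()))
            raise ValueError(f"gene-set mismatch in {name}: {diff}")
    ranks = np.array([[float(rk[g]) for rk in maps] for g in genes])
    if np.any(ranks < 1):
        raise ValueError("ranks must be >= 1")
    geo = np.exp(np.log(ranks).mean(axis=1))
    final = stats.rankdata(geo, method="average")
    order = sorted(range(len(genes)), key=lambda i: (geo[i], genes[i]))
    return ConsensusRanking(
        genes=genes,
        geo_mean_rank={g: float(v) for g, v in zip(genes, geo)},
        final_rank={g: float(v) for g, v in zip(genes, final)},
        contributing_methods=methods,
        most_stable_pair=(genes[order[0]], genes[order[1]]),
        least_stable=genes[order[-1]],
    )


def optimal_rg_number(
    v_series: Sequence[tuple[int, float]], threshold: float = 0.15
) -> OptimalRgNumber:
    """Smallest n whose pairwise variation V_n falls below the threshold.

    The series must start at n = 2 and be consecutive.  If no V_n
    qualifies, the recommendation is max(n) + 1 with ``satisfied=False`` —
    i.e. even the full candidate panel did not stabilise the normalization
    factor.
    """
    if not v_series:
        raise ValueError("empty V series")
    ns = [int(n) for n, _ in v_series]
    if ns[0] != 2 or ns != list(range(2, 2 + len(ns))):
        raise ValueError(f"V series n values must be consecutive from 2, got {ns}")
    for n, v in v_series:
        if v < threshold:
            return OptimalRgNumber(
                n_optimal=int(n),
                v_series=[(int(a), float(b)) for a, b in v_series],
                threshold=threshold,
                satisfied=True,
            )
    return OptimalRgNumber(
        n_optimal=ns[-1] + 1,
        v_series=[(int(a), float(b)) for a, b in v_series],
        threshold=threshold,
        satisfied=False,
    )
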