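"""The four reference-gene stability algorithms.

Each algorithm maps a genes x samples Ct matrix (optionally with group
labels) to a per-gene stability score — lower is more stable — plus a rank:

* comparative ``delta_ct_method``: mean over partner genes of the SD of the
  pairwise Ct difference;
* ``genorm``: geNorm M value (mean pairwise SD of log2 expression ratios),
  stepwise exclusion ranking, and the pairwise-variation V series used to
  choose how many reference genes to combine;
* ``normfinder``: model-based variance decomposition of log2 expression into
  gene-specific (intra-group) variance and, when groups are supplied,
  systematic inter-group deviations;
* ``bestkeeper``: descriptive dispersion of raw Ct (the classical "SD" is a
  mean absolute deviation from the arithmetic mean) plus the per-sample
  geometric-mean index correlation.

All logarithms are base 2, so scores are in cycles / log2 units.  Ties in
any ranking receive average (fractional) ranks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import stats

from .ct_model import (
    CtMatrix,
    CtValidationError,
    RelativeQuantities,
    SampleSet,
    to_relative_quantities,
)

__all__ = [
    "DeltaCtResult",
    "GeNormResult",
    "NormFinderResult",
    "BestKeeperResult",
    "delta_ct_method",
    "genorm",
    "normfinder",
    "bestkeeper",
]


def _rank_ascending(genes: list[str], scores: np.ndarray) -> dict[str, float]:
    ranks = stats.rankdata(scores, method="average")
    return {g: float(r) for g, r in zip(genes, ranks)}


def _prepare(m: CtMatrix, subset: SampleSet | None) -> CtMatrix:
    if subset is not None:
        m = m.subset(subset)
    m.require_complete()
    return m


# ---------------------------------------------------------------------------
# Comparative delta-Ct method


@dataclass
class DeltaCtResult:
    genes: list[str]
    score: dict[str, float]
    rank: dict[str, float]
    pairwise_sd: np.ndarray  # gene x gene, symmetric, zero diagonal


def delta_ct_method(m: CtMatrix, subset: SampleSet | None = None) -> DeltaCtResult:
    """Comparative delta-Ct stability.

    For every ordered gene pair (i, j) the per-sample difference
    dCt_ij(s) = Ct_i(s) - Ct_j(s) is formed; its sample SD (n-1 denominator)
    measures how much the two genes disagree across samples.  A gene's score
    is the mean SD against all partner genes.  Sample-wide loading shifts
    add the same constant to both genes of a pair and cancel exactly.
    """
    m = _prepare(m, subset)
    k, n = m.ct.shape
    if k < 3:
        raise CtValidationError("delta-Ct comparison needs >=3 genes")
    if n < 3:
        raise CtValidationError("delta-Ct comparison needs >=3 samples")
    diffs = m.ct[:, None, :] - m.ct[None, :, :]  # (i, j, sample)
    pairwise_sd = diffs.std(axis=2, ddof=1)
    np.fill_diagonal(pairwise_sd, 0.0)
    scores = pairwise_sd.sum(axis=1) / (k - 1)
    return DeltaCtResult(
        genes=list(m.genes),
        score={g: float(s) for g, s in zip(m.genes, scores)},
        rank=_rank_ascending(m.genes, scores),
        pairwise_sd=pairwise_sd,
    )


# ---------------------------------------------------------------------------
# geNorm


@dataclass
class GeNormResult:
    genes: list[str]
    full_set_M: dict[str, float]
    stepwise_M: dict[str, float]
    removal_order: list[str]
    retained_pair: tuple[str, str]
    rank: dict[str, float]
    pairwise_V: np.ndarray
    v_series: list[tuple[int, float]] = field(default_factory=list)


def _genorm_M(logq: np.ndarray) -> np.ndarray:
    """M_j = mean over k != j of SD_s(log2 q_j(s) - log2 q_k(s))."""
    diffs = logq[:, None, :] - logq[None, :, :]
    V = diffs.std(axis=2, ddof=1)
    k = logq.shape[0]
    return V.sum(axis=1) / (k - 1), V


def genorm(
    q: RelativeQuantities | CtMatrix,
    subset: SampleSet | None = None,
    mode: Literal["stepwise", "full_set"] = "stepwise",
) -> GeNormResult:
    """geNorm expression-stability measure M and the pairwise-variation series.

    Works on relative quantities; a Ct matrix is accepted and converted with
    a per-cycle fold amplification of 2.  M_j is the average SD of the log2
    ratio of gene j against every other candidate.  Stepwise mode re-computes
    M within the surviving set and drops the worst gene until two remain
    (the canonical geNorm ranking); the last pair is ordered by full-set M,
    then lexicographically.  The V series reports, for the top-n ranked
    genes, the SD of log2(NF_n / NF_{n+1}) where NF_n is the per-sample
    geometric mean of the n quantities — the V_n < 0.15 rule for choosing
    the number of reference genes reads off this series.
    """
    if isinstance(q, CtMatrix):
        q = to_relative_quantities(q, 2.0, subset)
        subset = None
    if subset is not None:
        idx = [q.samples.index(s) for s in subset.sample_ids]
        q = RelativeQuantities(
            list(q.genes), list(subset.sample_ids), q.q[:, idx],
            q.efficiency_per_gene,
        )
    k, n = q.q.shape
    if k < 3:
        raise CtValidationError("geNorm needs >=3 genes")
    if n < 3:
        raise CtValidationError("geNorm needs >=3 samples")
    if np.any(q.q <= 0):
        raise CtValidationError("relative quantities must be positive")
    logq = np.log2(q.q)
    genes = list(q.genes)

    full_M, pairwise_V = _genorm_M(logq)
    full_set_M = {g: float(v) for g, v in zip(genes, full_M)}

    # stepwise exclusion
    removal_order: list[str] = []
    stepwise_M: dict[str, float] = {}
    alive = list(range(k))
    while len(alive) > 2:
        M_alive, _ = _genorm_M(logq[alive])
        worst_pos = int(np.argmax(M_alive))
        worst = alive[worst_pos]
        stepwise_M[genes[worst]] = float(M_alive[worst_pos])
        removal_order.append(genes[worst])
        alive.pop(worst_pos)
    pair_M, _ = _genorm_M(logq[alive])
    a, b = (genes[alive[0]], genes[alive[1]])
    stepwise_M[a] = stepwise_M[b] = float(pair_M[0])  # pair shares one M
    # final pair ordered by full-set M, then lexicographic
    pair_sorted = sorted([a, b], key=lambda g: (full_set_M[g], g))
    retained_pair = (pair_sorted[0], pair_sorted[1])

    if mode == "stepwise":
        ordering = list(retained_pair) + removal_order[::-1]
        rank = {g: float(i + 1) for i, g in enumerate(ordering)}
    elif mode == "full_set":
        rank = _rank_ascending(genes, full_M)
        ordering = sorted(genes, key=lambda g: (rank[g], g))
    else:
        raise ValueError(f"unknown geNorm mode {mode!r}")

    # V series over the ranked ordering
    gi = {g: i for i, g in enumerate(genes)}
    v_series: list[tuple[int, float]] = []
    for n_top in range(2, k):
        top_n = [gi[g] for g in ordering[:n_top]]
        top_n1 = [gi[g] for g in ordering[: n_top + 1]]
        nf_n = logq[top_n].mean(axis=0)   # log2 of geometric mean
        nf_n1 = logq[top_n1].mean(axis=0)
        v_series.append((n_top, float((nf_n - nf_n1).std(ddof=1))))

    return GeNormResult(
        genes=genes,
        full_set_M=full_set_M,
        stepwise_M=stepwise_M,
        removal_order=removal_order,
        retained_pair=retained_pair,
        rank=rank,
        pairwise_V=pairwise_V,
        v_series=v_series,
    )


# ---------------------------------------------------------------------------
# NormFinder


@dataclass
class NormFinderResult:
    genes: list[str]
    stability: dict[str, float]
    rank: dict[str, float]
    mode: Literal["grouped", "ungrouped"]
    intra_group_variance: dict[tuple[str, str], float] = field(default_factory=dict)
    inter_group_deviation: dict[tuple[str, str], float] = field(default_factory=dict)


def _two_way_residuals(y: np.ndarray) -> np.ndarray:
    """Residuals of the additive two-way fit y_ij = a_i + b_j (joint centering)."""
    return y - y.mean(axis=1, keepdims=True) - y.mean(axis=0, keepdims=True) + y.mean()


def _moment_gene_variances(y: np.ndarray) -> np.ndarray:
    """Approximately unbiased gene-specific residual variances.

    Under the additive model with gene-specific noise variance s2_i, the raw
    per-gene residual mean square after joint two-way centering has
    expectation (1 - 2/k) * s2_i + S / k^2 with S the variance total: the
    joint centering leaks every gene's noise into every row.  Solving the
    linear system gives the de-biased estimates below; negative solutions
    are floored at zero.  Requires k >= 3 genes.
    """
    k, n = y.shape
    if k < 3:
        raise CtValidationError("variance decomposition needs >=3 genes")
    if n < 2:
        raise CtValidationError("variance decomposition needs >=2 samples")
    r = _two_way_residuals(y)
    s2_raw = (r**2).sum(axis=1) / (n - 1)
    total = s2_raw.sum() / (1.0 - 1.0 / k)
    s2 = (s2_raw - total / k**2) / (1.0 - 2.0 / k)
    return np.maximum(s2, 0.0)


def normfinder(
    m: CtMatrix,
    subset: SampleSet | None = None,
    mode: Literal["auto", "grouped", "ungrouped"] = "auto",
) -> NormFinderResult:
    """Model-based stability value from a variance decomposition.

    Works on y = -Ct, i.e. log2 expression up to per-gene constants.  Each
    sample is first centred across genes, removing common loading/template
    effects.  Ungrouped: the stability value is the estimated gene-specific
    noise SD from the additive model y_ij = a_i + b_j + e_ij with
    heteroscedastic e.  Grouped: systematic inter-group deviations d_ig
    (group mean minus overall gene mean; they sum to zero over genes within
    each group) are combined with the within-group noise as
    stability_i = mean_g(|d_ig| + sqrt(s2_ig / n_g)).
    """
    m = _prepare(m, subset)
    k, n = m.ct.shape
    groups = None
    if subset is not None and subset.groups is not None:
        groups = [subset.groups[s] for s in m.samples]
    if mode == "auto":
        mode = "grouped" if groups is not None else "ungrouped"
    if mode == "grouped" and groups is None:
        raise CtValidationError("grouped mode requires a SampleSet with groups")

    y = -m.ct
    y = y - y.mean(axis=0, keepdims=True)  # per-sample centering across genes

    if mode == "ungrouped":
        if n < 4:
            raise CtValidationError("ungrouped NormFinder needs >=4 samples")
        s2 = _moment_gene_variances(y)
        stability = np.sqrt(s2)
        return NormFinderResult(
            genes=list(m.genes),
            stability={g: float(v) for g, v in zip(m.genes, stability)},
            rank=_rank_ascending(m.genes, stability),
            mode="ungrouped",
        )

    labels = list(dict.fromkeys(groups))
    if len(labels) < 2:
        raise CtValidationError("grouped mode needs >=2 groups")
    cols = {g: [j for j, lab in enumerate(groups) if lab == g] for g in labels}
    for g, js in cols.items():
        if len(js) < 2:
            raise CtValidationError(f"group {g!r} has fewer than 2 samples")

    overall = y.mean(axis=1)
    inter: dict[tuple[str, str], float] = {}
    intra: dict[tuple[str, str], float] = {}
    contrib = np.zeros(k)
    for lab in labels:
        js = cols[lab]
        d = y[:, js].mean(axis=1) - overall
        s2_g = _moment_gene_variances(y[:, js])
        for i, gene in enumerate(m.genes):
            inter[(gene, lab)] = float(d[i])
            intra[(gene, lab)] = float(s2_g[i])
        contrib += np.abs(d) + np.sqrt(s2_g / len(js))
    stability = contrib / len(labels)
    return NormFinderResult(
        genes=list(m.genes),
        stability={g: float(v) for g, v in zip(m.genes, stability)},
        rank=_rank_ascending(m.genes, stability),
        mode="grouped",
        intra_group_variance=intra,
        inter_group_deviation=inter,
    )


# ---------------------------------------------------------------------------
# BestKeeper


@dataclass
class BestKeeperResult:
    genes: list[str]
    arithmetic_mean_ct: dict[str, float]
    geometric_mean_ct: dict[str, float]
    min_ct: dict[str, float]
    max_ct: dict[str, float]
    sd_mad: dict[str, float]
    sd_sample: dict[str, float]
    cv_percent: dict[str, float]
    rank: dict[str, float]
    ranking_key: str
    index_correlation: dict[str, float] | None = None


def bestkeeper(
    m: CtMatrix,
    subset: SampleSet | None = None,
    with_index: bool = True,
    ranking_key: Literal["sd_mad", "cv_percent"] = "sd_mad",
) -> BestKeeperResult:
    """Descriptive Ct dispersion per gene, BestKeeper style.

    The classical "SD" of this method is the mean absolute deviation of raw
    Ct from its arithmetic mean (the n-1 sample SD is reported alongside);
    CV% relates that dispersion to the mean Ct.  Because it works on raw Ct,
    the statistic — unlike the ratio-based methods — is sensitive to
    sample-wide loading differences.  ``with_index`` adds each gene's
    Pearson correlation with the per-sample geometric-mean index.
    """
    m = _prepare(m, subset)
    if m.ct.shape[1] < 2:
        raise CtValidationError("BestKeeper needs >=2 samples")
    if np.any(m.ct <= 0):
        raise CtValidationError("BestKeeper needs positive Ct (geometric mean)")
    ct = m.ct
    am = ct.mean(axis=1)
    gm = stats.gmean(ct, axis=1)
    sd_mad = np.abs(ct - am[:, None]).mean(axis=1)
    sd_sample = ct.std(axis=1, ddof=1)
    cv = sd_mad / am * 100.0
    key = {"sd_mad": sd_mad, "cv_percent": cv}[ranking_key]
    index_corr = None
    if with_index:
        index = stats.gmean(ct, axis=0)
        with np.errstate(invalid="ignore"):
            index_corr = {
                g: float(np.corrcoef(ct[i], index)[0, 1])
                for i, g in enumerate(m.genes)
            }
    as_map = lambda v: {g: float(x) for g, x in zip(m.genes, v)}
    return BestKeeperResult(
        genes=list(m.genes),
        arithmetic_mean_ct=as_map(am),
        geometric_mean_ct=as_map(gm),
        min_ct=as_map(ct.min(axis=1)),
        max_ct=as_map(ct.max(axis=1)),
        sd_mad=as_map(sd_mad),
        sd_sample=as_map(sd_sample),
        cv_percent=as_map(cv),
        rank=_rank_ascending(m.genes, key),
        ranking_key=ranking_key,
        index_correlation=index_corr,
    )
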