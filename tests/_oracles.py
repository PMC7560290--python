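"""Independent brute-force oracles, written directly from the formulas.

Deliberately naive (explicit loops, statistics module, dynamic programming)
and independent of the package's vectorised implementations.
"""

from __future__ import annotations

import math
import statistics

import numpy as np
from scipy import optimize


def sd(xs):
    return statistics.stdev(xs)  # n-1 denominator


def brute_delta_ct_scores(ct_rows: list[list[float]]) -> list[float]:
    """Mean over partner genes of the SD of pairwise Ct differences."""
    k = len(ct_rows)
    scores = []
    for i in range(k):
        sds = []
        for j in range(k):
            if j == i:
                continue
            diffs = [a - b for a, b in zip(ct_rows[i], ct_rows[j])]
            sds.append(sd(diffs))
        scores.append(sum(sds) / len(sds))
    return scores


def brute_genorm_full_M(q_rows: list[list[float]]) -> list[float]:
    """Mean over partners of SD of log2 expression ratios."""
    k = len(q_rows)
    out = []
    for j in range(k):
        vs = []
        for kk in range(k):
            if kk == j:
                continue
            ratios = [math.log2(a / b) for a, b in zip(q_rows[j], q_rows[kk])]
            vs.append(sd(ratios))
        out.append(sum(vs) / len(vs))
    return out


def brute_bestkeeper(ct_row: list[float]) -> dict:
    am = sum(ct_row) / len(ct_row)
    gm = math.exp(sum(math.log(x) for x in ct_row) / len(ct_row))
    mad = sum(abs(x - am) for x in ct_row) / len(ct_row)
    return {
        "am": am,
        "gm": gm,
        "min": min(ct_row),
        "max": max(ct_row),
        "sd_mad": mad,
        "sd_sample": sd(ct_row) if len(ct_row) > 1 else 0.0,
        "cv_percent": mad / am * 100.0,
    }


def brute_normfinder_sigma(ct_rows: list[list[float]]) -> list[float]:
    """Moment estimator written from the formulas, loops only.

    y = -Ct, columns centred across genes, two-way residuals, per-gene
    residual mean square de-biased by solving
    E[ms_i] = (1 - 2/k) s2_i + S / k^2, with S the total over genes.
    """
    k = len(ct_rows)
    n = len(ct_rows[0])
    y = [[-x for x in row] for row in ct_rows]
    for j in range(n):
        col_mean = sum(y[i][j] for i in range(k)) / k
        for i in range(k):
            y[i][j] -= col_mean
    row_means = [sum(row) / n for row in y]
    col_means = [sum(y[i][j] for i in range(k)) / k for j in range(n)]
    grand = sum(row_means) / k
    ms = []
    for i in range(k):
        ssq = 0.0
        for j in range(n):
            r = y[i][j] - row_means[i] - col_means[j] + grand
            ssq += r * r
        ms.append(ssq / (n - 1))
    total = sum(ms) / (1 - 1 / k)
    return [max((m - total / k**2) / (1 - 2 / k), 0.0) for m in ms]


def ml_variance_components(ct: np.ndarray) -> np.ndarray:
    """Direct maximum-likelihood fit of the heteroscedastic additive model.

    y_ij = a_i + b_j + e_ij, e_ij ~ N(0, s2_i).  For fixed s2 the fixed
    effects have a weighted least-squares solution; the profile likelihood
    over log s2 is minimised numerically.  Independent of the moment
    estimator.
    """
    y = -ct
    y = y - y.mean(axis=0, keepdims=True)
    k, n = y.shape

    def fixed_effects(w):
        # IRLS-style: alternate row effects (unweighted in j) and weighted
        # column effects until convergence.
        a = y.mean(axis=1).copy()
        b = np.zeros(n)
        for _ in range(200):
            b_new = ((y - a[:, None]) * w[:, None]).sum(axis=0) / w.sum()
            a_new = (y - b_new[None, :]).mean(axis=1)
            if np.max(np.abs(a_new - a)) + np.max(np.abs(b_new - b)) < 1e-12:
                a, b = a_new, b_new
                break
            a, b = a_new, b_new
        return a, b

    def nll(log_s2):
        s2 = np.exp(np.clip(log_s2, -12.0, 6.0))
        w = 1.0 / s2
        a, b = fixed_effects(w)
        r = y - a[:, None] - b[None, :]
        return float(
            0.5 * np.sum(n * np.log(s2))
            + 0.5 * np.sum((r**2) / s2[:, None])
        )

    x0 = np.log(np.var(y, axis=1, ddof=1) + 1e-6)
    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"maxiter": 5000, "xatol": 1e-8, "fatol": 1e-10})
    return np.exp(res.x)


def brute_needleman_wunsch_identity(
    a: str, b: str, match: float = 1.0, mismatch: float = 0.0, gap: float = -1.0
) -> float:
    """Exhaustive DP global alignment; returns percent identity of an
    optimal alignment (identical columns / alignment length * 100)."""
    la, lb = len(a), len(b)
    score = [[0.0] * (lb + 1) for _ in range(la + 1)]
    for i in range(1, la + 1):
        score[i][0] = score[i - 1][0] + gap
    for j in range(1, lb + 1):
        score[0][j] = score[0][j - 1] + gap
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            diag = score[i - 1][j - 1] + (match if a[i - 1] == b[j - 1] else mismatch)
            score[i][j] = max(diag, score[i - 1][j] + gap, score[i][j - 1] + gap)
    # traceback maximising identities among optimal paths
    best = {}

    def trace(i, j):
        if (i, j) in best:
            return best[(i, j)]
        if i == 0 and j == 0:
            return (0, 0)
        cands = []
        if i > 0 and j > 0:
            step = match if a[i - 1] == b[j - 1] else mismatch
            if abs(score[i][j] - (score[i - 1][j - 1] + step)) < 1e-9:
                ident, length = trace(i - 1, j - 1)
                cands.append((ident + (1 if a[i - 1] == b[j - 1] else 0), length + 1))
        if i > 0 and abs(score[i][j] - (score[i - 1][j] + gap)) < 1e-9:
            ident, length = trace(i - 1, j)
            cands.append((ident, length + 1))
        if j > 0 and abs(score[i][j] - (score[i][j - 1] + gap)) < 1e-9:
            ident, length = trace(i, j - 1)
            cands.append((ident, length + 1))
        # prefer max identity, then min length (max percent)
        out = max(cands, key=lambda t: (t[0], -t[1]))
        best[(i, j)] = out
        return out

    ident, length = trace(la, lb)
    return ident / length * 100.0


def brute_common_windows(seqs: list[str], min_len: int) -> set[str]:
    """All maximal substrings of seqs[0] of length >= min_len present in
    every sequence (maximal: no strictly longer common substring of seqs[0]
    contains them)."""
    s0 = seqs[0]
    common = set()
    n = len(s0)
    for i in range(n):
        for j in range(i + min_len, n + 1):
            sub = s0[i:j]
            if all(sub in s for s in seqs):
                common.add(sub)
    maximal = set()
    for sub in common:
        if not any(sub != other and sub in other for other in common):
            maximal.add(sub)
    return maximal
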