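"""Standard-curve efficiency estimation and 2^-ddCt relative expression.

A dilution series of template gives a straight line of Ct against
log10(dilution); the slope yields the amplification efficiency
E(%) = (10^(-1/slope) - 1) x 100, with 100% meaning perfect doubling per
cycle (slope -3.3219).  Relative expression of a target gene is computed by
the ddCt method against one or several reference genes and a calibrator
sample whose fold change is defined as 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .ct_model import CtMatrix, CtValidationError

__all__ = [
    "StandardCurve",
    "ExpressionResult",
    "fit_standard_curve",
    "relative_expression_ddct",
    "RELIABLE_EFFICIENCY_RANGE",
]

#: Efficiency window (percent) within which a primer pair is considered
#: reliable for quantification.
RELIABLE_EFFICIENCY_RANGE = (90.0, 115.0)


@dataclass
class StandardCurve:
    slope: float          # cycles per log10 dilution; negative for valid curves
    intercept: float      # cycles at log10 dilution 0
    r_squared: float
    efficiency_percent: float
    n_points: int
    reliable: bool

    @property
    def efficiency_fold(self) -> float:
        """Fold amplification per cycle, E_fold = 1 + E/100."""
        return 1.0 + self.efficiency_percent / 100.0


@dataclass
class ExpressionResult:
    target: str
    reference_genes: list[str]
    calibrator_sample: str
    samples: list[str]
    delta_ct: dict[str, float]
    delta_delta_ct: dict[str, float]
    fold_change: dict[str, float]


def efficiency_from_slope(slope: float) -> float:
    """E(%) = (10^(-1/slope) - 1) x 100."""
    return (10.0 ** (-1.0 / slope) - 1.0) * 100.0


def slope_from_efficiency(efficiency_percent: float) -> float:
    """Inverse of :func:`efficiency_from_slope`."""
    return -1.0 / np.log10(1.0 + efficiency_percent / 100.0)


def fit_standard_curve(points: Sequence[tuple[float, float]]) -> StandardCurve:
    """Ordinary least-squares fit of Ct on log10 dilution.

    Needs at least three distinct dilution levels.  A non-negative slope
    means Ct did not increase with dilution — a degenerate series that
    cannot yield an efficiency — and raises.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (log10_dilution, ct) pairs")
    x, y = pts[:, 0], pts[:, 1]
    if len(np.unique(x)) < 3:
        raise CtValidationError("standard curve needs >=3 distinct dilution levels")
    fit = stats.linregress(x, y)
    if not np.isfinite(fit.slope) or fit.slope >= 0:
        raise CtValidationError(
            f"degenerate standard curve: slope {fit.slope:.4g} is not negative "
            "(Ct must rise as template is diluted)"
        )
    eff = efficiency_from_slope(fit.slope)
    lo, hi = RELIABLE_EFFICIENCY_RANGE
    # closed interval, robust to last-bit rounding at the boundaries
    tol = 1e-9
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        efficiency_percent=float(eff),
        n_points=len(x),
        reliable=bool(lo - tol <= eff <= hi + tol),
    )


def relative_expression_ddct(
    m: CtMatrix,
    target: str,
    references: Sequence[str],
    calibrator: str,
) -> ExpressionResult:
    """Fold change of ``target`` by the 2^-ddCt method.

    Multi-reference normalization summarises the reference genes by their
    arithmetic-mean Ct per sample, which at perfect doubling equals the
    geometric mean of their relative quantities.  dCt = Ct_target - Ct_ref;
    ddCt subtracts the calibrator's dCt; fold change = 2^-ddCt, exactly 1
    for the calibrator.  Per-sample loading offsets shift target and
    references alike and cancel in dCt.
    """
    references = list(references)
    if not references:
        raise ValueError("at least one reference gene is required")
    if target in references:
        raise ValueError(f"target {target!r} cannot be its own reference")
    missing = [g for g in [target] + references if g not in m.genes]
    if missing:
        raise CtValidationError(f"genes absent from matrix: {missing}")
    if calibrator not in m.samples:
        raise CtValidationError(f"calibrator sample {calibrator!r} not in matrix")
    m.require_complete()
    gi = {g: i for i, g in enumerate(m.genes)}
    ct_target = m.ct[gi[target]]
    ct_ref = m.ct[[gi[g] for g in references]].mean(axis=0)
    dct = ct_target - ct_ref
    ddct = dct - dct[m.samples.index(calibrator)]
    fold = 2.0 ** (-ddct)
    return ExpressionResult(
        target=target,
        reference_genes=references,
        calibrator_sample=calibrator,
        samples=list(m.samples),
        delta_ct={s: float(v) for s, v in zip(m.samples, dct)},
        delta_delta_ct={s: float(v) for s, v in zip(m.samples, ddct)},
        fold_change={s: float(v) for s, v in zip(m.samples, fold)},
    )
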