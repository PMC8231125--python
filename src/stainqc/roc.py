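"""ROC curves, trapezoidal AUC and Hanley-McNeil inference.

A control group and a test (altered) group of scalar feature values are
compared by sweeping a cutoff over the pooled scores; the test group is
the positive class. The orientation of each feature — whether larger or
smaller values indicate alteration — is declared a priori and never
flipped from the data, so an uninformative-in-that-direction feature can
legitimately report an AUC below 0.5.

AUC is the trapezoidal area under the empirical curve, identical to the
tie-corrected Mann-Whitney statistic U/(n0*n1). The standard error is
the Hanley-McNeil approximation; 95% confidence limits are the plain
normal interval auc +/- 1.96*SE, deliberately not clipped to [0, 1].
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import norm

logger = logging.getLogger(__name__)

__all__ = [
    "ScoreGroup",
    "ROCCurve",
    "ROCSummary",
    "roc_curve",
    "auc_trapezoid",
    "auc_inference",
    "optimal_operating_point",
    "hanley_mcneil_se",
    "summarize_groups",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class ScoreGroup:
    """Scalar feature values of one condition group."""

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size < 1:
            raise ValueError(f"group {self.label!r} is empty")
        if not np.isfinite(self.values).all():
            raise ValueError(f"group {self.label!r} contains non-finite values")

    @property
    def n(self) -> int:
        return self.values.size


@dataclass
class ROCCurve:
    """Empirical ROC points over the candidate-cutoff grid.

    Points are ordered by (fpr, tpr); cutoffs include -inf/+inf
    sentinels so the (0,0) and (1,1) endpoints are always present.
    """

    cutoffs: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    tp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray
    fp: np.ndarray
    orientation: str
    degenerate: bool = False

    @property
    def n_pos(self) -> int:
        return int(self.tp[0] + self.fn[0])

    @property
    def n_neg(self) -> int:
        return int(self.tn[0] + self.fp[0])


@dataclass
class ROCSummary:
    """One discrimination row: AUC, its uncertainty and the operating point."""

    auc: float
    std_error: float
    asymptotic_p: float
    lcl95: float
    ucl95: float
    optimal_cutoff: float = float("nan")
    optimal_sensitivity: float = float("nan")
    optimal_specificity: float = float("nan")
    flags: list = field(default_factory=list)


def roc_curve(
    control: ScoreGroup, test: ScoreGroup, orientation: str = "greater_is_positive"
) -> ROCCurve:
    """Sweep cutoffs over the pooled scores; test group = positive class.

    Candidate cutoffs are the midpoints between consecutive distinct
    pooled values plus -inf/+inf sentinels. Under
    ``greater_is_positive`` an element is called positive when its value
    is >= the cutoff; under ``less_is_positive`` when it is <= the cutoff.
    """
    if orientation not in ("greater_is_positive", "less_is_positive"):
        raise ValueError(f"unknown orientation {orientation!r}")

    pooled = np.unique(np.concatenate([control.values, test.values]))
    degenerate = pooled.size == 1
    if degenerate:
        logger.warning("constant pooled scores: degenerate two-point ROC curve")
        cut = np.array([-np.inf, np.inf])
    else:
        mids = (pooled[:-1] + pooled[1:]) / 2.0
        cut = np.concatenate([[-np.inf], mids, [np.inf]])

    pos = test.values[None, :]
    neg = control.values[None, :]
    c = cut[:, None]
    if orientation == "greater_is_positive":
        called_pos = pos >= c
        called_neg_pos = neg >= c
    else:
        called_pos = pos <= c
        called_neg_pos = neg <= c

    tp = called_pos.sum(axis=1)
    fn = test.n - tp
    fp = called_neg_pos.sum(axis=1)
    tn = control.n - fp
    tpr = tp / test.n
    fpr = fp / control.n

    order = np.lexsort((tpr, fpr))
    return ROCCurve(
        cutoffs=cut[order],
        tpr=tpr[order],
        fpr=fpr[order],
        tp=tp[order],
        fn=fn[order],
        tn=tn[order],
        fp=fp[order],
        orientation=orientation,
        degenerate=degenerate,
    )


def auc_trapezoid(curve: ROCCurve) -> float:
    """Trapezoidal area under the (fpr, tpr) polyline.

    Never flipped: an AUC below 0.5 is reported as-is, matching the
    fixed-orientation convention.
    """
    return float(np.trapezoid(curve.tpr, curve.fpr))


def hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Hanley-McNeil standard error of a trapezoidal AUC.

    Uses the exponential-model moments Q1 = A/(2-A), Q2 = 2A^2/(1+A).
    Exactly zero at A = 1 (and A = 0 by the mirrored argument),
    consistent with perfect-separation rows reporting SE = 0.
    """
    if not 0.0 <= auc <= 1.0:
        raise ValueError("auc must lie in [0, 1]")
    if n_pos < 2 or n_neg < 2:
        raise ValueError("group sizes must be >= 2")
    a = auc
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (
        a * (1.0 - a)
        + (n_pos - 1) * (q1 - a * a)
        + (n_neg - 1) * (q2 - a * a)
    ) / (n_pos * n_neg)
    return math.sqrt(max(var, 0.0))


def auc_inference(auc: float, n_control: int, n_test: int) -> ROCSummary:
    """Standard error, asymptotic p and unclipped 95% limits for an AUC.

    The asymptotic p is the two-sided normal test of H0: AUC = 0.5 using
    the null standard error (Hanley-McNeil evaluated at A = 0.5), so it
    stays finite even when the observed SE is zero.
    """
    se = hanley_mcneil_se(auc, n_pos=n_test, n_neg=n_control)
    se0 = hanley_mcneil_se(0.5, n_pos=n_test, n_neg=n_control)
    z = (auc - 0.5) / se0
    p = float(2.0 * norm.sf(abs(z)))
    return ROCSummary(
        auc=auc,
        std_error=se,
        asymptotic_p=p,
        lcl95=auc - Z95 * se,
        ucl95=auc + Z95 * se,
    )


def optimal_operating_point(curve: ROCCurve) -> tuple[float, float, float]:
    """Cutoff-selection rule: among cutoffs with specificity > 0.5,
    maximize sensitivity + specificity; ties broken by highest
    sensitivity, then lowest cutoff.

    When no cutoff achieves specificity > 0.5 the unrestricted
    max-(sens+spec) point is returned with a warning.
    """
    sens = curve.tpr
    spec = 1.0 - curve.fpr
    admissible = spec > 0.5
    if not admissible.any():
        logger.warning("no cutoff with specificity > 0.5; returning unrestricted optimum")
        admissible = np.ones_like(sens, dtype=bool)

    idx = np.flatnonzero(admissible)
    total = sens[idx] + spec[idx]
    best = total == total.max()
    idx = idx[best]
    top_sens = sens[idx] == sens[idx].max()
    idx = idx[top_sens]
    finite = curve.cutoffs[idx]
    k = idx[int(np.argmin(finite))]
    return float(curve.cutoffs[k]), float(sens[k]), float(spec[k])


def summarize_groups(
    control: ScoreGroup,
    test: ScoreGroup,
    orientation: str = "greater_is_positive",
) -> ROCSummary:
    """Full discrimination summary of one control-vs-test comparison."""
    curve = roc_curve(control, test, orientation)
    auc = auc_trapezoid(curve)
    summary = auc_inference(auc, n_control=control.n, n_test=test.n)
    cut, sens, spec = optimal_operating_point(curve)
    summary.optimal_cutoff = cut
    summary.optimal_sensitivity = sens
    summary.optimal_specificity = spec
    if curve.degenerate:
        summary.flags.append("degenerate_curve")
    return summary
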