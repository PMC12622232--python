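"""Genus-classification evaluation of POCP/POCPu values.

A pair is predicted same-genus when its metric value exceeds a threshold
(reference value 50%); the taxonomy label is the truth. Performance is
summarized by the Matthews correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

which is balanced under heavy class imbalance. Family-specific thresholds
are found by maximizing MCC over the threshold; because MCC is piecewise
constant in the threshold, an exact sweep over the midpoints between
consecutive distinct values dominates any continuous 1-D optimizer, which
is kept only as a compatibility mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize as _sp_optimize
from scipy import stats as _sp_stats

from pocpu.pairs import GenomePair

DEFAULT_THRESHOLD = 50.0


@dataclass(frozen=True)
class LabeledValue:
    """One genome pair's POCP or POCPu value with its same-genus truth label."""

    pair: GenomePair
    value: float

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError(f"value must be >= 0, got {self.value}")


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class ThresholdResult:
    """A family's optimized threshold and the MCC gain over the 50% default."""

    family: str
    threshold: Optional[float]
    mcc_at_default: float
    mcc_at_threshold: Optional[float]
    delta_mcc: Optional[float]
    n_pairs: int = 0
    n_within: int = 0
    n_between: int = 0
    flag: str = ""


@dataclass(frozen=True)
class ConcordanceResult:
    """OLS fit of a reference method's values against an alternative's."""

    r_squared: float
    slope: float
    intercept: float
    n: int
    p_value: float

    def __post_init__(self) -> None:
        if not -1e-9 <= self.r_squared <= 1 + 1e-9:
            raise ValueError("r_squared must be on [0, 1]")


def confusion_at_threshold(
    values: Sequence[LabeledValue], threshold: float
) -> ConfusionMatrix:
    """Confusion matrix of the rule "predict same-genus iff value > threshold".

    The boundary goes to the negative prediction: a value exactly at the
    threshold is predicted different-genus (the ">50%" / "<=50%" split).
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if not values:
        raise ValueError("cannot build a confusion matrix from no values")
    tp = fp = tn = fn = 0
    for lv in values:
        positive = lv.value > threshold
        if positive:
            if lv.pair.same_genus:
                tp += 1
            else:
                fp += 1
        else:
            if lv.pair.same_genus:
                fn += 1
            else:
                tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation coefficient of a confusion matrix, on [-1, 1].

    If any of the four marginal sums is zero the coefficient is undefined;
    by convention the denominator is treated as 1 and 0 is returned (the
    random-classification value). Products are computed in exact integer
    arithmetic, so counts in the millions do not overflow.
    """
    tp, fp, tn, fn = cm.tp, cm.fp, cm.tn, cm.fn
    denom_sq = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom_sq == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom_sq)


def _candidate_thresholds(values: np.ndarray) -> np.ndarray:
    """Exhaustive sweep candidates: extremes, midpoints, and the 50 default.

    MCC as a function of the threshold is a step function changing only at
    the observed values, so evaluating the midpoints between consecutive
    distinct values (plus one candidate below the minimum and the maximum
    itself, and the default for comparability) covers every attainable
    confusion matrix.
    """
    distinct = np.unique(values)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    extremes = np.array([max(distinct[0] - 1.0, 0.0), distinct[-1]])
    return np.unique(np.concatenate([extremes, mids, [DEFAULT_THRESHOLD]]))


def _mcc_curve(
    vals: np.ndarray, labels: np.ndarray, thresholds: np.ndarray
) -> np.ndarray:
    """Vectorized MCC at each threshold for value/label arrays."""
    order = np.argsort(vals, kind="stable")
    sorted_vals = vals[order]
    sorted_pos = labels[order].astype(np.int64)
    n = len(vals)
    n_pos = int(sorted_pos.sum())
    n_neg = n - n_pos
    # For each threshold t: predictions negative are the values <= t.
    k = np.searchsorted(sorted_vals, thresholds, side="right")
    cum_pos = np.concatenate([[0], np.cumsum(sorted_pos)])
    fn = cum_pos[k]
    tn = k - fn
    tp = n_pos - fn
    fp = n_neg - tn
    # Marginal products overflow int64 at large counts; take them in float.
    denom_sq = (
        (tp + fp).astype(float)
        * (tp + fn).astype(float)
        * (tn + fp).astype(float)
        * (tn + fn).astype(float)
    )
    num = tp.astype(float) * tn - fp.astype(float) * fn
    out = np.zeros(len(thresholds), dtype=float)
    nz = denom_sq > 0
    out[nz] = num[nz] / np.sqrt(denom_sq[nz])
    return out


def optimize_threshold(
    values: Sequence[LabeledValue],
    family: str = "global",
    mode: str = "sweep",
) -> ThresholdResult:
    """Find the threshold maximizing MCC for one set of labeled values.

    ``mode='sweep'`` (the primary algorithm) evaluates MCC at every
    candidate threshold exactly; ties are broken toward the candidate
    closest to the 50% default. ``mode='brent'`` is a compatibility mode
    running a bounded continuous scalar maximization over
    [min value, max value]; being a local method on a step function it can
    stall on plateaus and never beats the sweep.
    """
    if not values:
        raise ValueError("cannot optimize with no values")
    labels = np.array([lv.pair.same_genus for lv in values], dtype=bool)
    vals = np.array([lv.value for lv in values], dtype=float)
    n_within = int(labels.sum())
    n_between = int((~labels).sum())
    if n_within == 0 or n_between == 0:
        raise ValueError("cannot optimize with one class")
    mcc_default = mcc(confusion_at_threshold(values, DEFAULT_THRESHOLD))

    if mode == "sweep":
        cands = _candidate_thresholds(vals)
        curve = _mcc_curve(vals, labels, cands)
        best_mcc = curve.max()
        at_best = cands[np.isclose(curve, best_mcc)]
        # Tie-break toward 50, then toward the smaller candidate.
        idx = np.lexsort((at_best, np.abs(at_best - DEFAULT_THRESHOLD)))
        best_threshold = float(at_best[idx[0]])
    elif mode == "brent":
        lo, hi = float(vals.min()), float(vals.max())
        if lo == hi:
            best_threshold, best_mcc = lo, mcc_default
        else:
            res = _sp_optimize.minimize_scalar(
                lambda t: -_mcc_curve(vals, labels, np.array([t]))[0],
                bounds=(lo, hi),
                method="bounded",
            )
            best_threshold = float(res.x)
            best_mcc = float(-res.fun)
    else:
        raise ValueError(f"unknown mode {mode!r}; expected 'sweep' or 'brent'")

    return ThresholdResult(
        family=family,
        threshold=best_threshold,
        mcc_at_default=mcc_default,
        mcc_at_threshold=float(best_mcc),
        delta_mcc=float(best_mcc) - mcc_default,
        n_pairs=len(values),
        n_within=n_within,
        n_between=n_between,
    )


def evaluate_per_family(values: Sequence[LabeledValue]) -> list[ThresholdResult]:
    """Optimize a threshold per family plus one pooled "global" row.

    Families containing a single truth class cannot be optimized; they are
    reported with the default-threshold MCC only and flagged.
    """
    if not values:
        raise ValueError("no values to evaluate")
    by_family: dict[str, list[LabeledValue]] = {}
    for lv in values:
        by_family.setdefault(lv.pair.family, []).append(lv)
    results = []
    for family in sorted(by_family):
        fam_values = by_family[family]
        try:
            results.append(optimize_threshold(fam_values, family=family))
        except ValueError:
            labels = [lv.pair.same_genus for lv in fam_values]
            results.append(
                ThresholdResult(
                    family=family,
                    threshold=None,
                    mcc_at_default=mcc(confusion_at_threshold(fam_values, DEFAULT_THRESHOLD)),
                    mcc_at_threshold=None,
                    delta_mcc=None,
                    n_pairs=len(fam_values),
                    n_within=sum(labels),
                    n_between=len(labels) - sum(labels),
                    flag="single_class",
                )
            )
    try:
        results.append(optimize_threshold(values, family="global"))
    except ValueError:
        labels = [lv.pair.same_genus for lv in values]
        results.append(
            ThresholdResult(
                family="global",
                threshold=None,
                mcc_at_default=mcc(confusion_at_threshold(values, DEFAULT_THRESHOLD)),
                mcc_at_threshold=None,
                delta_mcc=None,
                n_pairs=len(values),
                n_within=sum(labels),
                n_between=len(labels) - sum(labels),
                flag="single_class",
            )
        )
    return results


def method_concordance(
    values_x: Sequence[float], values_y: Sequence[float]
) -> ConcordanceResult:
    """OLS regression of reference-method values on an alternative method's.

    ``values_x`` are the evaluated method's values, ``values_y`` the
    reference's (paired per genome pair). Returns the coefficient of
    determination R² as the bounded goodness-of-fit measure, with the slope,
    intercept and classical F-test p-value.
    """
    x = np.asarray(values_x, dtype=float)
    y = np.asarray(values_y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired value collections must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in input values")
    fit = _sp_stats.linregress(x, y)
    return ConcordanceResult(
        r_squared=float(fit.rvalue**2),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n=len(x),
        p_value=float(fit.pvalue),
    )


EVALUATION_TSV_HEADER = (
    "family\tn_pairs\tn_within\tn_between\tthreshold\t"
    "mcc_at_default\tmcc_at_threshold\tdelta_mcc\tflag"
)


def format_evaluation_row(r: ThresholdResult) -> str:
    """One report TSV row (thresholds to 1 decimal, MCC to 2, Table-style)."""
    thr = "" if r.threshold is None else f"{r.threshold:.1f}"
    m_at = "" if r.mcc_at_threshold is None else f"{r.mcc_at_threshold:.2f}"
    d = "" if r.delta_mcc is None else f"{r.delta_mcc:.2f}"
    return (
        f"{r.family}\t{r.n_pairs}\t{r.n_within}\t{r.n_between}\t{thr}\t"
        f"{r.mcc_at_default:.2f}\t{m_at}\t{d}\t{r.flag}"
    )
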