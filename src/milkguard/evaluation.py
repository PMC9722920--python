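"""Confusion-matrix metrics and the model-selection sweeps.

Spiked milk is the positive class, normal milk the negative class. Seven
metrics are derived from TP/TN/FP/FN:

    accuracy     (TP+TN)/(TP+TN+FP+FN)
    sensitivity  TP/(TP+FN)          (recall)
    specificity  TN/(FP+TN)
    precision    TP/(TP+FP)          (positive predictive value)
    npv          TN/(TN+FN)          (negative predictive value)
    false_alarm  FP/(FP+TN)          (= 1 − specificity)
    f1           2·precision·sensitivity/(precision+sensitivity)

Any metric whose denominator is zero is UNDETERMINED, and UNDETERMINED
propagates (it is never coerced to 0): a detector that flags nothing has an
undefined precision, not a perfect one. Aggregation over repeated random
splits reports mean ± sample SD over the determined values.

The sweeps mirror the study's model-selection protocol: training:testing
split ratios {50:50, 60:40, 70:30, 80:20, 90:10} each repeated 3 times,
iteration counts {1, 5, 10, 50, 100}, and training-set fractions
{0.2, 0.4, 0.6, 0.8, 1.0}, all selected on highest mean F1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import train_test_split


class _Undetermined:
    """Singleton marker for a metric with a zero denominator."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "Undetermined"

    def __deepcopy__(self, memo):
        return self


UNDETERMINED = _Undetermined()


def is_undetermined(value) -> bool:
    return value is UNDETERMINED


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion-matrix counts must be >= 0")
        if self.total < 1:
            raise ValueError("confusion matrix must hold >= 1 sample")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_labels(cls, y_true: np.ndarray, y_pred: np.ndarray,
                    ) -> "ConfusionMatrix":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        )


METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "precision",
                "npv", "false_alarm", "f1")


@dataclass
class MetricsReport:
    accuracy: object
    sensitivity: object
    specificity: object
    precision: object
    npv: object
    false_alarm: object
    f1: object
    sd: dict = field(default_factory=dict)  # metric -> sample SD when aggregated
    n_repeats: int = 1

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in METRIC_NAMES}

    def __str__(self) -> str:
        parts = []
        for name in METRIC_NAMES:
            v = getattr(self, name)
            if is_undetermined(v):
                parts.append(f"{name}=Undetermined")
            elif name in self.sd:
                parts.append(f"{name}={v:.4f}±{self.sd[name]:.4f}")
            else:
                parts.append(f"{name}={v:.4f}")
        return " ".join(parts)


def _ratio(num: int, den: int):
    return num / den if den else UNDETERMINED


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """The seven metrics, each by its printed formula, with UNDETERMINED
    for zero denominators; F1 is UNDETERMINED when precision or
    sensitivity is."""
    acc = _ratio(cm.tp + cm.tn, cm.total)
    sens = _ratio(cm.tp, cm.tp + cm.fn)
    spec = _ratio(cm.tn, cm.fp + cm.tn)
    prec = _ratio(cm.tp, cm.tp + cm.fp)
    npv = _ratio(cm.tn, cm.tn + cm.fn)
    fa = _ratio(cm.fp, cm.fp + cm.tn)
    if is_undetermined(prec) or is_undetermined(sens) or (prec + sens) == 0:
        f1 = UNDETERMINED
    else:
        f1 = 2 * prec * sens / (prec + sens)
    return MetricsReport(accuracy=acc, sensitivity=sens, specificity=spec,
                         precision=prec, npv=npv, false_alarm=fa, f1=f1)


def aggregate(reports: Sequence[MetricsReport]) -> MetricsReport:
    """Mean ± sample SD per metric over repeats; a metric is UNDETERMINED
    in the aggregate only if it is UNDETERMINED in every repeat."""
    if not reports:
        raise ValueError("nothing to aggregate")
    agg: dict[str, object] = {}
    sds: dict[str, float] = {}
    for name in METRIC_NAMES:
        vals = [getattr(r, name) for r in reports
                if not is_undetermined(getattr(r, name))]
        if not vals:
            agg[name] = UNDETERMINED
            continue
        agg[name] = float(np.mean(vals))
        if len(vals) > 1:
            sds[name] = float(np.std(vals, ddof=1))
    return MetricsReport(**agg, sd=sds, n_repeats=len(reports))


# ---------------------------------------------------------------------------
# Selection sweeps
# ---------------------------------------------------------------------------
# ``fit_predict`` contract shared by all sweeps:
#   fit_predict(X_train, y_train, X_test, seed) -> binary predictions

FitPredict = Callable[[np.ndarray, np.ndarray, np.ndarray, int], np.ndarray]

DEFAULT_RATIOS = (0.5, 0.6, 0.7, 0.8, 0.9)
DEFAULT_ITERATIONS = (1, 5, 10, 50, 100)
DEFAULT_FRACTIONS = (0.2, 0.4, 0.6, 0.8, 1.0)


def _split_eval(X: np.ndarray, y: np.ndarray, fit_predict: FitPredict,
                train_frac: float, seed: int,
                strata: np.ndarray | None = None) -> MetricsReport:
    strat = strata if strata is not None else y
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=train_frac, random_state=seed, stratify=strat)
    y_hat = fit_predict(X_tr, y_tr, X_te, seed)
    return metrics(ConfusionMatrix.from_labels(y_te, y_hat))


def _mean_f1(reports: Sequence[MetricsReport]) -> float:
    vals = [r.f1 for r in reports if not is_undetermined(r.f1)]
    return float(np.mean(vals)) if vals else -1.0  # all-undetermined never wins


def split_sweep(X: np.ndarray, y: np.ndarray, fit_predict: FitPredict,
                ratios: Sequence[float] = DEFAULT_RATIOS,
                repeats: int = 3, seed: int = 0,
                strata: np.ndarray | None = None,
                ) -> tuple[float, dict[float, MetricsReport]]:
    """Choose the training:testing ratio with the highest mean F1.

    Each ratio is evaluated with ``repeats`` stratified random splits; ties
    break toward the larger training fraction. Returns
    ``(best_ratio, {ratio: aggregated MetricsReport})``.
    """
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required")
    per_ratio: dict[float, MetricsReport] = {}
    scores: dict[float, float] = {}
    for k, ratio in enumerate(ratios):
        reps = [_split_eval(X, y, fit_predict, ratio, seed + 1000 * k + r, strata)
                for r in range(repeats)]
        per_ratio[ratio] = aggregate(reps)
        scores[ratio] = _mean_f1(reps)
    best = max(sorted(scores), key=lambda r: (scores[r], r))
    return best, per_ratio


def iteration_sweep(X: np.ndarray, y: np.ndarray, fit_predict: FitPredict,
                    iterations: Sequence[int] = DEFAULT_ITERATIONS,
                    train_frac: float = 0.7, seed: int = 0,
                    strata: np.ndarray | None = None,
                    ) -> tuple[int, dict[int, MetricsReport]]:
    """Choose the iteration (repeat) count with the highest mean F1.

    An "iteration" is one random split + fit + test; the candidate's score
    is the mean F1 across its iterations. Ties break toward fewer
    iterations. Returns ``(best_count, {count: aggregated MetricsReport})``.
    """
    per_iter: dict[int, MetricsReport] = {}
    scores: dict[int, float] = {}
    for k, n_iter in enumerate(iterations):
        reps = [_split_eval(X, y, fit_predict, train_frac,
                            seed + 10000 * k + r, strata)
                for r in range(n_iter)]
        per_iter[n_iter] = aggregate(reps)
        scores[n_iter] = _mean_f1(reps)
    best = max(sorted(scores, reverse=True), key=lambda n: (scores[n], -n))
    return best, per_iter


def sample_size_study(X: np.ndarray, y: np.ndarray, fit_predict: FitPredict,
                      fractions: Sequence[float] = DEFAULT_FRACTIONS,
                      train_frac: float = 0.9, repeats: int = 3,
                      seed: int = 0, strata: np.ndarray | None = None,
                      ) -> dict[float, MetricsReport]:
    """Power-vs-sample-size study: evaluate at stratified subsamples.

    For each fraction, a stratified subsample of that size is drawn, split
    (default 90:10) and evaluated, ``repeats`` times; mean ± SD per metric
    is reported. Larger samples are expected to raise power and shrink
    variance.
    """
    out: dict[float, MetricsReport] = {}
    strat = strata if strata is not None else y
    for k, frac in enumerate(fractions):
        reps = []
        for r in range(repeats):
            rs = seed + 100000 * k + r
            if frac < 1.0:
                X_sub, _, y_sub, _, s_sub, _ = train_test_split(
                    X, y, strat, train_size=frac, random_state=rs,
                    stratify=strat)
            else:
                X_sub, y_sub, s_sub = X, y, strat
            if len(np.unique(y_sub)) < 2:
                raise ValueError(f"fraction {frac} leaves a single class")
            reps.append(_split_eval(X_sub, y_sub, fit_predict, train_frac,
                                    rs, s_sub))
        out[frac] = aggregate(reps)
    return out
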