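"""Seasonal and annual drift statistics for normal-milk composition.

Milk composition shifts with feeding season and across production years, so
a classifier trained on one batch degrades on the next. This module holds
the descriptive statistics used to document that drift: the three-bin
season partition (Jan–Mar, Apr–Aug, Sep–Dec), per-feature one-way ANOVA
across year groups with Fisher's LSD post-hoc pairwise tests (no
multiplicity correction — that is what LSD is), and Welch's unequal-
variance t-test for comparing repeat-level performance metrics between
years. Significance is assessed at P < 0.05.
"""

from __future__ import annotations

import datetime as _dt
import enum
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .evaluation import UNDETERMINED, is_undetermined


class SeasonBin(enum.Enum):
    JAN_MAR = "JAN_MAR"
    APR_AUG = "APR_AUG"
    SEP_DEC = "SEP_DEC"


def assign_season(date: _dt.date) -> SeasonBin:
    """Map a date to its season bin: months 1–3, 4–8, 9–12."""
    if date.month <= 3:
        return SeasonBin.JAN_MAR
    if date.month <= 8:
        return SeasonBin.APR_AUG
    return SeasonBin.SEP_DEC


@dataclass
class AnovaResult:
    """One-way ANOVA over year groups plus LSD pairwise comparisons."""

    feature: str
    F: float
    p: float
    lsd_pairs: list[tuple[str, str, float, float]] = field(default_factory=list)


def annual_anova(groups: dict[str, np.ndarray], feature: str = "") -> AnovaResult:
    """One-way fixed-effects ANOVA with Fisher's LSD post hoc.

    ``groups`` maps a group label (e.g. the year) to that group's values of
    one compositional feature. Every group needs >= 2 values. LSD pairwise
    t statistics use the pooled within-group variance (the ANOVA MSE) with
    N − k degrees of freedom; p-values are two-sided and uncorrected.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrays = {k: np.asarray(v, float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} has fewer than 2 values")
    F, p = stats.f_oneway(*arrays.values())
    # identical group means give a 0/0 F in scipy -> define F=0, p=1
    if not np.isfinite(F):
        means = [v.mean() for v in arrays.values()]
        if np.ptp(means) == 0:
            F, p = 0.0, 1.0
    N = sum(v.size for v in arrays.values())
    k = len(arrays)
    mse = sum(((v - v.mean()) ** 2).sum() for v in arrays.values()) / (N - k)
    pairs = []
    names = list(arrays)
    for i in range(k):
        for j in range(i + 1, k):
            a, b = arrays[names[i]], arrays[names[j]]
            diff = a.mean() - b.mean()
            if mse == 0:
                p_pair = 1.0 if diff == 0 else 0.0
            else:
                se = np.sqrt(mse * (1 / a.size + 1 / b.size))
                t = diff / se
                p_pair = float(2 * stats.t.sf(abs(t), N - k))
            pairs.append((names[i], names[j], float(diff), p_pair))
    return AnovaResult(feature=feature, F=float(F), p=float(p), lsd_pairs=pairs)


def welch_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Welch's two-sided t-test (Satterthwaite df) on two samples.

    Degenerate zero-variance-on-both-sides inputs are resolved by
    convention: equal means -> (0, 1); different means -> (inf-signed t, 0).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each side needs >= 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def metric_ttest(metrics_a: dict[str, list], metrics_b: dict[str, list],
                 alpha: float = 0.05) -> dict[str, dict]:
    """Per-metric Welch t-test between two sets of repeat-level values.

    UNDETERMINED entries (e.g. precision with no flagged samples in one
    repeat) are dropped per side; a side left with < 2 determined values
    makes that metric's p UNDETERMINED. Returns, per metric, a dict with
    ``t``, ``p`` and ``significant`` (p < alpha).
    """
    out: dict[str, dict] = {}
    for name in metrics_a:
        a = [v for v in metrics_a[name] if not is_undetermined(v)]
        b = [v for v in metrics_b.get(name, []) if not is_undetermined(v)]
        if len(a) < 2 or len(b) < 2:
            out[name] = {"t": UNDETERMINED, "p": UNDETERMINED,
                         "significant": UNDETERMINED}
            continue
        t, p = welch_ttest(np.asarray(a), np.asarray(b))
        out[name] = {"t": t, "p": p, "significant": p < alpha}
    return out
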