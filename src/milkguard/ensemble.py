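"""Fusion of base-model verdicts: majority voting and F1-weighted averaging.

Voting takes the per-sample mode of an odd number of binary verdicts.
Weighting assigns each member m a weight proportional to its F1 score,
the unique solution of

    w1 + w2 + ... + wk = 1      and      f_m1/w1 = f_m2/w2 = ... = f_mk/wk,

i.e. w_i = f_i / Σ f. The fused score of a sample is r = Σ w_i r_i over the
members' binary verdicts r_i, flagged spiked when r >= 0.5 (a tied score is
called spiked — conservative flagging for a food-safety screen). Member F1
scores used for the weights should come from a held-out calibration split,
never the test split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


@dataclass
class EnsembleWeights:
    """F1-proportional member weights with the 0.5 decision threshold."""

    member_names: tuple[str, ...]
    f1_scores: np.ndarray
    weights: np.ndarray
    decision_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not (len(self.member_names) == self.f1_scores.size
                == self.weights.size):
            raise ValueError("member_names, f1_scores, weights length mismatch")
        if np.any(self.weights < 0):
            raise ValueError("weights must be >= 0")
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")


@dataclass
class DetectionResult:
    """Fused per-sample verdict with the member votes that produced it."""

    sample_id: str
    member_verdicts: tuple[int, ...]
    fused_score: float
    fused_label: str  # "normal" | "spiked"
    method: str  # "voting" | "weighting" | "single"


def _as_verdict_matrix(verdicts: Sequence[Sequence[int]]) -> np.ndarray:
    V = np.asarray(verdicts)
    if V.ndim != 2:
        raise ValueError("verdicts must be a (members, samples) array")
    if not np.isin(V, (0, 1)).all():
        raise ValueError("verdicts must be binary 0/1")
    return V.astype(int)


def majority_vote(verdicts: Sequence[Sequence[int]]) -> np.ndarray:
    """Per-sample mode of an odd number of members' binary verdicts."""
    V = _as_verdict_matrix(verdicts)
    m = V.shape[0]
    if m % 2 == 0:
        raise ValueError(
            f"majority voting needs an odd member count, got {m}; "
            "use F1-weighted fusion for even ensembles")
    return (V.sum(axis=0) * 2 > m).astype(int)


def compute_weights(f1_scores: Sequence[float],
                    member_names: Sequence[str] | None = None,
                    decision_threshold: float = 0.5) -> EnsembleWeights:
    """F1-proportional weights: w_i = f_i / Σ f.

    This is the unique solution of the sum-to-one and equal-f/w constraints;
    members with F1 = 0 get weight 0. All-zero F1 vectors leave the weights
    undefined and raise.
    """
    f1 = np.asarray(f1_scores, float)
    if f1.size < 2:
        raise ValueError("need >= 2 members")
    if np.any((f1 < 0) | (f1 > 1)):
        raise ValueError("F1 scores must lie in [0, 1]")
    total = f1.sum()
    if total == 0:
        raise ValueError("all member F1 scores are 0; weights are undefined")
    names = (tuple(member_names) if member_names is not None
             else tuple(f"m{i + 1}" for i in range(f1.size)))
    return EnsembleWeights(member_names=names, f1_scores=f1,
                           weights=f1 / total,
                           decision_threshold=decision_threshold)


def weighted_combine(verdicts: Sequence[Sequence[int]],
                     weights: EnsembleWeights,
                     sample_ids: Sequence[str] | None = None,
                     ) -> list[DetectionResult]:
    """Fuse member verdicts as r = Σ w_i r_i; spiked iff r >= threshold."""
    V = _as_verdict_matrix(verdicts)
    if V.shape[0] != weights.weights.size:
        raise ValueError(
            f"{V.shape[0]} verdict rows but {weights.weights.size} weights")
    scores = weights.weights @ V
    labels = scores >= weights.decision_threshold
    ids = (list(sample_ids) if sample_ids is not None
           else [str(i) for i in range(V.shape[1])])
    if len(ids) != V.shape[1]:
        raise ValueError("sample_ids length mismatch")
    return [
        DetectionResult(
            sample_id=ids[j],
            member_verdicts=tuple(int(v) for v in V[:, j]),
            fused_score=float(scores[j]),
            fused_label="spiked" if labels[j] else "normal",
            method="weighting",
        )
        for j in range(V.shape[1])
    ]


def fused_binary(results: Sequence[DetectionResult]) -> np.ndarray:
    """Convenience: 0/1 array of fused labels."""
    return np.array([1 if r.fused_label == "spiked" else 0 for r in results])
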