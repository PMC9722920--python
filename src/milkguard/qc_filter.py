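"""Three-sigma quality-control filter for compositional features.

Each incoming batch is cleaned before modelling: per-feature bounds
``mean ± 3·SD`` are estimated on a presumed-clean reference population
(by default the normal-labelled records) and every record with one or more
features outside the closed interval is removed. Filtering is single-pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model_io import FEATURES, SampleRecord, SampleSet


@dataclass(frozen=True)
class FeatureBounds:
    """Per-feature mean, sample SD and the derived ``mean ± 3·sd`` bounds."""

    mean: np.ndarray
    sd: np.ndarray
    n_sigma: float = 3.0
    feature_names: tuple[str, ...] = FEATURES

    def __post_init__(self) -> None:
        if self.mean.shape != self.sd.shape or self.mean.ndim != 1:
            raise ValueError("mean and sd must be 1-D and congruent")
        if np.any(self.sd < 0):
            raise ValueError("sd must be >= 0")

    @property
    def lower(self) -> np.ndarray:
        return self.mean - self.n_sigma * self.sd

    @property
    def upper(self) -> np.ndarray:
        return self.mean + self.n_sigma * self.sd


@dataclass
class FilterReport:
    """Which records were removed and which features put them out of bounds."""

    n_input: int
    n_retained: int
    n_removed: int
    offenders: dict[str, list[str]] = field(default_factory=dict)


def compute_bounds(samples: SampleSet, population: str = "normal",
                   n_sigma: float = 3.0) -> FeatureBounds:
    """Estimate three-sigma bounds from a reference population.

    ``population`` selects the records the statistics are computed on:
    ``"normal"`` (default — bounds should come from presumed-clean data)
    or ``"all"``. SD uses the n−1 denominator. Requires ≥ 2 records.
    """
    if population == "normal":
        pop = [r for r in samples if r.label == "normal"]
    elif population == "all":
        pop = list(samples)
    else:
        raise ValueError(f"population must be 'normal' or 'all', got {population!r}")
    if len(pop) < 2:
        raise ValueError(
            f"need >= 2 records in population {population!r}, got {len(pop)}")
    X = np.vstack([r.profile.as_array() for r in pop])
    return FeatureBounds(mean=X.mean(axis=0), sd=X.std(axis=0, ddof=1),
                         n_sigma=n_sigma)


def three_sigma_filter(
    samples: SampleSet, bounds: FeatureBounds,
) -> tuple[SampleSet | None, SampleSet | None, FilterReport]:
    """Partition a batch into retained/removed by the three-sigma rule.

    A record is removed iff ANY feature falls strictly outside the closed
    interval ``[lower, upper]``; values exactly on a bound are retained.
    Returns ``(retained, removed, report)`` — either set is None when empty.
    The report lists, per removed record, the offending feature names.
    """
    lo, hi = bounds.lower, bounds.upper
    retained: list[SampleRecord] = []
    removed: list[SampleRecord] = []
    offenders: dict[str, list[str]] = {}
    for rec in samples:
        x = rec.profile.as_array()
        out = (x < lo) | (x > hi)
        if out.any():
            removed.append(rec)
            offenders[f"{rec.sample_id}#{rec.replicate_index}"] = [
                bounds.feature_names[i] for i in np.flatnonzero(out)]
        else:
            retained.append(rec)
    report = FilterReport(n_input=len(samples), n_retained=len(retained),
                          n_removed=len(removed), offenders=offenders)
    ret_set = SampleSet(retained, samples.provenance) if retained else None
    rem_set = SampleSet(removed, samples.provenance) if removed else None
    return ret_set, rem_set, report
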