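"""Experiment orchestration: model selection, drift-aware blinded
cross-validation, leave-one-adulterant-out testing and LOD estimation.

Three feature views are evaluated: the eight compositional features, the
eight standardized spectral coordinates, and their 16-column concatenation.
Five candidate detectors are compared per view — squared-Mahalanobis
scoring with an F1-optimal cutoff, ExtraTrees, XGBoost, 3-member majority
voting, and F1-weighted fusion — and the winner is the candidate with the
highest mean F1 over repeated stratified splits (ties break toward the
candidate order just listed).

Fusion weights are always computed on a held-out calibration slice of the
training data, never on test data, and every protocol stage asserts that
no sample identifier appears on both sides of a train/test split.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from sklearn.model_selection import train_test_split

from . import ensemble as ens
from . import evaluation as ev
from . import learners as lr
from . import md_scorer as md
from .data_model_io import FEATURES, ConfigError, SampleRecord, SampleSet
from .spectral_features import DEFAULT_REGIONS, standardize
from .data_model_io import Spectrum

CANDIDATES = ("md", "extratrees", "xgboost", "voting", "weighting")
VIEWS = ("compositional", "spectral8", "combined16")

NOT_DETECTED = "NOT_DETECTED"


class LeakageError(RuntimeError):
    """A sample id was found on both sides of a train/test split."""


@dataclass
class FeatureView:
    """A replicate-collapsed design matrix with row-aligned metadata."""

    view: str
    X: np.ndarray
    feature_names: tuple[str, ...]
    sample_ids: list[str]
    y: np.ndarray                 # 1 = spiked
    adulterant: list[str | None]
    concentration: list[float | None]
    dates: list[_dt.date]

    def strata(self) -> np.ndarray:
        """Stratification key: label refined by adulterant."""
        return np.array([
            f"spiked:{a}" if y else "normal"
            for y, a in zip(self.y, self.adulterant)
        ])


@dataclass(frozen=True)
class ProtocolConfig:
    """Knobs of the orchestrated experiments."""

    train_frac: float = 0.7
    repeats: int = 3
    calibration_frac: float = 0.2
    et_config: lr.LearnerConfig = field(
        default_factory=lambda: lr.LearnerConfig(kind="extratrees"))
    xgb_config: lr.LearnerConfig = field(
        default_factory=lambda: lr.LearnerConfig(kind="xgboost"))
    fusion_members: tuple[str, ...] = ("extratrees", "xgboost")
    normal_holdout_frac: float = 0.3
    seed: int = 0


# ---------------------------------------------------------------------------
# Feature views
# ---------------------------------------------------------------------------

def _mean_spectrum(specs: list[Spectrum]) -> Spectrum:
    """Point-wise average of replicate spectra (one pass, common grid)."""
    w = specs[0].wavenumbers
    a = np.mean([s.absorbances for s in specs], axis=0)
    return Spectrum(w.copy(), a)


def build_feature_view(samples: SampleSet, view: str) -> FeatureView:
    """Collapse replicates and build the requested design matrix.

    Replicate records of one sample are averaged (profiles point-wise,
    spectra point-wise before coordinate extraction). Spectral views raise
    a single error listing every sample that lacks a spectrum.
    """
    if view not in VIEWS:
        raise ValueError(f"view must be one of {VIEWS}, got {view!r}")
    groups: dict[str, list[SampleRecord]] = {}
    order: list[str] = []
    for rec in samples:
        if rec.sample_id not in groups:
            groups[rec.sample_id] = []
            order.append(rec.sample_id)
        groups[rec.sample_id].append(rec)

    if view in ("spectral8", "combined16"):
        missing = [sid for sid in order
                   if any(r.spectrum is None for r in groups[sid])]
        if missing:
            raise ValueError(
                f"{len(missing)} sample(s) lack spectra for view {view!r}: "
                f"{missing[:5]}")

    comp_rows, spec_rows = [], []
    ids, ys, adus, concs, dates = [], [], [], [], []
    spectral_names: tuple[str, ...] | None = None
    for sid in order:
        recs = groups[sid]
        first = recs[0]
        comp_rows.append(np.mean([r.profile.as_array() for r in recs], axis=0))
        if view in ("spectral8", "combined16"):
            coords = standardize(_mean_spectrum([r.spectrum for r in recs]))
            spec_rows.append(coords.values)
            if spectral_names is None:
                spectral_names = tuple(
                    f"spec_{lo:.0f}_{tag.rstrip('*') if tag == 'avg' else 'pk'}{i}"
                    for i, ((lo, hi), tag) in enumerate(coords.provenance))
        ids.append(sid)
        ys.append(1 if first.label == "spiked" else 0)
        adus.append(first.adulterant)
        concs.append(first.concentration)
        dates.append(first.date)

    comp = np.vstack(comp_rows)
    if view == "compositional":
        X, names = comp, tuple(FEATURES)
    elif view == "spectral8":
        X, names = np.vstack(spec_rows), spectral_names
    else:
        X = np.hstack([comp, np.vstack(spec_rows)])
        names = tuple(FEATURES) + spectral_names
    return FeatureView(view=view, X=X, feature_names=names, sample_ids=ids,
                       y=np.asarray(ys), adulterant=adus,
                       concentration=concs, dates=dates)


# ---------------------------------------------------------------------------
# Member training / prediction
# ---------------------------------------------------------------------------

def _train_member(name: str, X_tr: np.ndarray, y_tr: np.ndarray,
                  config: ProtocolConfig, seed: int):
    """Train one base detector; returns verdicts(X) -> 0/1 array."""
    if name == "md":
        normals = X_tr[y_tr == 0]
        model = md.fit_md(normals)
        scores_tr = md.score_md(model, X_tr)
        result = md.select_cutoff(scores_tr, y_tr)
        model.cutoff = result.cutoff
        return lambda X: md.flag(model, X)
    if name == "extratrees":
        cfg = replace(config.et_config, seed=seed)
    elif name == "xgboost":
        cfg = replace(config.xgb_config, seed=seed)
    else:
        raise ValueError(f"unknown member {name!r}")
    model = lr.fit(cfg, X_tr, y_tr)
    return lambda X: lr.predict(model, X)[0]


def _f1_of(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    rep = ev.metrics(ev.ConfusionMatrix.from_labels(y_true, y_pred))
    return rep.f1 if not ev.is_undetermined(rep.f1) else 0.0


def _weighting_verdicts(member_names: Sequence[str],
                        X_tr: np.ndarray, y_tr: np.ndarray,
                        X_te: np.ndarray, config: ProtocolConfig,
                        seed: int) -> tuple[np.ndarray, ens.EnsembleWeights]:
    """Train members on a fit slice, weight by calibration F1, fuse on test."""
    X_fit, X_cal, y_fit, y_cal = train_test_split(
        X_tr, y_tr, test_size=config.calibration_frac,
        random_state=seed, stratify=y_tr)
    members = [_train_member(m, X_fit, y_fit, config, seed)
               for m in member_names]
    f1s = [_f1_of(y_cal, fn(X_cal)) for fn in members]
    try:
        weights = ens.compute_weights(f1s, member_names=member_names)
    except ValueError:  # all calibration F1s zero -> equal weights
        weights = ens.EnsembleWeights(
            member_names=tuple(member_names),
            f1_scores=np.asarray(f1s, float),
            weights=np.full(len(f1s), 1.0 / len(f1s)))
    verdicts = [fn(X_te) for fn in members]
    fused = ens.fused_binary(ens.weighted_combine(verdicts, weights))
    return fused, weights


def _evaluate_candidates_once(X: np.ndarray, y: np.ndarray,
                              strata: np.ndarray, config: ProtocolConfig,
                              seed: int,
                              candidates: Sequence[str] = CANDIDATES,
                              ) -> dict[str, ev.MetricsReport]:
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=config.train_frac, random_state=seed,
        stratify=strata)
    base_names = ("md", "extratrees", "xgboost")
    base = {m: _train_member(m, X_tr, y_tr, config, seed)
            for m in base_names if m in candidates
            or "voting" in candidates}
    verdicts_te = {m: fn(X_te) for m, fn in base.items()}
    out: dict[str, ev.MetricsReport] = {}
    for cand in candidates:
        if cand in base_names:
            y_hat = verdicts_te[cand]
        elif cand == "voting":
            y_hat = ens.majority_vote([verdicts_te[m] for m in base_names])
        elif cand == "weighting":
            y_hat, _ = _weighting_verdicts(
                config.fusion_members, X_tr, y_tr, X_te, config, seed)
        else:
            raise ValueError(f"unknown candidate {cand!r}")
        out[cand] = ev.metrics(ev.ConfusionMatrix.from_labels(y_te, y_hat))
    return out


@dataclass
class ModelSelectionReport:
    per_view: dict[str, dict[str, ev.MetricsReport]]
    winner: dict[str, str]


def run_model_selection(training: SampleSet, config: ProtocolConfig,
                        views: Sequence[str] = VIEWS,
                        candidates: Sequence[str] = CANDIDATES,
                        ) -> ModelSelectionReport:
    """Evaluate every candidate on every view; pick the winner per view.

    Each candidate is scored by mean F1 over ``config.repeats`` stratified
    random splits at ``config.train_frac``; ties break toward the
    candidate listed first.
    """
    per_view: dict[str, dict[str, ev.MetricsReport]] = {}
    winner: dict[str, str] = {}
    for view in views:
        fv = build_feature_view(training, view)
        if len(np.unique(fv.y)) < 2:
            raise ValueError("both classes required for model selection")
        strata = fv.strata()
        reps: dict[str, list[ev.MetricsReport]] = {c: [] for c in candidates}
        for r in range(config.repeats):
            once = _evaluate_candidates_once(
                fv.X, fv.y, strata, config, config.seed + r, candidates)
            for c in candidates:
                reps[c].append(once[c])
        agg = {c: ev.aggregate(reps[c]) for c in candidates}
        per_view[view] = agg

        def _score(c: str) -> float:
            f1 = agg[c].f1
            return f1 if not ev.is_undetermined(f1) else -1.0

        best = max(range(len(candidates)),
                   key=lambda i: (_score(candidates[i]), -i))
        winner[view] = candidates[best]
    return ModelSelectionReport(per_view=per_view, winner=winner)


# ---------------------------------------------------------------------------
# Blinded cross-validation with drift handling
# ---------------------------------------------------------------------------

DRIFT_MODES = ("exclude", "include_sugars", "include_sugars_and_others")


def _assert_no_leakage(train_ids: Sequence[str], test_ids: Sequence[str]) -> None:
    overlap = set(train_ids) & set(test_ids)
    if overlap:
        raise LeakageError(
            f"{len(overlap)} sample id(s) in both train and test: "
            f"{sorted(overlap)[:5]}")


@dataclass
class BlindedCrossvalResult:
    drift_mode: str
    held_out: tuple[str, ...]
    metrics: ev.MetricsReport
    weights: ens.EnsembleWeights
    n_train: int
    n_test: int
    test_flags: dict[str, int]  # sample_id -> fused verdict


def blinded_crossval(training: SampleSet, crossval: SampleSet,
                     drift_mode: str = "include_sugars",
                     held_out: Sequence[str] | None = None,
                     sugars: Sequence[str] = ("glucose", "fructose", "sucrose"),
                     view: str = "combined16",
                     config: ProtocolConfig | None = None,
                     ) -> BlindedCrossvalResult:
    """Test on crossval normals + held-out-adulterant spikes.

    ``drift_mode`` controls which crossval spikes may augment the training
    pool: none (``exclude``), the sugar adulterants (``include_sugars``) or
    every non-held-out crossval spike (``include_sugars_and_others``).
    Crossval normals and held-out spikes never enter training; any overlap
    raises :class:`LeakageError`.
    """
    config = config or ProtocolConfig()
    if drift_mode not in DRIFT_MODES:
        raise ValueError(f"drift_mode must be one of {DRIFT_MODES}")
    cv_adults = {r.adulterant for r in crossval if r.label == "spiked"}
    train_adults = {r.adulterant for r in training if r.label == "spiked"}
    if held_out is None:
        held_out = tuple(sorted(cv_adults - train_adults))
    held_out = tuple(held_out)
    missing = set(held_out) - cv_adults
    if missing:
        raise ConfigError(f"held-out adulterant(s) absent from crossval: "
                          f"{sorted(missing)}")
    if drift_mode != "exclude":
        augment_pool = cv_adults - set(held_out)
        if drift_mode == "include_sugars":
            augment_pool &= set(sugars)
        if not augment_pool:
            raise ConfigError(
                f"drift_mode {drift_mode!r} has no crossval adulterants to "
                "include (all held out)")
    else:
        augment_pool = set()
    if set(held_out) & train_adults:
        raise LeakageError(
            f"held-out adulterant(s) present in training batch: "
            f"{sorted(set(held_out) & train_adults)}")

    train_records = list(training)
    train_records += [r for r in crossval
                      if r.label == "spiked" and r.adulterant in augment_pool]
    test_records = [r for r in crossval
                    if r.label == "normal"
                    or (r.label == "spiked" and r.adulterant in held_out)]
    if any(r.adulterant in held_out for r in train_records
           if r.label == "spiked"):
        raise LeakageError("a held-out-adulterant sample entered training")

    train_set = SampleSet(train_records, provenance="crossval-train-pool")
    test_set = SampleSet(test_records, provenance="crossval-test")
    fv_tr = build_feature_view(train_set, view)
    fv_te = build_feature_view(test_set, view)
    _assert_no_leakage(fv_tr.sample_ids, fv_te.sample_ids)

    fused, weights = _weighting_verdicts(
        config.fusion_members, fv_tr.X, fv_tr.y, fv_te.X, config, config.seed)
    rep = ev.metrics(ev.ConfusionMatrix.from_labels(fv_te.y, fused))
    return BlindedCrossvalResult(
        drift_mode=drift_mode, held_out=held_out, metrics=rep,
        weights=weights, n_train=len(fv_tr.sample_ids),
        n_test=len(fv_te.sample_ids),
        test_flags=dict(zip(fv_te.sample_ids, fused.tolist())))


# ---------------------------------------------------------------------------
# Leave-one-adulterant-out + LOD
# ---------------------------------------------------------------------------

@dataclass
class LODReport:
    adulterant: str
    tested_concentrations: tuple[float, ...]
    detected: tuple[bool, ...]
    lod: float | str  # a concentration, or NOT_DETECTED

    def __str__(self) -> str:
        if self.lod == NOT_DETECTED:
            return (f"{self.adulterant}: LOD > "
                    f"{max(self.tested_concentrations)} g/100 g")
        return f"{self.adulterant}: LOD = {self.lod} g/100 g"


def estimate_lod(adulterant: str, concentrations: Sequence[float],
                 flags: Sequence[int]) -> LODReport:
    """Lowest tested concentration with >= 1 flagged spiked sample.

    ``concentrations``/``flags`` are per spiked sample. With no detection
    at any level the report carries NOT_DETECTED (read: above the highest
    tested concentration).
    """
    if len(concentrations) == 0 or len(concentrations) != len(flags):
        raise ValueError("need matching non-empty concentrations and flags")
    conc = np.asarray(concentrations, float)
    flg = np.asarray(flags, int)
    levels = tuple(sorted(set(conc.tolist())))
    detected = tuple(bool(flg[conc == c].max()) for c in levels)
    lod: float | str = NOT_DETECTED
    for c, d in zip(levels, detected):
        if d:
            lod = c
            break
    return LODReport(adulterant=adulterant, tested_concentrations=levels,
                     detected=detected, lod=lod)


@dataclass
class LeaveOneOutResult:
    metrics: dict[str, ev.MetricsReport]
    lod: dict[str, LODReport]
    # per held-out adulterant: (concentration, fused verdict) per spiked sample
    spike_flags: dict[str, list[tuple[float, int]]] = field(
        default_factory=dict)


def leave_one_adulterant_out(dataset: SampleSet,
                             adulterants: Sequence[str] | None = None,
                             view: str = "combined16",
                             config: ProtocolConfig | None = None,
                             ) -> LeaveOneOutResult:
    """Hold out each adulterant in turn; test on its spikes + normal holdout.

    A fixed 30% of the normals (selected once per call from the protocol
    seed) is reserved as the shared normal test pool, so the per-adulterant
    results are comparable. Training uses the remaining normals and every
    spike of the *other* adulterants; the weighting ensemble is the
    detector. LOD per adulterant is derived from the per-concentration
    detection flags.
    """
    config = config or ProtocolConfig()
    present = sorted({r.adulterant for r in dataset if r.label == "spiked"})
    if len(present) < 2:
        raise ValueError("need >= 2 adulterants for leave-one-out")
    if adulterants is None:
        adulterants = present
    for name in adulterants:
        if name not in present:
            raise ValueError(f"adulterant {name!r} has no samples")

    normals = [r for r in dataset if r.label == "normal"]
    rng = np.random.default_rng(config.seed)
    n_hold = max(1, int(round(config.normal_holdout_frac * len(normals))))
    hold_idx = set(rng.choice(len(normals), size=n_hold, replace=False).tolist())
    normal_hold = [r for i, r in enumerate(normals) if i in hold_idx]
    normal_train = [r for i, r in enumerate(normals) if i not in hold_idx]

    metrics_out: dict[str, ev.MetricsReport] = {}
    lod_out: dict[str, LODReport] = {}
    flags_out: dict[str, list[tuple[float, int]]] = {}
    for target in adulterants:
        train_records = normal_train + [
            r for r in dataset
            if r.label == "spiked" and r.adulterant != target]
        test_records = normal_hold + [
            r for r in dataset
            if r.label == "spiked" and r.adulterant == target]
        fv_tr = build_feature_view(
            SampleSet(train_records, "loo-train"), view)
        fv_te = build_feature_view(
            SampleSet(test_records, "loo-test"), view)
        _assert_no_leakage(fv_tr.sample_ids, fv_te.sample_ids)
        fused, _ = _weighting_verdicts(
            config.fusion_members, fv_tr.X, fv_tr.y, fv_te.X, config,
            config.seed)
        metrics_out[target] = ev.metrics(
            ev.ConfusionMatrix.from_labels(fv_te.y, fused))
        spiked_idx = np.flatnonzero(fv_te.y == 1)
        concs = [fv_te.concentration[i] for i in spiked_idx]
        lod_out[target] = estimate_lod(target, concs, fused[spiked_idx])
        flags_out[target] = [(c, int(f))
                             for c, f in zip(concs, fused[spiked_idx])]
    return LeaveOneOutResult(metrics=metrics_out, lod=lod_out,
                             spike_flags=flags_out)
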