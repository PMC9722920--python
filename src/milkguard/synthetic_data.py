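"""Synthetic raw-milk study generator.

The real archive behind this pipeline is proprietary, so every stage is
exercised on generated data that reproduces the *structure* the method
assumes, not the real distributions:

* eight correlated compositional features drawn from a multivariate normal
  with additive season bins (Jan–Mar baseline; Apr–Aug lower fat/protein/
  NFS/TS/acidity and higher lactose; Sep–Dec the reverse) and per-year
  drift vectors;
* absorbance spectra built as sums of Gaussian bands on the canonical
  1056-point 1000–3550 cm⁻¹ grid, band heights modulated by the sample's
  composition (carbohydrate bands by lactose, amide II by protein, carbonyl
  and C–H stretch by fat) plus i.i.d. Gaussian noise;
* adulterant spiking that is linear in concentration — the simplest model
  consistent with serial dilution — over the standard concentration series
  {0.01, 0.02, 0.05, 0.1, 0.2} g/100 g.

The shipped mean profile, covariance and adulterant signatures are
order-of-magnitude-plausible constants for bovine raw milk; they are NOT
estimates of any real producer's distributions, and the adulterant spectral
signatures are illustrative only. The default study design mirrors the
protocol's two batches: a training batch (372 normals + 19 adulterants
x 15 spikes) and a later, drifted cross-validation batch (65 normals + 6
adulterants x 15 spikes) in which hydrogen peroxide, sodium hydroxide and
salt appear only in cross-validation.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass, field, replace as _dc_replace

import numpy as np

from .data_model_io import (
    FEATURES,
    CompositionalProfile,
    ConfigError,
    SampleRecord,
    SampleSet,
    Spectrum,
    default_grid,
)
from .drift_stats import SeasonBin, assign_season

__all__ = [
    "SpectrumPeak", "AdulterantSignature", "GeneratorConfig",
    "default_generator_config", "default_adulterant_library",
    "generate_normal", "spike", "generate_study",
]


def _fvec(**kw: float) -> np.ndarray:
    """8-vector in canonical feature order from sparse keyword deltas."""
    unknown = set(kw) - set(FEATURES)
    if unknown:
        raise ValueError(f"unknown feature(s): {sorted(unknown)}")
    return np.array([kw.get(f, 0.0) for f in FEATURES])


@dataclass(frozen=True)
class SpectrumPeak:
    """One Gaussian band: center/width in cm⁻¹, height in AU.

    ``modulates`` optionally names the compositional feature whose relative
    level scales the band height:

        height_eff = height · (1 + mod_scale · (value/mean − 1)),

    so ``mod_scale`` sets the strength (and, if negative, the direction —
    e.g. the O–H stretch grows as total solids fall) of the coupling.
    """

    center: float
    width: float
    height: float
    modulates: str | None = None
    mod_scale: float = 1.0


@dataclass(frozen=True)
class AdulterantSignature:
    """Per-unit-concentration effect of one adulterant.

    ``composition_delta`` is added to the profile and each
    ``spectral_delta`` band to the spectrum, both scaled by concentration in
    g/100 g. Categories follow the four adulterant groups of the study
    design (common chemicals, nitrogen-based, carbohydrate-based, others).
    """

    name: str
    composition_delta: np.ndarray
    spectral_delta: tuple[SpectrumPeak, ...] = ()
    category: str = "other"

    _CATEGORIES = ("common chemical", "nitrogen-based", "carbohydrate-based",
                   "other")

    def __post_init__(self) -> None:
        if self.category not in self._CATEGORIES:
            raise ValueError(f"category must be one of {self._CATEGORIES}")
        if (not np.any(self.composition_delta) and not self.spectral_delta):
            raise ValueError(
                f"signature {self.name!r} has no nonzero delta")


# ---------------------------------------------------------------------------
# Default constants (plausible for bovine raw milk; NOT fitted to any data)
# ---------------------------------------------------------------------------

DEFAULT_MEAN_PROFILE = _fvec(fat=3.8, protein=3.2, nfs=8.7, ts=12.5,
                             lactose=4.8, rd=1.030, fpd=0.525, acidity=16.0)

_DEFAULT_SD = _fvec(fat=0.40, protein=0.25, nfs=0.30, ts=0.50,
                    lactose=0.15, rd=0.0015, fpd=0.010, acidity=1.0)

# correlation structure: TS tracks fat+NFS; NFS carries protein/lactose/
# minerals and drives RD; FPD follows dissolved solids
_DEFAULT_CORR = np.array([
    #  fat   prot  nfs   ts    lact  rd    fpd   acid
    [1.00, 0.30, 0.10, 0.80, 0.00, -0.30, 0.00, 0.10],   # fat
    [0.30, 1.00, 0.70, 0.50, 0.10, 0.40, 0.20, 0.20],    # protein
    [0.10, 0.70, 1.00, 0.60, 0.50, 0.60, 0.30, 0.20],    # nfs
    [0.80, 0.50, 0.60, 1.00, 0.30, 0.20, 0.20, 0.20],    # ts
    [0.00, 0.10, 0.50, 0.30, 1.00, 0.20, 0.30, -0.10],   # lactose
    [-0.30, 0.40, 0.60, 0.20, 0.20, 1.00, 0.20, 0.10],   # rd
    [0.00, 0.20, 0.30, 0.20, 0.30, 0.20, 1.00, 0.10],    # fpd
    [0.10, 0.20, 0.20, 0.20, -0.10, 0.10, 0.10, 1.00],   # acidity
])

DEFAULT_COVARIANCE = _DEFAULT_CORR * np.outer(_DEFAULT_SD, _DEFAULT_SD)

DEFAULT_SEASONAL_SHIFT: dict[SeasonBin, np.ndarray] = {
    SeasonBin.JAN_MAR: _fvec(),
    SeasonBin.APR_AUG: _fvec(fat=-0.15, protein=-0.08, nfs=-0.10, ts=-0.20,
                             lactose=0.05, acidity=-0.40),
    SeasonBin.SEP_DEC: _fvec(fat=0.12, protein=0.06, nfs=0.08, ts=0.15,
                             lactose=-0.04, acidity=0.30),
}

DEFAULT_ANNUAL_SHIFT: dict[int, np.ndarray] = {
    2020: _fvec(),
    2021: _fvec(fat=0.12, protein=0.10, nfs=0.08, ts=0.18, lactose=-0.06,
                rd=0.0005, fpd=0.002, acidity=0.50),
}

#: Batch-dependent expression of the spike signal: procedural/matrix batch
#: effects attenuate how strongly an added adulterant shows up in the
#: measured features of a later batch (the drift failure mode the blinded
#: cross-validation protocol is designed to recover from).
DEFAULT_SPIKE_ATTENUATION: dict[int, float] = {2020: 1.0, 2021: 0.2}

DEFAULT_SPECTRUM_PEAKS: tuple[SpectrumPeak, ...] = (
    SpectrumPeak(1045.0, 14.0, 0.50, "lactose"),        # carbohydrate C-O
    SpectrumPeak(1080.0, 12.0, 0.38, "lactose"),
    SpectrumPeak(1350.0, 90.0, 0.22, "nfs", 2.0),       # broad fingerprint band
    SpectrumPeak(1548.0, 18.0, 0.30, "protein"),        # amide II
    SpectrumPeak(1745.0, 14.0, 0.48, "fat"),            # ester carbonyl
    SpectrumPeak(2855.0, 16.0, 0.32, "fat"),            # CH2 sym stretch
    SpectrumPeak(2925.0, 16.0, 0.44, "fat"),            # CH2 asym stretch
    SpectrumPeak(3490.0, 35.0, 0.62, "ts", -1.0),       # O-H stretch (water)
)

DEFAULT_CONCENTRATIONS = (0.01, 0.02, 0.05, 0.1, 0.2)

HELD_OUT_ADULTERANTS = ("hydrogen_peroxide", "sodium_hydroxide", "salt")
SUGAR_ADULTERANTS = ("glucose", "fructose", "sucrose")

TRAINING_ADULTERANTS = (
    "potassium_dichromate", "potassium_sulfate", "sodium_citrate",
    "trisodium_citrate", "citric_acid", "ammonium_sulfate", "urea",
    "melamine", "whey_protein", "whole_milk_powder", "skimmed_milk_powder",
    "soy_milk", "sucrose", "glucose", "lactose", "fructose", "maltodextrin",
    "starch", "water",
)
CROSSVAL_ADULTERANTS = HELD_OUT_ADULTERANTS + SUGAR_ADULTERANTS


#: Generic "dissolved solute" component shared by (almost) all adulterants:
#: adding material to milk raises density and freezing-point depression and
#: adds absorbance across the mixed fingerprint band. This shared axis is
#: what lets a non-targeted detector generalize to adulterants it has never
#: seen.
SOLUTE_COMPOSITION = _fvec(rd=0.015, fpd=0.08)
SOLUTE_PEAK = SpectrumPeak(1350.0, 60.0, 0.50)


def _with_solute(sig: AdulterantSignature, solute: float,
                 ) -> AdulterantSignature:
    if solute == 0.0:
        return sig
    return AdulterantSignature(
        name=sig.name,
        composition_delta=sig.composition_delta + solute * SOLUTE_COMPOSITION,
        spectral_delta=sig.spectral_delta + (SpectrumPeak(
            SOLUTE_PEAK.center, SOLUTE_PEAK.width,
            solute * SOLUTE_PEAK.height),),
        category=sig.category,
    )


def default_adulterant_library() -> dict[str, AdulterantSignature]:
    """Illustrative signatures for the 22 adulterants of the study design.

    Each signature is a specific fingerprint (the features and spectral
    windows that adulterant physically touches) plus the shared solute
    component above. Magnitudes are chosen so the strongest concentration
    (0.2 g/100 g) shifts the primary affected features by a few reference
    SDs while the lowest (0.01) sits near the noise floor; spectral bands
    fall inside the standardization windows so the 8-coordinate view can
    see them. Hydrogen peroxide carries almost no signature (it decomposes
    to water), mirroring its role as the hard case of the study; water is
    a diluent with negative deltas and no solute component.
    """
    P = SpectrumPeak
    sig = AdulterantSignature
    lib = {
        # -- common chemicals -------------------------------------------
        "potassium_dichromate": sig(
            "potassium_dichromate", _fvec(acidity=1.0),
            (P(1280.0, 40.0, 0.30),), "common chemical"),
        "potassium_sulfate": sig(
            "potassium_sulfate", _fvec(fpd=0.05),
            (P(1090.0, 15.0, 0.50),), "common chemical"),
        "sodium_citrate": sig(
            "sodium_citrate", _fvec(acidity=-3.0),
            (P(1580.0, 16.0, 0.60),), "common chemical"),
        "trisodium_citrate": sig(
            "trisodium_citrate", _fvec(acidity=-4.0),
            (P(1585.0, 16.0, 0.70),), "common chemical"),
        "citric_acid": sig(
            "citric_acid", _fvec(acidity=6.0),
            (P(1740.0, 15.0, 0.80),), "common chemical"),
        "hydrogen_peroxide": sig(
            "hydrogen_peroxide", _fvec(fpd=0.02),
            (P(1350.0, 40.0, 0.08),), "common chemical"),
        "sodium_hydroxide": sig(
            "sodium_hydroxide", _fvec(acidity=-8.0),
            (P(1560.0, 18.0, 0.90),), "common chemical"),
        "salt": sig(
            "salt", _fvec(fpd=0.15),
            (P(3500.0, 40.0, 0.40),), "common chemical"),
        # -- nitrogen-based ---------------------------------------------
        "ammonium_sulfate": sig(
            "ammonium_sulfate", _fvec(protein=3.0),
            (P(1420.0, 20.0, 0.50), P(1090.0, 15.0, 0.30)), "nitrogen-based"),
        "urea": sig(
            "urea", _fvec(protein=4.0),
            (P(1590.0, 18.0, 0.70),), "nitrogen-based"),
        "melamine": sig(
            "melamine", _fvec(protein=5.0),
            (P(1550.0, 15.0, 1.00), P(1030.0, 12.0, 0.30)), "nitrogen-based"),
        "whey_protein": sig(
            "whey_protein", _fvec(protein=4.0, nfs=3.0, ts=3.0),
            (P(1540.0, 20.0, 0.80),), "nitrogen-based"),
        "whole_milk_powder": sig(
            "whole_milk_powder",
            _fvec(fat=2.0, protein=1.5, nfs=4.0, ts=6.0, lactose=2.0),
            (P(1745.0, 14.0, 0.50), P(2920.0, 16.0, 0.50)), "nitrogen-based"),
        "skimmed_milk_powder": sig(
            "skimmed_milk_powder",
            _fvec(protein=2.0, nfs=5.0, ts=5.0, lactose=2.5),
            (P(1040.0, 14.0, 0.50), P(1540.0, 20.0, 0.30)), "nitrogen-based"),
        "soy_milk": sig(
            "soy_milk", _fvec(protein=1.5, fat=0.8, ts=0.8),
            (P(1745.0, 14.0, 0.30), P(1550.0, 18.0, 0.40)), "nitrogen-based"),
        # -- carbohydrate-based -----------------------------------------
        "sucrose": sig(
            "sucrose", _fvec(lactose=2.0, nfs=2.0, ts=2.0),
            (P(1055.0, 12.0, 1.00), P(1025.0, 12.0, 0.60)),
            "carbohydrate-based"),
        "glucose": sig(
            "glucose", _fvec(lactose=1.5, nfs=1.5, ts=1.5),
            (P(1035.0, 12.0, 0.80),), "carbohydrate-based"),
        "lactose": sig(
            "lactose", _fvec(lactose=3.0, nfs=2.0, ts=2.0),
            (P(1045.0, 14.0, 1.00), P(1075.0, 12.0, 0.50)),
            "carbohydrate-based"),
        "fructose": sig(
            "fructose", _fvec(lactose=1.5, nfs=1.5, ts=1.5),
            (P(1063.0, 12.0, 0.80),), "carbohydrate-based"),
        "maltodextrin": sig(
            "maltodextrin", _fvec(lactose=1.0, nfs=2.0, ts=2.0),
            (P(1020.0, 14.0, 0.90),), "carbohydrate-based"),
        "starch": sig(
            "starch", _fvec(nfs=2.0, ts=2.5),
            (P(1015.0, 14.0, 1.00),), "carbohydrate-based"),
        # -- others ------------------------------------------------------
        "water": sig(
            "water",
            _fvec(fat=-0.3, protein=-0.25, nfs=-0.6, ts=-0.9, lactose=-0.35,
                  rd=-0.005, fpd=-0.05, acidity=-1.0),
            (P(3500.0, 40.0, 0.30),), "other"),
    }
    solute_factor = {"water": 0.0, "hydrogen_peroxide": 0.05}
    return {name: _with_solute(s, solute_factor.get(name, 1.0))
            for name, s in lib.items()}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic generator (see module docstring)."""

    n_normal_training: int = 372
    n_normal_crossval: int = 65
    mean_profile: np.ndarray = field(
        default_factory=lambda: DEFAULT_MEAN_PROFILE.copy())
    covariance: np.ndarray = field(
        default_factory=lambda: DEFAULT_COVARIANCE.copy())
    seasonal_shift: dict = field(
        default_factory=lambda: {k: v.copy()
                                 for k, v in DEFAULT_SEASONAL_SHIFT.items()})
    annual_shift: dict = field(
        default_factory=lambda: {k: v.copy()
                                 for k, v in DEFAULT_ANNUAL_SHIFT.items()})
    annual_spike_attenuation: dict = field(
        default_factory=lambda: dict(DEFAULT_SPIKE_ATTENUATION))
    spectrum_peaks: tuple = DEFAULT_SPECTRUM_PEAKS
    noise_sd: float = 0.005
    adulterant_library: dict = field(default_factory=default_adulterant_library)
    concentrations: tuple = DEFAULT_CONCENTRATIONS
    n_spikes_per_adulterant: int = 15
    training_adulterants: tuple = TRAINING_ADULTERANTS
    crossval_adulterants: tuple = CROSSVAL_ADULTERANTS
    held_out_adulterants: tuple = HELD_OUT_ADULTERANTS
    training_year: int = 2020
    crossval_year: int = 2021
    wavenumbers: np.ndarray = field(default_factory=default_grid)
    with_spectra: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        cov = self.covariance
        if cov.shape != (8, 8) or not np.allclose(cov, cov.T, atol=1e-10):
            raise ConfigError("covariance must be a symmetric 8x8 matrix")
        if np.linalg.eigvalsh(cov).min() < -1e-10 * abs(np.trace(cov)):
            raise ConfigError("covariance must be positive semi-definite")
        conc = np.asarray(self.concentrations)
        if np.any(conc <= 0) or np.any(np.diff(conc) <= 0):
            raise ConfigError(
                "concentrations must be strictly positive and ascending")
        w_lo, w_hi = self.wavenumbers[0], self.wavenumbers[-1]
        for peak in self.spectrum_peaks:
            if not (w_lo <= peak.center <= w_hi):
                raise ConfigError(
                    f"peak center {peak.center} outside grid "
                    f"[{w_lo}, {w_hi}]")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")


def default_generator_config(seed: int = 0, **overrides) -> GeneratorConfig:
    return GeneratorConfig(seed=seed, **overrides)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _uniform_dates(rng: np.random.Generator, start: _dt.date, end: _dt.date,
                   n: int) -> list[_dt.date]:
    span = (end - start).days
    if span < 0:
        raise ValueError("date range is empty")
    offsets = rng.integers(0, span + 1, size=n)
    return [start + _dt.timedelta(days=int(d)) for d in offsets]


def _shift_for(config: GeneratorConfig, date: _dt.date) -> np.ndarray:
    shift = config.seasonal_shift.get(assign_season(date))
    total = shift.copy() if shift is not None else np.zeros(8)
    annual = config.annual_shift.get(date.year)
    if annual is not None:
        total += annual
    return total

def _profile_from(values: np.ndarray) -> CompositionalProfile:
    vals = values.copy()
    # numerical guards for the physical invariants of the type
    idx_ts, idx_nfs = FEATURES.index("ts"), FEATURES.index("nfs")
    for i, name in enumerate(("fat", "protein", "nfs", "ts", "lactose")):
        j = FEATURES.index(name)
        vals[j] = max(vals[j], 0.0)
    vals[idx_ts] = max(vals[idx_ts], vals[idx_nfs])
    return CompositionalProfile.from_array(vals)


def synth_spectrum(profile: CompositionalProfile, config: GeneratorConfig,
                   rng: np.random.Generator) -> Spectrum:
    """Sum of Gaussian bands modulated by the profile, plus i.i.d. noise."""
    w = config.wavenumbers
    a = np.zeros_like(w)
    values = profile.as_array()
    for peak in config.spectrum_peaks:
        h = peak.height
        if peak.modulates is not None:
            i = FEATURES.index(peak.modulates)
            mean_i = config.mean_profile[i]
            if mean_i != 0:
                h *= 1.0 + peak.mod_scale * (values[i] / mean_i - 1.0)
        a += h * np.exp(-0.5 * ((w - peak.center) / peak.width) ** 2)
    if config.noise_sd > 0:
        a = a + rng.normal(0.0, config.noise_sd, size=w.size)
    return Spectrum(w.copy(), a)


def generate_normal(config: GeneratorConfig, n: int,
                    dates: tuple[_dt.date, _dt.date] | None = None,
                    seed: int | None = None,
                    id_prefix: str = "N",
                    provenance: str = "synthetic-normal") -> SampleSet:
    """Generate ``n`` normal-labelled records with drift applied by date.

    ``dates`` is an inclusive (start, end) range sampled uniformly; the
    default covers the training year. Deterministic given the seed
    (``config.seed`` when not overridden).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if dates is None:
        y = config.training_year
        dates = (_dt.date(y, 1, 1), _dt.date(y, 12, 31))
    sample_dates = _uniform_dates(rng, dates[0], dates[1], n)
    base = rng.multivariate_normal(config.mean_profile, config.covariance,
                                   size=n, method="cholesky")
    records = []
    for i in range(n):
        values = base[i] + _shift_for(config, sample_dates[i])
        profile = _profile_from(values)
        spectrum = (synth_spectrum(profile, config, rng)
                    if config.with_spectra else None)
        records.append(SampleRecord(
            sample_id=f"{id_prefix}{i:05d}",
            date=sample_dates[i],
            label="normal",
            profile=profile,
            spectrum=spectrum,
        ))
    return SampleSet(records, provenance=provenance)


def spike(record: SampleRecord, signature: AdulterantSignature,
          concentration: float, seed: int | None = None,
          expression: float = 1.0) -> SampleRecord:
    """Spike a copy of ``record`` with ``concentration`` g/100 g of an
    adulterant.

    The perturbation is linear: profile += c·composition_delta and each
    spectral band adds c·height at its center. ``expression`` scales how
    strongly the nominal concentration shows up in the measurements
    (batch/procedural effects; the recorded concentration stays nominal).
    ``seed`` is accepted for interface symmetry but unused — spiking is
    deterministic. A zero concentration leaves the measurements unchanged
    but still relabels the record (flagged degenerate with a warning).
    """
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    if concentration == 0:
        warnings.warn(
            f"spiking {record.sample_id} with {signature.name} at "
            "concentration 0: degenerate spike (label changes, data do not)",
            stacklevel=2)
    c_eff = expression * concentration
    values = record.profile.as_array() + c_eff * signature.composition_delta
    profile = _profile_from(values)
    spectrum = None
    if record.spectrum is not None:
        spec = record.spectrum.copy()
        w = spec.wavenumbers
        for peak in signature.spectral_delta:
            spec.absorbances = spec.absorbances + (
                c_eff * peak.height
                * np.exp(-0.5 * ((w - peak.center) / peak.width) ** 2))
        spectrum = spec
    return SampleRecord(
        sample_id=record.sample_id,
        date=record.date,
        label="spiked",
        profile=profile,
        adulterant=signature.name,
        concentration=concentration,
        spectrum=spectrum,
        replicate_index=record.replicate_index,
    )


def _spike_batch(config: GeneratorConfig, adulterants: tuple[str, ...],
                 year: int, rng: np.random.Generator,
                 id_prefix: str) -> list[SampleRecord]:
    records: list[SampleRecord] = []
    n_per = config.n_spikes_per_adulterant
    conc_cycle = list(config.concentrations)
    expression = config.annual_spike_attenuation.get(year, 1.0)
    for name in adulterants:
        if name not in config.adulterant_library:
            raise ConfigError(f"unknown adulterant {name!r} in study design")
        signature = config.adulterant_library[name]
        bases = generate_normal(
            config, n_per,
            dates=(_dt.date(year, 1, 1), _dt.date(year, 12, 31)),
            seed=int(rng.integers(2 ** 31)),
            id_prefix=f"{id_prefix}-{name}-",
            provenance="spike-base")
        for i, rec in enumerate(bases):
            conc = conc_cycle[i % len(conc_cycle)]
            records.append(spike(rec, signature, conc, expression=expression))
    return records


def generate_study(config: GeneratorConfig) -> dict[str, SampleSet]:
    """Generate the two-batch study: training and drifted cross-validation.

    Training: normals + spikes of every training adulterant, dated in the
    training year. Cross-validation: its own normals and spikes (held-out
    adulterants plus sugars), dated in the crossval year so the annual
    drift vector separates the batches. Held-out adulterants must not
    appear in the training list.
    """
    overlap = set(config.held_out_adulterants) & set(config.training_adulterants)
    if overlap:
        raise ConfigError(
            f"held-out adulterants also in training: {sorted(overlap)}")
    rng = np.random.default_rng(config.seed)
    y_tr, y_cv = config.training_year, config.crossval_year

    train_normals = generate_normal(
        config, config.n_normal_training,
        dates=(_dt.date(y_tr, 1, 1), _dt.date(y_tr, 12, 31)),
        seed=int(rng.integers(2 ** 31)), id_prefix="TN",
        provenance=f"training-{y_tr}")
    train_spikes = _spike_batch(config, config.training_adulterants, y_tr,
                                rng, "TS")
    cv_normals = generate_normal(
        config, config.n_normal_crossval,
        dates=(_dt.date(y_cv, 1, 1), _dt.date(y_cv, 12, 31)),
        seed=int(rng.integers(2 ** 31)), id_prefix="CN",
        provenance=f"crossval-{y_cv}")
    cv_spikes = _spike_batch(config, config.crossval_adulterants, y_cv,
                             rng, "CS")

    training = SampleSet(list(train_normals) + train_spikes,
                         provenance=f"training-{y_tr}")
    crossval = SampleSet(list(cv_normals) + cv_spikes,
                         provenance=f"crossval-{y_cv}")
    return {"training": training, "crossval": crossval}
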