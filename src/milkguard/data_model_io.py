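"""Domain types and file I/O for raw-milk sample tables and FTIR spectra.

A sample is described by eight physiochemical features measured by the
MilkoScan-style routine quality check — fat, protein, non-fat solids (NFS),
total solids (TS), lactose, relative density (RD), freezing point depression
(FPD) and titratable acidity — and, optionally, a full mid-infrared
absorbance spectrum of 1056 points on a fixed wavenumber grid.

Sample tables travel as CSV/TSV with a header; spectra travel either wide
(one row per sample, one column per wavenumber) or long
(sample_id, wavenumber, absorbance). The canonical internal wavenumber axis
is ascending; files stored descending are flipped on ingest.
"""

from __future__ import annotations

import datetime as _dt
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("milkguard")

#: Canonical order of the eight compositional features.
FEATURES: tuple[str, ...] = (
    "fat", "protein", "nfs", "ts", "lactose", "rd", "fpd", "acidity",
)

#: Canonical instrument grid: 1056 points, ascending 1000 -> 3550 cm^-1.
N_GRID_POINTS = 1056
GRID_LO_CM1 = 1000.0
GRID_HI_CM1 = 3550.0

VALID_LABELS = frozenset({"normal", "spiked", "untested"})


def default_grid(n: int = N_GRID_POINTS,
                 lo: float = GRID_LO_CM1,
                 hi: float = GRID_HI_CM1) -> np.ndarray:
    """Ascending canonical wavenumber grid (cm^-1)."""
    return np.linspace(lo, hi, n)


class SchemaError(ValueError):
    """A mandatory column is missing or the column mapping is invalid."""


class FormatError(ValueError):
    """A row of an input file violates the file-format contract."""


class ConfigError(ValueError):
    """A configuration value violates its invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompositionalProfile:
    """The eight physiochemical features of one milk sample.

    Units: fat/protein/nfs/ts/lactose in g/100 g; rd dimensionless;
    fpd in degrees C (depression, positive); acidity in degrees T.
    """

    fat: float
    protein: float
    nfs: float
    ts: float
    lactose: float
    rd: float
    fpd: float
    acidity: float

    def __post_init__(self) -> None:
        vals = self.as_array()
        if not np.all(np.isfinite(vals)):
            raise ValueError("all eight compositional features must be finite")
        if self.ts < self.nfs:
            raise ValueError(
                f"total solids ({self.ts}) must be >= non-fat solids ({self.nfs})"
            )
        for name in ("fat", "protein", "nfs", "ts", "lactose"):
            if getattr(self, name) < 0:
                raise ValueError(f"mass fraction {name!r} must be >= 0")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in FEATURES], dtype=float)

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "CompositionalProfile":
        values = np.asarray(values, dtype=float)
        if values.shape != (len(FEATURES),):
            raise ValueError(f"expected {len(FEATURES)} values, got {values.shape}")
        return cls(**dict(zip(FEATURES, values.tolist())))


@dataclass
class Spectrum:
    """A full absorbance spectrum on a strictly monotone wavenumber grid.

    On construction the axis is normalized to strictly ascending order;
    descending input (as some instruments export) is flipped together with
    its absorbances.
    """

    wavenumbers: np.ndarray
    absorbances: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumbers, dtype=float)
        a = np.asarray(self.absorbances, dtype=float)
        if w.shape != a.shape or w.ndim != 1:
            raise ValueError("wavenumbers and absorbances must be 1-D, same length")
        if w.size < 2:
            raise ValueError("a spectrum needs at least 2 points")
        if np.any(~np.isfinite(w)) or np.any(~np.isfinite(a)):
            raise ValueError("spectrum contains NaN or infinite values")
        dw = np.diff(w)
        if np.all(dw < 0):  # stored descending -> normalize
            w, a = w[::-1], a[::-1]
        elif not np.all(dw > 0):
            raise ValueError("wavenumber axis must be strictly monotone")
        self.wavenumbers = w
        self.absorbances = a

    def __len__(self) -> int:
        return self.wavenumbers.size

    def copy(self) -> "Spectrum":
        return Spectrum(self.wavenumbers.copy(), self.absorbances.copy())


@dataclass
class SampleRecord:
    """One tested milk sample: identity, date, label, composition, spectrum."""

    sample_id: str
    date: _dt.date
    label: str
    profile: CompositionalProfile
    adulterant: str | None = None
    concentration: float | None = None  # g adulterant / 100 g milk
    spectrum: Spectrum | None = None
    replicate_index: int = 1

    def __post_init__(self) -> None:
        if self.label not in VALID_LABELS:
            raise ValueError(f"label must be one of {sorted(VALID_LABELS)}, "
                             f"got {self.label!r}")
        if self.label == "spiked" and self.adulterant is None:
            raise ValueError("spiked samples must name their adulterant")
        if self.concentration is not None and self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        if self.replicate_index < 1:
            raise ValueError("replicate_index must be >= 1")


@dataclass
class SampleSet:
    """An ordered, validated collection of sample records.

    ``(sample_id, replicate_index)`` pairs are unique; ingest never reorders
    records.
    """

    records: list[SampleRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("a SampleSet must be non-empty")
        keys = [(r.sample_id, r.replicate_index) for r in self.records]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValueError(f"duplicate (sample_id, replicate) keys: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SampleRecord]:
        return iter(self.records)

    def subset(self, predicate: Callable[[SampleRecord], bool],
               provenance: str | None = None) -> "SampleSet":
        kept = [r for r in self.records if predicate(r)]
        return SampleSet(kept, provenance if provenance is not None
                         else self.provenance)

    def feature_matrix(self) -> np.ndarray:
        """(n_records, 8) matrix in canonical feature order."""
        return np.vstack([r.profile.as_array() for r in self.records])

    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records])

    def binary_labels(self) -> np.ndarray:
        """1 for spiked (positive class), 0 otherwise."""
        return np.array([1 if r.label == "spiked" else 0 for r in self.records])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "sample_id": r.sample_id,
                "date": r.date.isoformat(),
                "label": r.label,
                "adulterant": r.adulterant if r.adulterant is not None else "",
                "concentration": (r.concentration
                                  if r.concentration is not None else np.nan),
                "replicate_index": r.replicate_index,
            }
            row.update(dict(zip(FEATURES, r.profile.as_array())))
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Sample-table I/O
# ---------------------------------------------------------------------------

#: identity column mapping; override entries to adapt a foreign header
DEFAULT_SCHEMA: dict[str, str] = {
    **{f: f for f in FEATURES},
    "sample_id": "sample_id",
    "date": "date",
    "label": "label",
    "adulterant": "adulterant",
    "concentration": "concentration",
    "replicate_index": "replicate_index",
}

_MANDATORY = tuple(FEATURES) + ("sample_id", "date", "label")


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_samples(path: str | Path,
                 schema: Mapping[str, str] | None = None) -> SampleSet:
    """Read a sample table (CSV/TSV with header) into a validated SampleSet.

    ``schema`` maps canonical field names to file column names; unmapped
    optional columns (adulterant, concentration, replicate_index) default to
    empty/NaN/1. Rows failing validation raise :class:`FormatError` listing
    the offending 1-based data-row numbers.
    """
    path = Path(path)
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    df = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)

    missing = [canon for canon in _MANDATORY if colmap[canon] not in df.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing mandatory column(s) "
            f"{[colmap[c] for c in missing]}"
        )

    records: list[SampleRecord] = []
    bad_rows: list[tuple[int, str]] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        rowd = dict(zip(df.columns, row))
        try:
            date = _dt.date.fromisoformat(rowd[colmap["date"]].strip())
        except ValueError:
            bad_rows.append((i, f"unparseable date {rowd[colmap['date']]!r}"))
            continue
        try:
            profile = CompositionalProfile(
                **{f: float(rowd[colmap[f]]) for f in FEATURES})
            adu_col = colmap["adulterant"]
            adulterant = (rowd[adu_col].strip() or None) \
                if adu_col in df.columns else None
            conc_col = colmap["concentration"]
            conc_raw = rowd.get(conc_col, "") if conc_col in df.columns else ""
            concentration = float(conc_raw) if str(conc_raw).strip() else None
            rep_col = colmap["replicate_index"]
            rep_raw = rowd.get(rep_col, "") if rep_col in df.columns else ""
            replicate = int(rep_raw) if str(rep_raw).strip() else 1
            records.append(SampleRecord(
                sample_id=str(rowd[colmap["sample_id"]]),
                date=date,
                label=rowd[colmap["label"]].strip(),
                profile=profile,
                adulterant=adulterant,
                concentration=concentration,
                replicate_index=replicate,
            ))
        except (ValueError, TypeError) as exc:
            bad_rows.append((i, str(exc)))
    if bad_rows:
        details = "; ".join(f"row {i}: {msg}" for i, msg in bad_rows[:10])
        raise FormatError(f"{path.name}: {len(bad_rows)} invalid row(s): {details}")
    return SampleSet(records, provenance=path.name)


def write_samples(samples: SampleSet, path: str | Path) -> None:
    """Write a sample table; round-trips through :func:`read_samples`."""
    path = Path(path)
    df = samples.to_frame()
    df.to_csv(path, sep=_sep_for(path), index=False,
              float_format="%.17g")


# ---------------------------------------------------------------------------
# Spectra I/O
# ---------------------------------------------------------------------------

def read_spectra(path: str | Path,
                 grid: np.ndarray | None = None) -> dict[str, Spectrum]:
    """Read spectra (wide or long CSV) into ``{sample_id: Spectrum}``.

    Wide: ``sample_id`` column plus one numeric-named column per wavenumber.
    Long: columns ``sample_id, wavenumber, absorbance``.
    All spectra are returned on an ascending axis; a ``grid`` argument
    enforces the expected number of points per spectrum.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
    if "wavenumber" in df.columns:  # long format
        out: dict[str, Spectrum] = {}
        for sid, grp in df.groupby("sample_id", sort=False):
            w = grp["wavenumber"].to_numpy(float)
            a = grp["absorbance"].to_numpy(float)
            order = np.argsort(w)
            spec = Spectrum(w[order], a[order])
            if grid is not None and len(spec) != len(grid):
                raise FormatError(
                    f"{path.name}: sample {sid!r} has {len(spec)} points, "
                    f"expected {len(grid)}")
            out[str(sid)] = spec
        return out
    # wide format
    if "sample_id" not in df.columns:
        raise SchemaError(f"{path.name}: expected a 'sample_id' column")
    wavecols = [c for c in df.columns if c != "sample_id"]
    try:
        w = np.array([float(c) for c in wavecols])
    except ValueError as exc:
        raise SchemaError(f"{path.name}: non-numeric wavenumber column: {exc}")
    out = {}
    for _, row in df.iterrows():
        a = row[wavecols].to_numpy(float)
        if grid is not None and a.size != len(grid):
            raise FormatError(
                f"{path.name}: sample {row['sample_id']!r} has {a.size} "
                f"points, expected {len(grid)}")
        out[str(row["sample_id"])] = Spectrum(w.copy(), a)
    return out


def write_spectra(spectra: Mapping[str, Spectrum], path: str | Path) -> None:
    """Write spectra in wide CSV form (ascending wavenumber columns)."""
    path = Path(path)
    items = list(spectra.items())
    if not items:
        raise ValueError("no spectra to write")
    w0 = items[0][1].wavenumbers
    for sid, spec in items:
        if not np.array_equal(spec.wavenumbers, w0):
            raise ValueError(f"sample {sid!r} is on a different grid")
    df = pd.DataFrame(
        np.vstack([s.absorbances for _, s in items]),
        columns=[f"{w:.6f}" for w in w0],
    )
    df.insert(0, "sample_id", [sid for sid, _ in items])
    df.to_csv(path, sep=_sep_for(path), index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# National-standard pass/fail hook
# ---------------------------------------------------------------------------

def attach_gb_standard(
    rules: Callable[[CompositionalProfile], bool] | None = None,
) -> Callable[[SampleRecord], str]:
    """Return a labelling function mapping a record to ``"pass"``/``"fail"``.

    ``rules`` is a total predicate over a CompositionalProfile (True = pass),
    e.g. a user's encoding of national raw-milk limits. The default predicate
    passes everything, because the actual limit values are not distributed
    with this package.
    """
    if rules is None:
        warnings.warn(
            "no pass/fail rules supplied: using an always-pass predicate; "
            "actual national-standard limit values are not distributed with "
            "this package", stacklevel=2)
        rules = lambda profile: True  # noqa: E731

    def labeller(record: SampleRecord) -> str:
        return "pass" if rules(record.profile) else "fail"

    return labeller


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

CONFIG_SECTIONS = ("io", "qc", "spectral", "md", "learners", "ensemble",
                   "protocol", "synth")


def load_config(path: str | Path) -> dict:
    """Load the single-YAML pipeline configuration.

    Unknown top-level sections raise :class:`ConfigError`; missing sections
    default to empty dicts so every consumer applies its own defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(raw) - set(CONFIG_SECTIONS)
    if unknown:
        raise ConfigError(f"unknown config section(s): {sorted(unknown)}")
    return {sec: raw.get(sec, {}) for sec in CONFIG_SECTIONS}


def setup_logging(level: int = logging.INFO) -> None:
    """Configure the package logger once (console handler, terse format)."""
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter(
            "%(asctime)s %(name)s %(levelname)s %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(level)
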