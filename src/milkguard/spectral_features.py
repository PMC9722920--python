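"""Standardization of a full absorbance spectrum into eight coordinates.

A 1056-point mid-IR spectrum is reduced to seven peak absorbances picked
from five fixed wavenumber windows plus one band-average absorbance over
1250–1450 cm⁻¹. The default window set (ascending, cm⁻¹):

    1000–1100  2 peaks   (carbohydrate C–O doublet)
    1250–1450  average   (mixed fingerprint band)
    1500–1600  1 peak    (amide II)
    1730–1800  1 peak    (ester carbonyl, fat)
    2840–2940  2 peaks   (CH2 symmetric/asymmetric stretch, fat)
    3450–3550  1 peak    (O–H stretch)

The doublet allocation (2,1,1,2,1) over the five peak windows reflects the
carbohydrate and C–H stretch regions of milk mid-IR spectra carrying paired
bands; it is fully configurable. Peaks are detected on the raw grid with no
interpolation; ties in height break toward the lower wavenumber.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model_io import ConfigError, Spectrum


@dataclass(frozen=True)
class RegionSpec:
    """One extraction window: ``[lo, hi]`` cm⁻¹, peak- or average-mode."""

    lo: float
    hi: float
    mode: str = "peak"  # "peak" | "average"
    n_peaks: int = 1

    def __post_init__(self) -> None:
        if self.lo >= self.hi:
            raise ValueError(f"region lo ({self.lo}) must be < hi ({self.hi})")
        if self.mode not in ("peak", "average"):
            raise ValueError(f"mode must be 'peak' or 'average', got {self.mode!r}")
        if self.mode == "peak" and self.n_peaks < 1:
            raise ValueError("n_peaks must be >= 1 in peak mode")


#: Default extraction profile: 7 peaks + 1 band average = 8 coordinates.
DEFAULT_REGIONS: tuple[RegionSpec, ...] = (
    RegionSpec(1000.0, 1100.0, "peak", 2),
    RegionSpec(1250.0, 1450.0, "average"),
    RegionSpec(1500.0, 1600.0, "peak", 1),
    RegionSpec(1730.0, 1800.0, "peak", 1),
    RegionSpec(2840.0, 2940.0, "peak", 2),
    RegionSpec(3450.0, 3550.0, "peak", 1),
)


@dataclass(frozen=True)
class SpectralCoordinates:
    """The 8-coordinate standardization of one spectrum.

    ``provenance[i]`` records, per coordinate, the source region and either
    the peak wavenumber (with a ``*`` suffix when the global-maximum
    fallback fired) or the string ``"avg"``.
    """

    values: np.ndarray
    provenance: tuple[tuple[tuple[float, float], str], ...]

    def __post_init__(self) -> None:
        if self.values.shape != (8,):
            raise ValueError(f"expected 8 coordinates, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("coordinates must be finite")
        if len(self.provenance) != 8:
            raise ValueError("provenance must have 8 entries")


def _region_mask(spectrum: Spectrum, region: RegionSpec) -> np.ndarray:
    w = spectrum.wavenumbers
    mask = (w >= region.lo) & (w <= region.hi)
    if not mask.any():
        raise ValueError(
            f"region [{region.lo}, {region.hi}] contains no grid points "
            f"(grid spans [{w[0]}, {w[-1]}])")
    return mask


def _moving_average(a: np.ndarray, window: int = 5) -> np.ndarray:
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(a, pad, mode="edge")
    return np.convolve(padded, kernel, mode="valid")


def region_peaks(spectrum: Spectrum, region: RegionSpec,
                 smooth: bool = False) -> list[tuple[float, float]]:
    """The ``n_peaks`` highest local maxima in a window.

    Local maxima are interior grid points of the window that strictly exceed
    both neighbours. With ``smooth`` set, detection and reported heights use
    a 5-point moving average of the window (edge-padded), which suppresses
    the upward bias that picking a maximum over noisy points would otherwise
    add. Candidates are ranked by absorbance descending, ties broken toward
    lower wavenumber. If the window holds fewer local maxima than requested,
    the window's global maximum pads the list (marked by the standardizer's
    provenance).
    """
    if region.mode != "peak":
        raise ValueError("region_peaks requires a peak-mode region")
    mask = _region_mask(spectrum, region)
    idx = np.flatnonzero(mask)
    w = spectrum.wavenumbers[idx]
    a = _moving_average(spectrum.absorbances[idx]) if smooth \
        else spectrum.absorbances[idx]

    interior = np.arange(1, len(idx) - 1)
    if interior.size:
        is_max = (a[interior] > a[interior - 1]) & (a[interior] > a[interior + 1])
        candidates = interior[is_max]
    else:
        candidates = np.array([], dtype=int)

    # rank by height desc, tie -> lower wavenumber (stable sort on -height)
    order = np.argsort(-a[candidates], kind="stable")
    ranked = candidates[order].tolist()

    peaks = [(float(w[i]), float(a[i])) for i in ranked[: region.n_peaks]]
    while len(peaks) < region.n_peaks:  # global-max fallback
        g = int(np.argmax(a))
        peaks.append((float(w[g]), float(a[g])))
    return peaks


def region_average(spectrum: Spectrum, region: RegionSpec) -> float:
    """Arithmetic mean absorbance over the closed window ``[lo, hi]``."""
    if region.mode != "average":
        raise ValueError("region_average requires an average-mode region")
    mask = _region_mask(spectrum, region)
    return float(spectrum.absorbances[mask].mean())


def standardize(spectrum: Spectrum,
                regions: tuple[RegionSpec, ...] = DEFAULT_REGIONS,
                smooth: bool = False) -> SpectralCoordinates:
    """Reduce a spectrum to its 8 standardized coordinates.

    Coordinates are ordered by ascending region ``lo``, then ascending peak
    wavenumber within a region; the region layout must yield exactly 8.
    """
    total = sum(r.n_peaks if r.mode == "peak" else 1 for r in regions)
    if total != 8:
        raise ConfigError(
            f"region profile yields {total} coordinates, expected 8")
    values: list[float] = []
    prov: list[tuple[tuple[float, float], str]] = []
    for region in sorted(regions, key=lambda r: r.lo):
        key = (region.lo, region.hi)
        if region.mode == "average":
            values.append(region_average(spectrum, region))
            prov.append((key, "avg"))
        else:
            peaks = region_peaks(spectrum, region, smooth=smooth)
            seen: set[tuple[float, float]] = set()
            for wn, height in sorted(peaks):
                fallback = "*" if (wn, height) in seen else ""
                seen.add((wn, height))
                values.append(height)
                prov.append((key, f"{wn:.4f}{fallback}"))
    return SpectralCoordinates(np.asarray(values), tuple(prov))
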