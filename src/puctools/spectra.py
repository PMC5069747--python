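"""Peak detection in whole-cell absorption spectra and LH complex inference.

Intact-cell near-infrared absorption reveals which LH complexes a culture
is making: LH2 absorbs at ~800 and ~860 nm in whole cells (the isolated
complex's red band sits at 850 nm; both are recorded in the catalog), LH3
at ~800 and ~820 nm, LH4 at ~800 nm only, LH2' at ~800 and ~840 nm, and the
LH1 core at ~875 nm.  Peaks are local maxima of a moving-average-smoothed
trace above a prominence threshold; inference reports, per complex, how
many of its diagnostic bands are matched within a wavelength tolerance.
The output is consistency evidence, never a unique deconvolution: an
800-nm-only spectrum is consistent with LH4 but also with the 800-nm band
of any complex whose second band is masked, and the inference flags that
ambiguity instead of resolving it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

#: diagnostic whole-cell absorption bands (nm) per complex
BAND_CATALOG: dict[str, tuple[float, ...]] = {
    "LH2": (800.0, 860.0),
    "LH3": (800.0, 820.0),
    "LH4": (800.0,),
    "LH1": (875.0,),
    "LH2prime": (800.0, 840.0),
}

#: the isolated LH2 complex's red band; whole cells show it near 860 nm
LH2_RED_BAND_ISOLATED_NM = 850.0

DEFAULT_TOLERANCE_NM = 8.0
DEFAULT_SMOOTHING_WINDOW = 5
LH_CALL_RANGE_NM = (750.0, 900.0)
MIN_POINTS = 50


@dataclass
class Spectrum:
    """A whole-cell absorption trace on a strictly increasing nm grid."""

    wavelengths: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavelengths.shape != self.absorbance.shape:
            raise ValueError("wavelength and absorbance vectors differ in length")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")

    def covers_lh_range(self) -> bool:
        lo, hi = LH_CALL_RANGE_NM
        return (len(self.wavelengths) >= MIN_POINTS
                and self.wavelengths[0] <= lo and self.wavelengths[-1] >= hi)


@dataclass
class ComplexEvidence:
    complex: str
    diagnostic_bands: tuple[float, ...]
    matched_bands: list[float] = field(default_factory=list)
    matched_peaks: list[float] = field(default_factory=list)

    @property
    def n_matched(self) -> int:
        return len(self.matched_bands)

    @property
    def n_total(self) -> int:
        return len(self.diagnostic_bands)

    @property
    def fully_supported(self) -> bool:
        return self.n_matched == self.n_total

    ambiguous: bool = False


def moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge shrinkage (window must be odd)."""
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    if window > len(values):
        raise ValueError("smoothing window larger than the trace")
    half = window // 2
    padded = np.pad(values, half, mode="edge")
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")


def detect_peaks(
    spectrum: Spectrum,
    smoothing_window: int = DEFAULT_SMOOTHING_WINDOW,
    min_prominence: float = 0.02,
    refine: bool = True,
) -> list[float]:
    """Wavelengths (nm) of local maxima of the smoothed trace.

    Prominence is measured on the smoothed trace in absorbance units.
    With *refine* each maximum is relocated to the vertex of a parabola
    fitted over +-4 grid points, which stabilizes the position of broad
    bands whose tops are nearly flat relative to the noise.
    """
    smooth = moving_average(spectrum.absorbance, smoothing_window)
    idx, _ = find_peaks(smooth, prominence=min_prominence)
    wl = spectrum.wavelengths
    peaks: list[float] = []
    for i in idx:
        if not refine:
            peaks.append(float(wl[i]))
            continue
        lo, hi = max(0, i - 4), min(len(smooth), i + 5)
        coeffs = np.polyfit(wl[lo:hi], smooth[lo:hi], 2)
        if coeffs[0] < 0:
            vertex = -coeffs[1] / (2 * coeffs[0])
            if wl[lo] <= vertex <= wl[hi - 1]:
                peaks.append(float(vertex))
                continue
        peaks.append(float(wl[i]))
    return peaks


def infer_complexes(
    peaks: list[float],
    catalog: dict[str, tuple[float, ...]] | None = None,
    tolerance_nm: float = DEFAULT_TOLERANCE_NM,
) -> dict[str, ComplexEvidence]:
    """Evidence for each LH complex given detected peak wavelengths.

    A band is matched when some peak lies within *tolerance_nm* of it.
    A fully supported complex is flagged ambiguous when its diagnostic
    band set is a strict subset of another complex's that is itself fully
    supported (e.g. with LH2 present, LH4's lone 800-nm band cannot be
    told apart from LH2's own 800-nm band).
    """
    catalog = catalog or BAND_CATALOG
    peaks = sorted(peaks)
    evidence: dict[str, ComplexEvidence] = {}
    for name, bands in catalog.items():
        ev = ComplexEvidence(name, tuple(bands))
        for band in bands:
            matches = [p for p in peaks if abs(p - band) <= tolerance_nm]
            if matches:
                ev.matched_bands.append(band)
                ev.matched_peaks.append(min(matches, key=lambda p: abs(p - band)))
        evidence[name] = ev
    for name, ev in evidence.items():
        if not ev.fully_supported:
            continue
        mine = set(ev.diagnostic_bands)
        for other, obands in catalog.items():
            if (other != name and mine < set(obands)
                    and evidence[other].fully_supported):
                ev.ambiguous = True
                break
    return evidence


def unambiguously_supported(evidence: dict[str, ComplexEvidence]) -> list[str]:
    """Fully supported complexes whose evidence is not explainable as a
    subset of another fully supported complex's bands."""
    return sorted(n for n, ev in evidence.items()
                  if ev.fully_supported and not ev.ambiguous)


def supported_complexes(evidence: dict[str, ComplexEvidence]) -> list[str]:
    """Names of complexes whose every diagnostic band is matched."""
    return sorted(n for n, ev in evidence.items() if ev.fully_supported)


def evidence_report(evidence: dict[str, ComplexEvidence]) -> list[dict]:
    """Flat records for the JSON/TSV evidence report."""
    return [
        dict(
            complex=ev.complex,
            diagnostic_bands=list(ev.diagnostic_bands),
            matched_bands=ev.matched_bands,
            matched_peaks=ev.matched_peaks,
            matched=ev.n_matched,
            total=ev.n_total,
            fully_supported=ev.fully_supported,
            ambiguous=ev.ambiguous,
        )
        for ev in evidence.values()
    ]
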