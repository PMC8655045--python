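"""ZooMS spectral quality scoring and marker-based taxonomic calls.

Scores MALDI-TOF peptide-mass-fingerprint spectra for the
signal-to-noise ratio of collagen type I peptide markers and derives a
taxonomic call as the intersection of the taxa consistent with every
marker found.  Peaks matching known contaminant masses (e.g. human
keratin) are excluded before calling.  Absent markers can only broaden
a call, never narrow it — this is why spectra lacking the high-mass
markers yield Bos/Bison/Ovibos rather than Bos/Bison.

The shipped marker table is a small synthetic stand-in: only the
1208 m/z mass of COL1α2 978-990 is anchored in the study; the other
masses are placeholder configuration values to be replaced from the
marker literature for real analyses.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "Spectrum",
    "PeptideMarker",
    "TaxonCall",
    "preprocess_spectrum",
    "snr_at_markers",
    "assign_taxon",
    "load_marker_db",
    "default_marker_db",
    "DEFAULT_CONTAMINANT_MASSES",
]

# placeholder keratin-derived contaminant masses (configuration values)
DEFAULT_CONTAMINANT_MASSES = (1179.6, 1475.7, 2383.9)


@dataclass
class Spectrum:
    """Profile or centroided MALDI spectrum (m/z ascending, Da)."""

    mz: np.ndarray
    intensity: np.ndarray
    label: str = ""
    noise: float | None = None  # set by preprocess_spectrum
    baseline_removed: bool = False

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape or self.mz.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays of equal length")
        if np.any(np.diff(self.mz) <= 0):
            raise ValueError("mz values must be strictly increasing")


@dataclass(frozen=True)
class PeptideMarker:
    """A collagen peptide marker: name, mass, consistent taxa, mass class."""

    name: str
    mz: float
    taxa: frozenset[str]
    mass_class: str = "low"  # {low, high}

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("marker m/z must be positive")
        if not self.taxa:
            raise ValueError("marker taxa set must be non-empty")


@dataclass
class TaxonCall:
    taxa: frozenset[str]
    markers_found: list[PeptideMarker]
    markers_absent: list[PeptideMarker]
    snr: dict[str, float] = field(default_factory=dict)


def _snip_baseline(intensity: np.ndarray, half_window: int) -> np.ndarray:
    """SNIP-style baseline: iterative clipping with shrinking windows."""
    y = np.log1p(np.log1p(np.sqrt(np.maximum(intensity, 0.0) + 1.0)))  # LLS transform
    base = y.copy()
    n = y.size
    for m in range(half_window, 0, -1):
        left = np.empty_like(base)
        right = np.empty_like(base)
        left[m:] = base[:-m]
        left[:m] = base[0]
        right[:-m] = base[m:]
        right[-m:] = base[-1]
        base = np.minimum(base, 0.5 * (left + right))
    return (np.expm1(np.expm1(base))) ** 2 - 1.0  # invert LLS


def preprocess_spectrum(spectrum: Spectrum, half_window: int = 40) -> Spectrum:
    """Baseline-correct a spectrum and estimate its noise level.

    The baseline is estimated by SNIP-style iterative clipping and
    subtracted; the noise level is the scaled median absolute deviation
    of the corrected intensities in signal-free regions (points within
    5 MAD of zero).  Idempotent within tolerance.
    """
    if spectrum.mz.size < 100:
        raise ValueError("spectrum too short to preprocess (need >= 100 points)")
    baseline = _snip_baseline(spectrum.intensity, half_window)
    corrected = spectrum.intensity - baseline
    mad = 1.4826 * np.median(np.abs(corrected - np.median(corrected)))
    if mad > 0:
        quiet = np.abs(corrected) < 5 * mad
        if quiet.sum() >= 100:
            c = corrected[quiet]
            mad = 1.4826 * np.median(np.abs(c - np.median(c)))
    noise = float(mad) if mad > 0 else float(np.std(corrected) or 1.0)
    return Spectrum(
        mz=spectrum.mz.copy(), intensity=corrected, label=spectrum.label,
        noise=noise, baseline_removed=True,
    )


def snr_at_markers(
    spectrum: Spectrum,
    markers: list[PeptideMarker],
    tol: float = 0.5,
    presence_threshold: float = 6.0,
) -> dict[str, dict]:
    """Per-marker signal-to-noise: max corrected intensity within ±tol / noise.

    A marker is reported present when its S/N reaches
    ``presence_threshold`` (default 6).  Invariant under multiplicative
    intensity rescaling and under any baseline the preprocessor removes.
    """
    spec = spectrum if spectrum.baseline_removed else preprocess_spectrum(spectrum)
    assert spec.noise is not None
    out = {}
    for m in markers:
        lo = np.searchsorted(spec.mz, m.mz - tol)
        hi = np.searchsorted(spec.mz, m.mz + tol, side="right")
        if hi <= lo:
            snr = 0.0
        else:
            snr = float(np.max(spec.intensity[lo:hi]) / spec.noise)
        out[m.name] = {"snr": snr, "present": snr >= presence_threshold, "mz": m.mz}
    return out


def assign_taxon(
    spectrum: Spectrum,
    marker_db: list[PeptideMarker],
    contaminant_masses: tuple[float, ...] | list[float] = DEFAULT_CONTAMINANT_MASSES,
    tol: float = 0.5,
    presence_threshold: float = 6.0,
) -> TaxonCall:
    """Taxonomic call from the markers present in a spectrum.

    Markers whose mass collides with a known contaminant mass (within
    ±tol) are excluded first.  The call is the intersection of the taxa
    sets of all markers found; an empty intersection (or no markers
    found) means no identification.
    """
    if not marker_db:
        raise ValueError("marker database is empty")
    usable = [
        m for m in marker_db
        if not any(abs(m.mz - c) <= tol for c in contaminant_masses)
    ]
    scores = snr_at_markers(spectrum, usable, tol=tol, presence_threshold=presence_threshold)
    found = [m for m in usable if scores[m.name]["present"]]
    absent = [m for m in usable if not scores[m.name]["present"]]
    if found:
        taxa = frozenset.intersection(*[m.taxa for m in found])
    else:
        taxa = frozenset()
    return TaxonCall(
        taxa=taxa, markers_found=found, markers_absent=absent,
        snr={k: v["snr"] for k, v in scores.items()},
    )


def load_marker_db(path: str | Path) -> list[PeptideMarker]:
    """Read a marker table CSV with columns name, mz, taxa (';'-separated), mass_class."""
    markers = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            markers.append(
                PeptideMarker(
                    name=row["name"],
                    mz=float(row["mz"]),
                    taxa=frozenset(t.strip() for t in row["taxa"].split(";") if t.strip()),
                    mass_class=row.get("mass_class", "low"),
                )
            )
    return markers


def default_marker_db() -> list[PeptideMarker]:
    """The bundled toy bovid marker table (synthetic stand-in)."""
    ref = resources.files("eemtopo").joinpath("data/markers.csv")
    with resources.as_file(ref) as path:
        return load_marker_db(path)
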