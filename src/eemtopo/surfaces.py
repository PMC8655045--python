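"""Domain types for gridded surface metrology and study metadata.

A surface scan is a rectangular grid of heights in micrometres with a
validity mask marking measured points.  The grid is row-major with (0, 0)
at the top-left corner; x increases along columns, y increases downward
along rows.  All heights and lateral spacings are carried internally in
micrometres; unit conversion happens only at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np


class Area(str, Enum):
    """Region of interest on the bone: over a cut mark, or unmodified."""

    CUT = "cut"
    CONTROL = "control"


class Phase(str, Enum):
    """Sampling phase relative to the eraser extraction event."""

    BEFORE = "before"
    AFTER = "after"


@dataclass(frozen=True)
class ScanMetadata:
    """Identity of one confocal scan within a study.

    (specimen, area, location, phase) must be unique within a study:
    each specimen carries two regions of interest, each measured at five
    locations, before and after eraser sampling.
    """

    specimen: str
    area: Area
    location: int
    phase: Phase

    def __post_init__(self) -> None:
        object.__setattr__(self, "area", Area(self.area))
        object.__setattr__(self, "phase", Phase(self.phase))
        if self.location < 1:
            raise ValueError(f"location must be >= 1, got {self.location}")

    @property
    def key(self) -> tuple[str, str, int, str]:
        return (self.specimen, self.area.value, self.location, self.phase.value)

    @property
    def pair_key(self) -> tuple[str, str, int]:
        """Key shared by the before/after scans of one measurement location."""
        return (self.specimen, self.area.value, self.location)


@dataclass
class HeightMap:
    """A rectangular grid of surface heights (µm) with a validity mask.

    Parameters
    ----------
    heights : (ny, nx) float array
        Surface heights in µm.  Values at non-measured points are ignored
        (and may be NaN); they never enter numeric reductions.
    dx, dy : float
        Lateral sample spacing in µm, strictly positive.
    valid : (ny, nx) bool array, optional
        Mask of measured points.  Defaults to all-true.
    origin_offset : (float, float)
        Physical (x, y) position of the grid corner in µm.
    """

    heights: np.ndarray
    dx: float
    dy: float
    valid: np.ndarray | None = None
    origin_offset: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise ValueError("heights must be a 2-D array")
        if not (self.dx > 0 and self.dy > 0):
            raise ValueError(f"spacing must be positive, got dx={self.dx}, dy={self.dy}")
        if self.valid is None:
            self.valid = np.ones(self.heights.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.heights.shape:
                raise ValueError("valid mask shape must match heights")
        if not np.all(np.isfinite(self.heights[self.valid])):
            raise ValueError("heights must be finite wherever valid")

    @property
    def nx(self) -> int:
        return self.heights.shape[1]

    @property
    def ny(self) -> int:
        return self.heights.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape

    @property
    def measured_fraction(self) -> float:
        """Fraction of grid points that were measured (compare to the 0.95 QC threshold)."""
        return float(self.valid.mean())

    @property
    def is_fully_valid(self) -> bool:
        return bool(self.valid.all())

    def measured_heights(self) -> np.ndarray:
        """1-D array of heights at measured points only."""
        return self.heights[self.valid]

    def copy(self) -> "HeightMap":
        return HeightMap(
            heights=self.heights.copy(),
            dx=self.dx,
            dy=self.dy,
            valid=self.valid.copy(),
            origin_offset=self.origin_offset,
        )

    def with_heights(self, heights: np.ndarray, valid: np.ndarray | None = None) -> "HeightMap":
        return HeightMap(
            heights=np.asarray(heights, dtype=float),
            dx=self.dx,
            dy=self.dy,
            valid=self.valid.copy() if valid is None else valid,
            origin_offset=self.origin_offset,
        )


@dataclass
class QCResult:
    accepted: bool
    measured_fraction: float
    threshold: float


def coverage_qc(surface: HeightMap, threshold: float = 0.95) -> QCResult:
    """Accept a scan iff its measured fraction reaches ``threshold``.

    The boundary is inclusive: a scan with exactly 95 % coverage passes a
    0.95 threshold.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    frac = surface.measured_fraction
    return QCResult(accepted=frac >= threshold, measured_fraction=frac, threshold=threshold)


@dataclass
class SurfacePair:
    """A before/after scan pair cropped to their common area.

    ``offset`` is the (x, y) shift in µm that maps the *after* grid onto
    the *before* grid; ``overlap_fraction`` is the proportion of the
    original field retained in the intersection.
    """

    before: HeightMap
    after: HeightMap
    offset: tuple[float, float]
    overlap_fraction: float

    def __post_init__(self) -> None:
        if self.before.shape != self.after.shape:
            raise ValueError("paired surfaces must share grid dimensions after extraction")
        if not (abs(self.before.dx - self.after.dx) < 1e-12 and abs(self.before.dy - self.after.dy) < 1e-12):
            raise ValueError("paired surfaces must share grid spacing")
        if not (0.0 <= self.overlap_fraction <= 1.0):
            raise ValueError("overlap_fraction must lie in [0, 1]")


@dataclass
class TextureRecord:
    """The four ISO 25178 texture parameters for one scan.

    Sa (µm) and Sha (µm²) are non-negative; Smrk1 is a material-ratio
    percentage in (0, 100); Spc (1/µm) is non-negative.  A parameter that
    is undefined for the scan (e.g. no closed hills for Sha) is stored as
    NaN and excluded from downstream modelling.
    """

    metadata: ScanMetadata
    Sa: float
    Spc: float
    Sha: float
    Smrk1: float
    settings_fingerprint: str = ""

    PARAMETERS = ("Sa", "Spc", "Sha", "Smrk1")

    def __post_init__(self) -> None:
        for name, value in (("Sa", self.Sa), ("Spc", self.Spc), ("Sha", self.Sha)):
            if np.isfinite(value) and value < 0:
                raise ValueError(f"{name} must be non-negative, got {value}")
        if np.isfinite(self.Smrk1) and not (0.0 < self.Smrk1 < 100.0):
            raise ValueError(f"Smrk1 must lie in (0, 100) %, got {self.Smrk1}")

    @property
    def values(self) -> np.ndarray:
        return np.array([self.Sa, self.Spc, self.Sha, self.Smrk1], dtype=float)

    @property
    def complete(self) -> bool:
        return bool(np.all(np.isfinite(self.values)))
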