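"""ISO 25178 areal surface-texture parameters.

Implements the four parameters used to quantify eraser-induced wear on
bone microtopography:

* ``Sa`` — arithmetic mean height deviation (µm); overall roughness.
* ``Smrk1`` — upper material ratio (%): the material ratio at which the
  Abbott–Firestone curve departs from the equivalent core line on the
  peak side.  A plateaued (worn-down) surface concentrates material near
  the top and raises Smrk1.
* ``Sha`` — mean closed hill area (µm²): average cross-sectional area,
  at a material-ratio cut height, of watershed hills whose cross-section
  does not touch the measurement boundary.
* ``Spc`` — arithmetic mean peak curvature (1/µm); pointedness of the
  surviving hill summits.

All operations expect an S-L (band-limited roughness) surface; Sa and
the material-ratio operations tolerate a validity mask, the feature
parameters require a fully measured grid.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import morphology, segmentation

from .surfaces import HeightMap, ScanMetadata, TextureRecord

__all__ = [
    "MaterialRatioCurve",
    "HillSegmentation",
    "TextureSettings",
    "sa",
    "material_ratio_curve",
    "smrk1",
    "segment_hills",
    "sha",
    "spc",
    "compute_texture_record",
]


def _heights(surface: HeightMap | np.ndarray) -> np.ndarray:
    if isinstance(surface, HeightMap):
        return surface.measured_heights()
    return np.asarray(surface, dtype=float).ravel()


def sa(surface: HeightMap | np.ndarray) -> float:
    """Arithmetic mean absolute height deviation from the mean plane (µm).

    With uniform grid spacing the area-weighted integral reduces to the
    plain average over measured points.
    """
    z = _heights(surface)
    if z.size == 0:
        raise ValueError("empty surface")
    return float(np.mean(np.abs(z - z.mean())))


@dataclass
class MaterialRatioCurve:
    """Abbott–Firestone curve: material ratio versus height level.

    ``heights`` descend from the surface maximum to the minimum; at each
    level, ``ratio`` is the percentage of the surface lying at or above
    that level, so it grows from 0 % to 100 % with depth.
    """

    heights: np.ndarray
    ratio: np.ndarray

    def ratio_at(self, height: float) -> float:
        """Material ratio (%) at an arbitrary height, by interpolation."""
        # heights descending -> reverse for np.interp
        return float(np.interp(height, self.heights[::-1], self.ratio[::-1]))

    def height_at(self, ratio: float) -> float:
        """Height (µm) at a given material ratio (%)."""
        return float(np.interp(ratio, self.ratio, self.heights))


def material_ratio_curve(surface: HeightMap | np.ndarray, n_levels: int = 1001) -> MaterialRatioCurve:
    """Empirical material ratio curve over ``n_levels`` height levels."""
    z = _heights(surface)
    if z.size == 0:
        raise ValueError("empty surface")
    zs = np.sort(z)  # ascending
    levels = np.linspace(zs[-1], zs[0], n_levels)  # descending heights
    # fraction of points >= level
    n_below = np.searchsorted(zs, levels, side="left")
    ratio = 100.0 * (z.size - n_below) / z.size
    ratio[0] = 0.0  # exactly zero material strictly above the global maximum
    ratio[-1] = 100.0
    return MaterialRatioCurve(heights=levels, ratio=ratio)


def _height_at_mr(z_sorted_desc: np.ndarray, mr: np.ndarray) -> np.ndarray:
    """Height at material ratio mr (%) from descending-sorted heights."""
    n = z_sorted_desc.size
    pos = np.clip(mr / 100.0 * (n - 1), 0, n - 1)
    lo = np.floor(pos).astype(int)
    hi = np.minimum(lo + 1, n - 1)
    w = pos - lo
    return z_sorted_desc[lo] * (1 - w) + z_sorted_desc[hi] * w


def smrk1(surface: HeightMap | np.ndarray, window: float = 40.0, mr_step: float = 0.1) -> float:
    """Upper material ratio Smr1 (%), Sk-family algorithm.

    A secant window of ``window`` % width slides along the material ratio
    curve; the position with the least-steep secant defines the
    equivalent core line.  Extending that line to 0 % material ratio
    gives the core-top height; Smr1 is the material ratio of the surface
    at that height.  Higher values mean a plateaued top surface.
    """
    z = _heights(surface)
    if z.size == 0:
        raise ValueError("empty surface")
    if np.ptp(z) == 0:
        raise ValueError("degenerate flat surface: material ratio curve has zero height range")
    z_desc = np.sort(z)[::-1]
    mr = np.arange(0.0, 100.0 + mr_step / 2, mr_step)
    zc = _height_at_mr(z_desc, mr)
    nwin = int(round(window / mr_step))
    # least-steep secant over the sliding window (curve is non-increasing)
    drop = zc[:-nwin] - zc[nwin:]
    i0 = int(np.argmin(drop))
    slope = -drop[i0] / window  # height per % material ratio (<= 0)
    z_top = zc[i0] - slope * mr[i0]  # equivalent line extended to mr = 0
    # material ratio of the surface at the core-top height
    smr1 = 100.0 * np.mean(z >= z_top)
    return float(smr1)


@dataclass
class HillSegmentation:
    """Watershed hill segmentation of a surface.

    ``labels`` partitions the grid into hills (catchment basins of the
    inverted surface, Wolf-pruned).  ``closed`` lists the hills whose
    cross-section at the cut height is non-empty and does not touch the
    grid boundary; ``areas`` maps hill id to that cross-sectional area in
    µm².  ``peaks`` holds the (row, col) summit of each hill.
    """

    labels: np.ndarray
    closed: list[int]
    areas: dict[int, float]
    peaks: dict[int, tuple[int, int]]
    cut_height: float


def _wolf_merge(z: np.ndarray, labels: np.ndarray, h: float) -> np.ndarray:
    """Merge watershed basins whose separating saddle is shallower than h.

    Persistence-style pruning: adjacent-basin saddles are visited from
    the highest down; whenever the lower of the two summits stands less
    than ``h`` above the saddle, the basins are merged (the summit of
    the union is the higher one).
    """
    n_lab = labels.max()
    peak = np.full(n_lab + 1, -np.inf)
    np.maximum.at(peak, labels.ravel(), z.ravel())
    # saddle height between adjacent basins: max over boundary pixel pairs
    saddles: dict[tuple[int, int], float] = {}
    for la, lb, za, zb in (
        (labels[:, :-1], labels[:, 1:], z[:, :-1], z[:, 1:]),
        (labels[:-1, :], labels[1:, :], z[:-1, :], z[1:, :]),
    ):
        diff = la != lb
        a = la[diff].ravel()
        b = lb[diff].ravel()
        s = np.minimum(za[diff].ravel(), zb[diff].ravel())
        lo = np.minimum(a, b)
        hi = np.maximum(a, b)
        for key_lo, key_hi, val in zip(lo, hi, s):
            key = (int(key_lo), int(key_hi))
            if val > saddles.get(key, -np.inf):
                saddles[key] = float(val)

    parent = np.arange(n_lab + 1)

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for (a, b), s in sorted(saddles.items(), key=lambda kv: -kv[1]):
        ra, rb = find(a), find(b)
        if ra == rb:
            continue
        if min(peak[ra], peak[rb]) - s < h:
            keep, drop = (ra, rb) if peak[ra] >= peak[rb] else (rb, ra)
            parent[drop] = keep
    roots = np.array([find(i) for i in range(n_lab + 1)])
    # compact relabel
    uniq = np.unique(roots[1:])
    remap = np.zeros(n_lab + 1, dtype=int)
    remap[uniq] = np.arange(1, uniq.size + 1)
    return remap[roots[labels]]


def segment_hills(
    surface: HeightMap,
    pruning_threshold: float = 5.0,
    cut_ratio: float = 10.0,
) -> HillSegmentation:
    """Segment the surface into hills by watershed on the inverted heights.

    Hills whose separating saddle is shallower than ``pruning_threshold``
    percent of the total height range are merged (Wolf pruning,
    implemented by h-maxima suppression of shallow summits before the
    watershed).  Hill cross-sections are evaluated at the height of the
    ``cut_ratio`` % material ratio; a hill is *closed* when that
    cross-section exists and contains no boundary pixel.
    """
    if not surface.is_fully_valid:
        raise ValueError("segment_hills requires a fully measured surface")
    z = surface.heights
    rng = np.ptp(z)
    if rng == 0:
        labels = np.ones(z.shape, dtype=int)
        return HillSegmentation(labels, [], {}, {1: (0, 0)}, cut_height=float(z.flat[0]))
    h = pruning_threshold / 100.0 * rng
    # seed basins at maxima surviving h-maxima suppression (fast first cut;
    # equal-height summits joined by a shallow saddle survive it and are
    # handled by the saddle merge below)
    if h > 0:
        summits = morphology.h_maxima(z, h)
    else:
        summits = morphology.local_maxima(z)
    markers, n_marks = ndimage.label(summits)
    if n_marks == 0:
        markers, n_marks = ndimage.label(morphology.local_maxima(z))
    labels = segmentation.watershed(-z, markers=markers)
    if h > 0 and n_marks > 1:
        labels = _wolf_merge(z, labels, h)

    curve_cut = _height_at_mr(np.sort(z.ravel())[::-1], np.array([cut_ratio]))[0]
    above = z >= curve_cut
    border = np.zeros(z.shape, dtype=bool)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True

    pixel_area = surface.dx * surface.dy
    closed: list[int] = []
    areas: dict[int, float] = {}
    peaks: dict[int, tuple[int, int]] = {}
    for hill_id in range(1, labels.max() + 1):
        in_hill = labels == hill_id
        if not in_hill.any():
            continue
        # summit of the hill
        idx = np.flatnonzero(in_hill.ravel())
        peak_flat = idx[np.argmax(z.ravel()[idx])]
        peaks[hill_id] = np.unravel_index(peak_flat, z.shape)
        cross = in_hill & above
        n_cross = int(cross.sum())
        if n_cross > 0:
            areas[hill_id] = n_cross * pixel_area
            if not (cross & border).any():
                closed.append(hill_id)
    return HillSegmentation(labels=labels, closed=closed, areas=areas, peaks=peaks, cut_height=float(curve_cut))


def sha(
    surface: HeightMap,
    pruning_threshold: float = 5.0,
    cut_ratio: float = 10.0,
    segmentation_result: HillSegmentation | None = None,
) -> float:
    """Mean closed hill area (µm²) at the material-ratio cut height.

    Returns NaN (the undefined-result marker) when no closed hill exists;
    downstream modelling excludes such records.
    """
    seg = segmentation_result or segment_hills(surface, pruning_threshold, cut_ratio)
    if not seg.closed:
        return float("nan")
    return float(np.mean([seg.areas[i] for i in seg.closed]))


def spc(
    surface: HeightMap,
    pruning_threshold: float = 5.0,
    segmentation_result: HillSegmentation | None = None,
) -> float:
    """Arithmetic mean peak curvature (1/µm).

    Spc = -(1/2n) * sum over significant peaks of the finite-difference
    Laplacian of the heights; peaks on the grid boundary are excluded.
    Returns NaN when no interior peak survives pruning.
    """
    seg = segmentation_result or segment_hills(surface, pruning_threshold)
    z = surface.heights
    ny, nx = z.shape
    curvatures = []
    for hill_id, (i, j) in seg.peaks.items():
        if i == 0 or j == 0 or i == ny - 1 or j == nx - 1:
            continue
        d2x = (z[i, j + 1] - 2 * z[i, j] + z[i, j - 1]) / surface.dx**2
        d2y = (z[i + 1, j] - 2 * z[i, j] + z[i - 1, j]) / surface.dy**2
        curvatures.append(d2x + d2y)
    if not curvatures:
        return float("nan")
    return float(-0.5 * np.mean(curvatures))


@dataclass(frozen=True)
class TextureSettings:
    """Settings shared by the feature-parameter computations."""

    pruning_threshold: float = 5.0  # Wolf pruning, % of height range
    sha_cut_ratio: float = 10.0  # material ratio (%) of the Sha cut height
    smrk1_window: float = 40.0  # secant window width, % material ratio

    def fingerprint(self) -> str:
        payload = json.dumps(
            {
                "pruning_threshold": self.pruning_threshold,
                "sha_cut_ratio": self.sha_cut_ratio,
                "smrk1_window": self.smrk1_window,
            },
            sort_keys=True,
        )
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


def compute_texture_record(
    surface: HeightMap,
    metadata: ScanMetadata,
    settings: TextureSettings | None = None,
) -> TextureRecord:
    """All four ISO 25178 parameters of an S-L surface, shared segmentation.

    Parameters that are undefined for the scan (flat surface, no closed
    hills, no interior peaks) are recorded as NaN, never as zeros.
    """
    settings = settings or TextureSettings()
    sa_val = sa(surface)
    try:
        smrk1_val = smrk1(surface, window=settings.smrk1_window)
    except ValueError:
        smrk1_val = float("nan")
    if surface.is_fully_valid and np.ptp(surface.heights) > 0:
        seg = segment_hills(surface, settings.pruning_threshold, settings.sha_cut_ratio)
        sha_val = sha(surface, segmentation_result=seg)
        spc_val = spc(surface, segmentation_result=seg)
    else:
        sha_val = float("nan")
        spc_val = float("nan")
    return TextureRecord(
        metadata=metadata,
        Sa=sa_val,
        Spc=spc_val,
        Sha=sha_val,
        Smrk1=smrk1_val,
        settings_fingerprint=settings.fingerprint(),
    )
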