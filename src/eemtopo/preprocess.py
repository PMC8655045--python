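"""Scan pre-processing: leveling, outlier removal, pair alignment, S-/L-filtering.

The chain mirrors standard confocal surface-texture workflows: scans are
leveled by least-squares plane subtraction, isolated spikes are removed
and non-measured points filled, before/after scans of the same spot are
registered and cropped to their common area, and the band of interest is
isolated with a robust Gaussian regression filter applied twice — a
small-scale S-filter (noise suppression, keep the smooth part) and a
larger-scale L-filter (form removal, keep the residual), yielding the
S-L surface on which the ISO 25178 parameters are computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve
from skimage.restoration import inpaint_biharmonic

from .surfaces import HeightMap, SurfacePair

__all__ = [
    "level_ls_plane",
    "remove_outliers_fill",
    "align_pair",
    "PairRejection",
    "robust_gaussian_filter",
    "make_sl_surface",
]


def level_ls_plane(surface: HeightMap) -> HeightMap:
    """Subtract the least-squares plane fitted over the measured points.

    Requires at least three non-collinear measured points; the validity
    mask is unchanged.  Idempotent, and invariant to adding any plane.
    """
    iy, ix = np.nonzero(surface.valid)
    if iy.size < 3:
        raise ValueError("plane leveling needs >= 3 measured points")
    x = ix * surface.dx
    y = iy * surface.dy
    design = np.column_stack([np.ones(x.size), x, y])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("plane leveling needs non-collinear support")
    z = surface.heights[iy, ix]
    coef, *_ = np.linalg.lstsq(design, z, rcond=None)
    xx = np.arange(surface.nx) * surface.dx
    yy = np.arange(surface.ny) * surface.dy
    plane = coef[0] + coef[1] * xx[None, :] + coef[2] * yy[:, None]
    out = surface.heights - plane
    out[~surface.valid] = np.nan
    return surface.with_heights(out)


_STRENGTH_K = {"soft": 5.0, "normal": 3.0, "strong": 2.0}


def remove_outliers_fill(surface: HeightMap, strength: str = "normal") -> HeightMap:
    """Remove isolated spikes and fill all non-measured points.

    A measured point is flagged when it deviates from the median of its
    3x3 neighborhood by more than k * MAD of those deviations (k = 3 for
    ``"normal"`` strength).  Only *isolated* flags — no flagged point in
    the 8-neighborhood — are invalidated, matching the "isolated outlier
    removal" rule: adjacent spikes are retained as real topography.
    Invalid points are then filled by biharmonic inpainting, so the
    returned surface is fully measured.
    """
    if strength not in _STRENGTH_K:
        raise ValueError(f"unknown strength {strength!r}; expected one of {sorted(_STRENGTH_K)}")
    k = _STRENGTH_K[strength]
    z = surface.heights.copy()
    valid = surface.valid.copy()

    work = z.copy()
    if not valid.all():
        work[~valid] = np.nanmedian(z[valid])
    from scipy.ndimage import median_filter

    med = median_filter(work, size=3, mode="reflect")
    dev = work - med
    dev_valid = dev[valid]
    # robust scale of the neighborhood deviations; on locally monotone
    # surfaces the centre often *is* its neighborhood median, so most
    # deviations are exactly zero and the plain MAD degenerates
    scale = 1.4826 * np.median(np.abs(dev_valid - np.median(dev_valid)))
    nonzero = dev_valid[dev_valid != 0]
    if scale == 0 and nonzero.size:
        # e.g. spikes on a plane: the typical nonzero deviation sets the scale
        scale = 1.4826 * np.median(np.abs(nonzero))
    if scale > 0:
        flagged = valid & (np.abs(dev) > k * scale)
    else:
        flagged = np.zeros_like(valid)
    if flagged.any():
        # isolated flags only: no flagged 8-neighbor
        has_flagged_neighbor = (
            fftconvolve(flagged.astype(float), np.ones((3, 3)), mode="same") > 1.5
        )
        isolated = flagged & ~has_flagged_neighbor
        valid = valid & ~isolated
        z[~valid] = np.nan

    if valid.all():
        return surface.with_heights(z, valid=valid)
    filled = inpaint_biharmonic(np.nan_to_num(z, nan=0.0), ~valid)
    return HeightMap(
        filled, dx=surface.dx, dy=surface.dy,
        valid=np.ones_like(valid), origin_offset=surface.origin_offset,
    )


@dataclass
class PairRejection:
    """Result marker for a before/after pair rejected for minimal overlap."""

    offset: tuple[float, float]
    overlap_fraction: float
    min_overlap: float


def _estimate_shift(before: np.ndarray, after: np.ndarray) -> tuple[float, float, int, int]:
    """Integer-pixel cross-correlation shift with parabolic sub-pixel refinement.

    Returns (sy_sub, sx_sub, sy_int, sx_int) such that
    after[i, j] ~ before[i - sy, j - sx].
    """
    b = before - before.mean()
    a = after - after.mean()
    cc = fftconvolve(a, b[::-1, ::-1], mode="full")
    ny, nx = before.shape
    py, px = np.unravel_index(np.argmax(cc), cc.shape)
    sy, sx = py - (ny - 1), px - (nx - 1)

    def _parab(c_m, c_0, c_p):
        denom = c_m - 2 * c_0 + c_p
        if denom >= 0 or abs(denom) < 1e-300:
            return 0.0
        return float(0.5 * (c_m - c_p) / denom)

    dy = dx = 0.0
    if 0 < py < cc.shape[0] - 1:
        dy = _parab(cc[py - 1, px], cc[py, px], cc[py + 1, px])
    if 0 < px < cc.shape[1] - 1:
        dx = _parab(cc[py, px - 1], cc[py, px], cc[py, px + 1])
    return sy + dy, sx + dx, int(sy), int(sx)


def align_pair(
    before: HeightMap,
    after: HeightMap,
    offset: tuple[float, float] | None = None,
    min_overlap: float = 0.25,
) -> SurfacePair | PairRejection:
    """Register an after scan onto its before scan and crop to the intersection.

    ``offset`` is the known (x, y) shift in µm of the after content
    relative to the before content; when omitted it is estimated by
    integer-pixel normalized cross-correlation with parabolic sub-pixel
    refinement.  Cropping happens at integer pixels.  When the retained
    intersection is smaller than ``min_overlap`` of the field, the pair
    is rejected and a :class:`PairRejection` carrying the fraction is
    returned instead.
    """
    if before.shape != after.shape or before.dx != after.dx or before.dy != after.dy:
        raise ValueError("align_pair expects scans on identical grids")
    if not (before.is_fully_valid and after.is_fully_valid):
        raise ValueError("align_pair expects preprocessed (fully measured) surfaces")
    ny, nx = before.shape
    if offset is not None:
        sx_sub = offset[0] / before.dx
        sy_sub = offset[1] / before.dy
        sx_i, sy_i = int(round(sx_sub)), int(round(sy_sub))
    else:
        sy_sub, sx_sub, sy_i, sx_i = _estimate_shift(before.heights, after.heights)

    h = ny - abs(sy_i)
    w = nx - abs(sx_i)
    offset_um = (sx_sub * before.dx, sy_sub * before.dy)
    overlap = max(h, 0) * max(w, 0) / (ny * nx)
    if h <= 0 or w <= 0 or overlap < min_overlap:
        return PairRejection(offset=offset_um, overlap_fraction=max(overlap, 0.0), min_overlap=min_overlap)

    a0_row, a0_col = max(0, sy_i), max(0, sx_i)
    b0_row, b0_col = max(0, -sy_i), max(0, -sx_i)
    before_crop = before.heights[b0_row : b0_row + h, b0_col : b0_col + w]
    after_crop = after.heights[a0_row : a0_row + h, a0_col : a0_col + w]
    mk = lambda z: HeightMap(z.copy(), dx=before.dx, dy=before.dy)
    return SurfacePair(
        before=mk(before_crop), after=mk(after_crop),
        offset=offset_um, overlap_fraction=overlap,
    )


# --------------------------------------------------- robust Gaussian filter

# Gaussian weight scale for 50 % transmission at the nesting index with a
# second-order polynomial basis: the smoother's transfer function is
# T(k) = (1 + s^2 k^2 / 2) exp(-s^2 k^2 / 2); solving T = 1/2 at
# k = 2*pi/lambda_c gives s = sqrt(2 x*) / (2 pi) * lambda_c with
# (1 + x*) exp(-x*) = 1/2.
_X_STAR = 1.6783469900166608
_SIGMA_PER_NESTING = np.sqrt(2 * _X_STAR) / (2 * np.pi)
_TUKEY_C = 4.685


def _regression_kernels(sigma_x: float, sigma_y: float, dx: float, dy: float):
    """Gaussian-weighted monomial kernels for local quadratic regression."""
    rx = max(int(np.ceil(4 * sigma_x / dx)), 1)
    ry = max(int(np.ceil(4 * sigma_y / dy)), 1)
    ux = np.arange(-rx, rx + 1) * dx
    uy = np.arange(-ry, ry + 1) * dy
    gx = np.exp(-0.5 * (ux / sigma_x) ** 2)
    gy = np.exp(-0.5 * (uy / sigma_y) ** 2)
    g = gy[:, None] * gx[None, :]
    X, Y = np.meshgrid(ux, uy)
    # quadratic basis phi = (1, x, y, x^2, x*y, y^2)
    basis = [np.ones_like(X), X, Y, X * X, X * Y, Y * Y]
    return g, basis


def robust_gaussian_filter(
    surface: HeightMap,
    nesting_index: float,
    order: int = 2,
    robust: bool = True,
    max_iter: int = 20,
    rtol: float = 1e-6,
) -> tuple[HeightMap, HeightMap]:
    """Second-order robust Gaussian regression filter (ISO 16610-31 style).

    At every grid point a quadratic polynomial is fitted to the local
    neighborhood under a Gaussian weight whose scale is set so the
    smoother transmits 50 % of a sinusoid at the nesting index.  With
    ``robust=True`` the fit is iterated with Tukey-biweight reweighting
    of MAD-scaled residuals until the smooth part changes by less than
    ``rtol`` (relative to the height range) or ``max_iter`` passes, so
    spikes are down-weighted rather than smeared.  Regression moments are
    accumulated over the available support only, which renormalizes the
    kernel at the borders — no data is discarded.

    Returns ``(waviness, roughness)`` with waviness + roughness == input
    at every measured point.
    """
    if order != 2:
        raise ValueError("only the second-order polynomial basis is supported")
    if nesting_index < 2 * max(surface.dx, surface.dy):
        raise ValueError(
            f"nesting index {nesting_index} µm is below 2x the grid spacing "
            f"({surface.dx} x {surface.dy} µm); the kernel would be meaningless"
        )
    sigma = _SIGMA_PER_NESTING * nesting_index
    g, basis = _regression_kernels(sigma, sigma, surface.dx, surface.dy)
    # correlation kernels: correlate(im, k) == fftconvolve(im, k[::-1, ::-1])
    mom_kernels = []
    pairs = []
    for a in range(6):
        for b in range(a, 6):
            mom_kernels.append((g * basis[a] * basis[b])[::-1, ::-1])
            pairs.append((a, b))
    rhs_kernels = [(g * basis[a])[::-1, ::-1] for a in range(6)]

    z = surface.heights
    valid = surface.valid.astype(float)
    z0 = np.where(surface.valid, z, 0.0)
    scale_ref = np.ptp(z0[surface.valid == 1] if surface.valid.any() else z0) or 1.0

    w = valid.copy()
    waviness = None
    for iteration in range(max_iter if robust else 1):
        wz = w * z0
        moments = [fftconvolve(w, k, mode="same") for k in mom_kernels]
        rhs = [fftconvolve(wz, k, mode="same") for k in rhs_kernels]
        M = np.empty(z.shape + (6, 6))
        for (a, b), m in zip(pairs, moments):
            M[..., a, b] = m
            M[..., b, a] = m
        bvec = np.stack(rhs, axis=-1)
        # ridge jitter keeps border/degenerate systems solvable
        M += np.eye(6) * (1e-12 * np.abs(M[..., 0, 0])[..., None, None] + 1e-300)
        beta = np.linalg.solve(M, bvec[..., None])[..., 0]
        new_wav = beta[..., 0]
        if waviness is not None and np.max(np.abs(new_wav - waviness)) < rtol * scale_ref:
            waviness = new_wav
            break
        waviness = new_wav
        if not robust:
            break
        resid = np.where(surface.valid, z0 - waviness, 0.0)
        r_meas = resid[surface.valid]
        mad = np.median(np.abs(r_meas - np.median(r_meas)))
        s = 1.4826 * mad
        if s <= 0:
            break
        u = resid / (_TUKEY_C * s)
        w = valid * np.where(np.abs(u) < 1, (1 - u * u) ** 2, 0.0)
        if w.sum() < 0.5 * valid.sum():  # guard against weight collapse
            w = valid.copy()
            break

    roughness = np.where(surface.valid, z0 - waviness, np.nan)
    wav_map = surface.with_heights(np.where(surface.valid, waviness, np.nan))
    rough_map = surface.with_heights(roughness)
    return wav_map, rough_map


def make_sl_surface(
    surface: HeightMap,
    s_nesting: float = 0.8,
    l_nesting: float = 8.0,
    robust: bool = True,
) -> HeightMap:
    """Apply the S-filter then the L-filter, yielding the S-L surface.

    The S-filter (default nesting index 0.8 µm) suppresses measurement
    noise: its smooth part is kept.  The L-filter (default 0.008 mm =
    8 µm) removes residual form: its *residual* part is kept.  The result
    is the band-limited roughness surface on which all ISO 25178
    parameters are computed.
    """
    denoised, _ = robust_gaussian_filter(surface, s_nesting, robust=robust)
    _, sl = robust_gaussian_filter(denoised, l_nesting, robust=robust)
    # final re-level: the robust L-filter tracks the plateau of a skewed
    # surface, so its residual can carry a small offset
    z = sl.heights - np.nanmean(sl.heights[sl.valid])
    return sl.with_heights(np.where(sl.valid, z, np.nan))
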