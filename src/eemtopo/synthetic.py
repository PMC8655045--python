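"""Synthetic data with the statistical structure of an EEM sampling study.

Generates (i) bone-like surface scans, (ii) an eraser-wear operator,
(iii) whole before/after studies at the study design size, (iv) force
traces from the instrumented sampling stage, and (v) MALDI-TOF spectra
with collagen peptide markers — so every downstream analysis stage is
testable without any instrument data.

Surface model
-------------
Bone microtopography in the roughness band is modelled as a stationary
correlated random field with a *two-process* height distribution: a
tight Gaussian "plateau" mode (the load-bearing lamellar surface),
an exponential upper tail of asperities/residue peaks, and an
exponential lower tail of pores and valleys.  The field is produced by
spectral synthesis of a squared-exponential Gaussian field, band-limited
to the S-L analysis band, then transformed to the two-process marginal
through its quantile function (a Gaussian copula), and rescaled so the
realized Sa matches the target.  The two-process shape is what gives
realistic upper-material-ratio (Smrk1) values around 20 % with small
scan-to-scan spread — a purely Gaussian marginal pins Smrk1 near 10 %
and cannot reproduce the response of the parameter to surface wear.

Eraser wear is modelled as (a) soft truncation of the asperity tail
above a material-ratio cut, (b) *polish* of the plateau band (shrinking
its micro-relief toward its centre — the mechanism that raises Smrk1),
(c) shallow parallel micro-striations along the eraser stroke direction,
and (d) i.i.d. remeasurement noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import norm

from .iso25178 import TextureSettings, compute_texture_record, sa as _sa
from .surfaces import Area, HeightMap, Phase, ScanMetadata, TextureRecord

__all__ = [
    "TwoProcessMarginal",
    "CutmarkParams",
    "ResidueParams",
    "SurfaceGenParams",
    "StriationParams",
    "WearParams",
    "StudyGenParams",
    "generate_surface",
    "apply_eem_wear",
    "generate_study",
    "generate_force_trace",
    "generate_spectrum",
]

# 50 % transmission constant of the second-order Gaussian regression filter,
# reused here so generated surfaces are band-limited to the analysis band.
_X_STAR = 1.6783469900166608
_SIGMA_PER_NESTING = math.sqrt(2 * _X_STAR) / (2 * math.pi)


@dataclass(frozen=True)
class TwoProcessMarginal:
    """Two-process height marginal: plateau core + peak and valley tails.

    ``quantile(p)`` maps a uniform probability to a height (µm, before Sa
    rescaling): a Gaussian core of scale ``s_core`` plus exponential
    tails of scale ``tau_peak`` above the upper ``p_peak`` fraction and
    ``tau_valley`` below the lower ``p_valley`` fraction.
    """

    s_core: float = 0.10
    tau_peak: float = 0.5
    tau_valley: float = 0.8
    p_peak: float = 0.20
    p_valley: float = 0.35

    def quantile(self, p: np.ndarray) -> np.ndarray:
        p = np.clip(p, 1e-12, 1 - 1e-12)
        z = self.s_core * norm.ppf(p)
        z = z + self.tau_peak * np.maximum(0.0, np.log(self.p_peak / (1 - p)))
        z = z - self.tau_valley * np.maximum(0.0, np.log(self.p_valley / p))
        return z


@dataclass(frozen=True)
class CutmarkParams:
    """V-profile cut marks superimposed on the surface."""

    depth: float = 2.0  # µm
    width: float = 12.0  # µm
    orientation_deg: float = 90.0
    count: int = 1


@dataclass(frozen=True)
class ResidueParams:
    """Raised sediment/residue blobs on the surface."""

    count: int = 3
    radius: float = 3.0  # µm
    height: float = 1.0  # µm


@dataclass(frozen=True)
class SurfaceGenParams:
    nx: int = 160
    ny: int = 160
    dx: float = 0.4  # µm
    dy: float = 0.4  # µm
    target_Sa: float = 0.60  # µm
    correlation_length: float = 1.5  # µm
    band_limit: float = 8.0  # µm; large-scale cut matching the L-filter
    marginal: TwoProcessMarginal = field(default_factory=TwoProcessMarginal)
    cutmark: CutmarkParams | None = None
    residues: ResidueParams | None = None
    dropout_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.target_Sa <= 0:
            raise ValueError("target_Sa must be positive")
        if not (0.0 <= self.dropout_fraction <= 0.05):
            raise ValueError("dropout_fraction outside [0, 0.05]: generated scans must pass the 95 % QC")


def generate_surface(params: SurfaceGenParams, seed: int | np.random.SeedSequence) -> HeightMap:
    """Generate one synthetic scan.

    The realized Sa of the full surface (before dropout masking) is
    rescaled exactly to ``target_Sa``; cut marks and residues are then
    superimposed, and ``dropout_fraction`` of points is marked
    non-measured.
    """
    p = params
    if min(p.nx * p.dx, p.ny * p.dy) < 5 * p.correlation_length:
        raise ValueError(
            "grid too small: need at least 5 correlation lengths per axis "
            f"({p.nx * p.dx:.1f} x {p.ny * p.dy:.1f} µm vs correlation length {p.correlation_length} µm)"
        )
    rng = np.random.default_rng(seed)
    noise = rng.normal(size=(p.ny, p.nx))
    kx = np.fft.fftfreq(p.nx, d=p.dx) * 2 * np.pi
    ky = np.fft.fftfreq(p.ny, d=p.dy) * 2 * np.pi
    KX, KY = np.meshgrid(kx, ky)
    k2 = KX**2 + KY**2
    amp = np.exp(-(p.correlation_length**2) * k2 / 4)  # squared-exponential correlation
    if p.band_limit and p.band_limit > 0:
        s = _SIGMA_PER_NESTING * p.band_limit
        t_low = (1 + s * s * k2 / 2) * np.exp(-s * s * k2 / 2)
        amp = amp * np.sqrt(np.maximum(0.0, 1.0 - t_low))  # remove form/waviness scales
    g = np.real(np.fft.ifft2(np.fft.fft2(noise) * amp))
    g = (g - g.mean()) / g.std()
    z = p.marginal.quantile(norm.cdf(g))
    z = z - z.mean()
    z = z * (p.target_Sa / _sa(z))

    x = np.arange(p.nx) * p.dx
    y = np.arange(p.ny) * p.dy
    X, Y = np.meshgrid(x, y)
    if p.cutmark is not None and p.cutmark.count > 0:
        cm = p.cutmark
        theta = math.radians(cm.orientation_deg)
        nvec = (-math.sin(theta), math.cos(theta))  # normal to the mark direction
        for _ in range(cm.count):
            cx = rng.uniform(0.2, 0.8) * p.nx * p.dx
            cy = rng.uniform(0.2, 0.8) * p.ny * p.dy
            dist = np.abs((X - cx) * nvec[0] + (Y - cy) * nvec[1])
            z = z - cm.depth * np.maximum(0.0, 1.0 - dist / (cm.width / 2))
    if p.residues is not None and p.residues.count > 0:
        rs = p.residues
        for _ in range(rs.count):
            cx = rng.uniform(0, p.nx * p.dx)
            cy = rng.uniform(0, p.ny * p.dy)
            r2 = (X - cx) ** 2 + (Y - cy) ** 2
            z = z + rs.height * np.exp(-r2 / (2 * (rs.radius / 2) ** 2))

    valid = np.ones(z.shape, dtype=bool)
    if p.dropout_fraction > 0:
        drop = rng.random(z.shape) < p.dropout_fraction
        valid &= ~drop
        z = np.where(valid, z, np.nan)
    return HeightMap(z, dx=p.dx, dy=p.dy, valid=valid)


@dataclass(frozen=True)
class StriationParams:
    """Parallel micro-striations along the eraser stroke direction."""

    depth: float = 0.01  # µm; superficial relative to Sa
    width: float = 1.2  # µm
    spacing: float = 4.0  # µm
    orientation_deg: float = 0.0  # stroke direction; grooves run along it


@dataclass(frozen=True)
class WearParams:
    """Eraser-wear operator settings.

    ``truncation_quantile`` is the material-ratio fraction of the
    uppermost surface that is flattened: heights above the
    (1 - q)-quantile are moved toward that cut height, retaining a
    ``compression`` fraction of their excursion (``hard_clip`` sets them
    exactly to the cut).  ``polish`` shrinks the micro-relief of the
    plateau band (percentile band ``polish_band``) toward its centre; by
    default it is coupled to the truncation quantile (polish = 2 q,
    capped at 0.6) so a single knob scales the whole wear intensity.
    """

    truncation_quantile: float = 0.05
    compression: float = 0.2
    polish: float | None = None
    polish_band: tuple[float, float] = (35.0, 80.0)  # percentiles of the pre-wear surface
    hard_clip: bool = False
    striation: StriationParams | None = field(default_factory=StriationParams)
    lateral_offset: tuple[float, float] = (0.0, 0.0)  # µm (x, y)
    remeasure_noise_sd: float = 0.005  # µm

    def __post_init__(self) -> None:
        if not (0.0 <= self.truncation_quantile < 0.5):
            raise ValueError("truncation_quantile must lie in [0, 0.5)")

    @property
    def effective_polish(self) -> float:
        if self.polish is not None:
            return self.polish
        return min(2.0 * self.truncation_quantile, 0.6)


def apply_eem_wear(surface: HeightMap, wear: WearParams, seed: int | np.random.SeedSequence) -> HeightMap:
    """Apply the eraser-wear operator to a surface.

    The operation is monotone in ``truncation_quantile`` for Smrk1
    (non-decreasing) and Sa (non-increasing) while the cut height stays
    above the plateau band — i.e. for truncation quantiles up to the
    asperity mass fraction (~0.2 with the default marginal).
    """
    rng = np.random.default_rng(seed)
    z0 = surface.heights
    if not surface.is_fully_valid:
        raise ValueError("apply_eem_wear expects a fully measured surface")
    z = z0.copy()
    q = wear.truncation_quantile
    if q > 0:
        h_cut = np.quantile(z0, 1 - q)
        above = z > h_cut
        if wear.hard_clip:
            z = np.where(above, h_cut, z)
        else:
            z = np.where(above, h_cut + wear.compression * (z - h_cut), z)
    pol = wear.effective_polish
    if pol > 0:
        lo, hi = np.percentile(z0, wear.polish_band)
        band = (z > lo) & (z <= hi)
        if band.any():
            centre = z[band].mean()
            z = np.where(band, centre + (1 - pol) * (z - centre), z)
    if wear.striation is not None and wear.striation.depth > 0:
        st = wear.striation
        x = np.arange(surface.nx) * surface.dx
        y = np.arange(surface.ny) * surface.dy
        X, Y = np.meshgrid(x, y)
        theta = math.radians(st.orientation_deg)
        # coordinate across the stroke direction; grooves repeat along it
        u = -X * math.sin(theta) + Y * math.cos(theta)
        phase = rng.uniform(0, st.spacing)
        dist = np.abs(((u - phase + st.spacing / 2) % st.spacing) - st.spacing / 2)
        z = z - st.depth * np.maximum(0.0, 1.0 - dist / (st.width / 2))
    ox, oy = wear.lateral_offset
    sx = int(round(ox / surface.dx))
    sy = int(round(oy / surface.dy))
    if sx or sy:
        # shift the content; freshly exposed margins are filled by reflection
        z = np.pad(z, ((abs(sy),) * 2, (abs(sx),) * 2), mode="reflect")
        z = z[abs(sy) - sy : abs(sy) - sy + surface.ny, abs(sx) - sx : abs(sx) - sx + surface.nx]
    if wear.remeasure_noise_sd > 0:
        z = z + rng.normal(scale=wear.remeasure_noise_sd, size=z.shape)
    out = surface.with_heights(z)
    out.origin_offset = (surface.origin_offset[0] + ox, surface.origin_offset[1] + oy)
    return out


# ------------------------------------------------------------------ studies

_PARAM_NAMES = ("Sa", "Spc", "Sha", "Smrk1")


def _default_fixed_effects() -> np.ndarray:
    # rows: intercept, area (cut), erasing (after); columns: Sa, Spc, Sha, Smrk1
    return np.array(
        [
            [math.log(0.60), math.log(2.71), math.log(123.50), math.log(19.87)],
            [0.0, 0.0, 0.0, 0.0],
            [0.0, 0.0, 0.0, math.log(1.02)],
        ]
    )


@dataclass(frozen=True)
class StudyGenParams:
    """Study design and effect sizes for whole-study generation.

    The default geometry mirrors the sampling experiment: 6 specimens,
    2 areas (cut, control), 5 measurement locations per area, scanned
    before and after EEM; ``drop_pairs`` removes whole before/after
    pairs (1 reproduces the n = 118 design).  Effects and dispersions
    are on the natural-log scale of the four texture parameters.
    """

    n_specimens: int = 6
    n_locations_per_area: int = 5
    fixed_effects: np.ndarray = field(default_factory=_default_fixed_effects)
    specimen_sd: np.ndarray = field(
        default_factory=lambda: np.array([0.35, 0.25, 0.30, 0.03])
    )
    location_sd: np.ndarray = field(
        default_factory=lambda: np.array([0.45, 0.35, 0.35, 0.03])
    )
    residual_cov: np.ndarray = field(
        default_factory=lambda: np.diag(np.array([0.055, 0.055, 0.09, 0.025]) ** 2)
    )
    drop_pairs: int = 0

    def __post_init__(self) -> None:
        cov = np.asarray(self.residual_cov, dtype=float)
        if cov.shape != (4, 4) or not np.allclose(cov, cov.T):
            raise ValueError("residual_cov must be a symmetric 4x4 matrix")
        eig = np.linalg.eigvalsh(cov)
        if np.any(eig <= 0):
            raise ValueError("residual_cov must be positive definite")
        B = np.asarray(self.fixed_effects, dtype=float)
        if B.shape != (3, 4):
            raise ValueError("fixed_effects must be 3x4 (intercept, area, erasing) x (Sa, Spc, Sha, Smrk1)")


def study_design(params: StudyGenParams) -> list[ScanMetadata]:
    """The full scan list (one entry per scan, two phases per location)."""
    metas: list[ScanMetadata] = []
    for s in range(params.n_specimens):
        specimen = f"SIM-{s + 1:02d}"
        for area in (Area.CUT, Area.CONTROL):
            for loc in range(1, params.n_locations_per_area + 1):
                for phase in (Phase.BEFORE, Phase.AFTER):
                    metas.append(ScanMetadata(specimen, area, loc, phase))
    if params.drop_pairs:
        # mirror the study: drop whole pairs, starting with location 2 of
        # the control area of the first specimen
        dropped = 0
        keep: list[ScanMetadata] = []
        drop_keys = set()
        for s in range(params.n_specimens):
            for loc in range(2, params.n_locations_per_area + 1):
                if dropped < params.drop_pairs:
                    drop_keys.add((f"SIM-{s + 1:02d}", Area.CONTROL.value, loc))
                    dropped += 1
        for m in metas:
            if m.pair_key in drop_keys:
                continue
            keep.append(m)
        metas = keep
    return metas


def generate_study(
    params: StudyGenParams,
    mode: str = "model_level",
    seed: int | np.random.SeedSequence = 0,
    surface_params: SurfaceGenParams | None = None,
    wear: WearParams | None = None,
) -> tuple[list[TextureRecord], dict]:
    """Generate a whole before/after study.

    ``model_level`` draws the log texture parameters directly from the
    multivariate mixed model Y = XB + ZU + E with the configured effects,
    and the truth record carries the exact parameters used.
    ``surface_level`` generates full before/after surface pairs whose
    wear strength realizes the plateauing effect, and runs the texture
    computation on them; specimen/location scale effects modulate the
    target Sa.
    """
    if mode not in ("model_level", "surface_level"):
        raise ValueError(f"unknown mode {mode!r}")
    metas = study_design(params)
    ss = np.random.SeedSequence(seed if isinstance(seed, int) else seed.entropy)
    rng = np.random.default_rng(ss.spawn(1)[0])

    specimens = sorted({m.specimen for m in metas})
    locations = sorted({m.pair_key for m in metas})
    spec_idx = {s: i for i, s in enumerate(specimens)}
    loc_idx = {k: i for i, k in enumerate(locations)}

    B = np.asarray(params.fixed_effects, dtype=float)
    u_spec = rng.normal(size=(len(specimens), 4)) * params.specimen_sd[None, :]
    u_loc = rng.normal(size=(len(locations), 4)) * params.location_sd[None, :]
    truth = {
        "fixed_effects": B,
        "u_specimen": u_spec,
        "u_location": u_loc,
        "specimen_sd": np.asarray(params.specimen_sd, dtype=float),
        "location_sd": np.asarray(params.location_sd, dtype=float),
        "residual_cov": np.asarray(params.residual_cov, dtype=float),
        "specimens": specimens,
        "locations": locations,
    }

    if mode == "model_level":
        chol = np.linalg.cholesky(np.asarray(params.residual_cov, dtype=float))
        records = []
        for m in metas:
            x = np.array([1.0, 1.0 if m.area is Area.CUT else 0.0, 1.0 if m.phase is Phase.AFTER else 0.0])
            mean = x @ B + u_spec[spec_idx[m.specimen]] + u_loc[loc_idx[m.pair_key]]
            y = mean + chol @ rng.normal(size=4)
            vals = np.exp(y)
            records.append(TextureRecord(m, Sa=vals[0], Spc=vals[1], Sha=vals[2], Smrk1=vals[3]))
        return records, truth

    # surface_level
    sp = surface_params or SurfaceGenParams()
    wp = wear or WearParams()
    settings = TextureSettings()
    records = []
    loc_seeds = {k: s for k, s in zip(locations, ss.spawn(len(locations) + 1)[1:])}
    for key in locations:
        specimen, area, loc = key
        # specimen/location random effects scale the local roughness
        scale = math.exp(u_spec[spec_idx[specimen]][0] + u_loc[loc_idx[key]][0])
        local = replace(sp, target_Sa=sp.target_Sa * scale)
        child = np.random.SeedSequence(entropy=loc_seeds[key].entropy)
        s_gen, s_noise, s_wear = child.spawn(3)
        base = generate_surface(local, s_gen)
        noise_rng = np.random.default_rng(s_noise)
        before = base.with_heights(
            base.heights + noise_rng.normal(scale=wp.remeasure_noise_sd, size=base.shape)
        )
        after = apply_eem_wear(base, wp, s_wear)
        meta_b = ScanMetadata(specimen, area, loc, Phase.BEFORE)
        meta_a = ScanMetadata(specimen, area, loc, Phase.AFTER)
        records.append(compute_texture_record(before, meta_b, settings))
        records.append(compute_texture_record(after, meta_a, settings))
    truth["wear"] = wp
    truth["surface_params"] = sp
    return records, truth


# ------------------------------------------------------------- force traces


def generate_force_trace(
    n_events: int,
    peak_mean: float = 8.12,
    peak_sd: float = 1.21,
    rate_hz: float = 10.0,
    seed: int | np.random.SeedSequence = 0,
    baseline_noise_sd: float = 0.02,
    pulse_width_s: float = 0.25,
    event_spacing_s: float = 1.2,
):
    """A force trace with ``n_events`` smooth contact pulses.

    Pulse maxima are drawn from Normal(peak_mean, peak_sd) truncated
    above the detection threshold; events are spaced
    ``event_spacing_s`` apart with jitter, emulating rhythmic erasing
    strokes sampled at ``rate_hz``.
    """
    from .force import ForceTrace  # local import to avoid a cycle

    if n_events > 0 and peak_mean <= 0.5:
        raise ValueError("peak_mean must exceed the 0.5 N detection threshold")
    rng = np.random.default_rng(seed)
    duration = max(n_events, 1) * event_spacing_s + 4.0
    n = int(round(duration * rate_hz)) + 1
    t = np.arange(n) / rate_hz
    f = rng.normal(scale=baseline_noise_sd, size=n)
    if n_events > 0:
        centers = 2.0 + np.arange(n_events) * event_spacing_s
        centers = centers + rng.uniform(-0.15, 0.15, size=n_events) * event_spacing_s
        # snap to the sample grid so the drawn amplitude is the sampled maximum
        centers = np.round(centers * rate_hz) / rate_hz
        amps = rng.normal(peak_mean, peak_sd, size=n_events)
        amps = np.clip(amps, 0.75, None)
        sig = pulse_width_s / 2.355  # FWHM -> sd
        for c, a in zip(centers, amps):
            f = f + a * np.exp(-0.5 * ((t - c) / sig) ** 2)
    return ForceTrace(t=t, f=np.maximum(f, 0.0), rate=rate_hz)


# ---------------------------------------------------------------- spectra


def generate_spectrum(
    markers_present,
    snr: float = 50.0,
    baseline: tuple[float, float] = (120.0, -0.02),
    seed: int | np.random.SeedSequence = 0,
    mz_range: tuple[float, float] = (800.0, 3600.0),
    dm: float = 0.1,
    noise_sd: float = 1.0,
    peak_sigma: float = 0.35,
    label: str = "synthetic",
):
    """A profile MALDI-TOF spectrum with Gaussian marker peaks.

    Each marker contributes a Gaussian peak of amplitude snr x noise_sd
    at its m/z; a linear baseline (intercept, slope per Da relative to
    the range start) and i.i.d. Gaussian noise are added.
    """
    from .zooms import Spectrum  # local import to avoid a cycle

    mzs = [m.mz for m in markers_present]
    if len(set(np.round(mzs, 6))) != len(mzs):
        raise ValueError("marker m/z values must be distinct")
    rng = np.random.default_rng(seed)
    mz = np.arange(mz_range[0], mz_range[1] + dm / 2, dm)
    b0, b1 = baseline
    inten = np.maximum(b0 + b1 * (mz - mz_range[0]), 0.0)
    inten = inten + rng.normal(scale=noise_sd, size=mz.size)
    for m in markers_present:
        inten = inten + snr * noise_sd * np.exp(-0.5 * ((mz - m.mz) / peak_sigma) ** 2)
    return Spectrum(mz=mz, intensity=np.maximum(inten, 0.0), label=label)
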