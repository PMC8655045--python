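"""Metrology oracles: the four ISO 25178 parameters against independent
brute-force or analytic references."""

import numpy as np
import pytest
from scipy import ndimage

from eemtopo import iso25178 as iso
from eemtopo.surfaces import HeightMap, ScanMetadata
from eemtopo.synthetic import SurfaceGenParams, WearParams, apply_eem_wear, generate_surface

from conftest import grid_surface


# ----------------------------------------------------- independent oracles


def smr1_bruteforce(z: np.ndarray, window_pct: float = 40.0) -> float:
    """Sk-family upper material ratio by exhaustive secant search.

    Written directly against the sorted sample: slide a window of
    ``window_pct`` % of the points along the descending height sequence,
    take the secant through the window endpoints, keep the least-steep
    one, extend it to material ratio 0 and count the fraction of points
    at or above that height.
    """
    zs = np.sort(np.ravel(z))[::-1]
    n = zs.size
    win = int(round(window_pct / 100.0 * (n - 1)))
    drops = zs[: n - win] - zs[win:]
    i0 = int(np.argmin(drops))
    slope = drops[i0] / (100.0 * win / (n - 1))  # height drop per % material ratio
    mr0 = 100.0 * i0 / (n - 1)
    z_top = zs[i0] + slope * mr0
    return 100.0 * np.mean(np.ravel(z) >= z_top)


def sha_bruteforce(surface: HeightMap, cut_ratio: float = 10.0) -> float:
    """Mean area of interior connected components above the cut height."""
    z = surface.heights
    h_cut = np.quantile(z, 1 - cut_ratio / 100.0)
    mask = z >= h_cut
    labels, nlab = ndimage.label(mask)
    areas = []
    for lab in range(1, nlab + 1):
        comp = labels == lab
        touches = comp[0, :].any() or comp[-1, :].any() or comp[:, 0].any() or comp[:, -1].any()
        if not touches:
            areas.append(comp.sum() * surface.dx * surface.dy)
    return float(np.mean(areas)) if areas else float("nan")


# ------------------------------------------------------------------- tests


class TestSa:
    def test_constant_surface_is_zero(self):
        assert iso.sa(grid_surface(np.full((16, 16), 3.7))) == pytest.approx(0.0, abs=1e-12)

    def test_sinusoid_matches_2A_over_pi(self):
        A, lam, dx = 0.8, 32.0, 0.5  # 64 samples per period
        x = np.arange(256) * dx
        z = A * np.sin(2 * np.pi * x / lam)
        s = grid_surface(np.tile(z, (32, 1)), dx=dx)
        assert iso.sa(s) == pytest.approx(2 * A / np.pi, rel=1e-3)

    def test_binary_surface(self):
        z = np.ones((10, 10)) * 0.5
        z[:, :5] = -0.5
        assert iso.sa(grid_surface(z)) == pytest.approx(0.5)

    def test_invariant_to_constant_offset(self, bone_surface):
        shifted = bone_surface.with_heights(bone_surface.heights + 5.0)
        assert iso.sa(shifted) == pytest.approx(iso.sa(bone_surface), rel=1e-12)


class TestMaterialRatioCurve:
    def test_endpoints(self, bone_surface):
        curve = iso.material_ratio_curve(bone_surface)
        assert curve.ratio[0] == 0.0
        assert curve.ratio[-1] == 100.0

    def test_binary_surface_ratio_step(self):
        z = np.zeros((10, 10))
        z[:2, :] = 1.0  # 20 % of surface at the high level
        curve = iso.material_ratio_curve(grid_surface(z))
        assert curve.ratio_at(0.5) == pytest.approx(20.0, abs=0.5)

    def test_monotone_with_depth(self, bone_surface):
        curve = iso.material_ratio_curve(bone_surface)
        assert np.all(np.diff(curve.ratio) >= 0)


class TestSmrk1:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_bruteforce_oracle(self, seed):
        surf = generate_surface(SurfaceGenParams(), seed=seed)
        ours = iso.smrk1(surf)
        oracle = smr1_bruteforce(surf.heights)
        assert ours == pytest.approx(oracle, abs=0.1)

    def test_matches_oracle_on_gaussian_heights(self, rng):
        z = ndimage.gaussian_filter(rng.normal(size=(128, 128)), 2.0)
        s = grid_surface(z)
        assert iso.smrk1(s) == pytest.approx(smr1_bruteforce(z), abs=0.1)

    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_nondecreasing_under_plateau_wear(self, seed):
        surf = generate_surface(SurfaceGenParams(), seed=seed)
        prev = iso.smrk1(surf)
        for q in (0.05, 0.10, 0.20):
            wear = WearParams(truncation_quantile=q, striation=None, remeasure_noise_sd=0.0)
            worn = apply_eem_wear(surf, wear, seed=0)
            cur = iso.smrk1(worn)
            assert cur >= prev - 1e-9
            prev = cur

    def test_flat_surface_raises(self):
        with pytest.raises(ValueError, match="flat"):
            iso.smrk1(grid_surface(np.zeros((8, 8))))

    def test_peak_valley_duality(self, bone_surface):
        """Negating heights swaps the peak side with the valley side, so the
        upper material ratio of the negation reflects the lower-side analogue."""
        z = bone_surface.heights
        up = iso.smrk1(bone_surface)
        down = iso.smrk1(bone_surface.with_heights(-z))
        assert 0.0 < up < 100.0 and 0.0 < down < 100.0
        assert up != pytest.approx(down, abs=1e-6)  # the surface is not symmetric


class TestSegmentHills:
    @staticmethod
    def _bump(nx, cx, cy, radius, height, dx=1.0):
        x = np.arange(nx) * dx
        X, Y = np.meshgrid(x, x)
        return height * np.exp(-((X - cx) ** 2 + (Y - cy) ** 2) / (2 * radius**2))

    def test_single_interior_bump_is_one_closed_hill(self):
        z = self._bump(64, 32, 32, 4.0, 1.0)
        seg = iso.segment_hills(grid_surface(z, dx=1.0), cut_ratio=10.0)
        assert len(seg.closed) == 1

    def test_boundary_bump_yields_no_closed_hill(self):
        z = self._bump(64, 0.0, 32, 4.0, 1.0)
        seg = iso.segment_hills(grid_surface(z, dx=1.0), cut_ratio=10.0)
        assert len(seg.closed) == 0

    def test_shallow_saddle_merges_hills(self):
        # two bumps; saddle depth relative to the range controls merging
        z = self._bump(64, 24, 32, 6.0, 1.0) + self._bump(64, 40, 32, 6.0, 1.0)
        rng_z = np.ptp(z)
        saddle_depth = z.max() - z[32, 32]
        seg_merge = iso.segment_hills(
            grid_surface(z), pruning_threshold=100.0 * saddle_depth / rng_z * 1.5
        )
        seg_split = iso.segment_hills(
            grid_surface(z), pruning_threshold=100.0 * saddle_depth / rng_z * 0.5
        )
        n_merge = len(np.unique(seg_merge.labels))
        n_split = len(np.unique(seg_split.labels))
        assert n_merge == 1
        assert n_split == 2


class TestSha:
    def _mesa(self, nx, centers, radius, dx=1.0):
        x = np.arange(nx) * dx
        X, Y = np.meshgrid(x, x)
        z = np.zeros((nx, nx))
        for cx, cy in centers:
            z[np.hypot(X - cx, Y - cy) <= radius] = 1.0
        return z

    def test_single_mesa_cross_section(self):
        z = self._mesa(64, [(32, 32)], radius=5.64)  # ~100 px^2 disc
        s = grid_surface(z, dx=1.0)
        val = iso.sha(s, cut_ratio=2.0)
        expected = float((z > 0).sum())  # dx = dy = 1 -> area == pixel count
        assert val == pytest.approx(expected, rel=0.02)

    def test_two_identical_mesas_mean(self):
        z1 = self._mesa(64, [(20, 20)], radius=5.64)
        z2 = self._mesa(64, [(44, 44)], radius=5.64)
        z = z1 + z2
        val = iso.sha(grid_surface(z, dx=1.0), cut_ratio=3.0)
        expected = float((z1 > 0).sum())
        assert val == pytest.approx(expected, rel=0.02)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_connected_component_oracle_on_bump_fields(self, seed):
        rng = np.random.default_rng(seed)
        nx = 96
        x = np.arange(nx)
        X, Y = np.meshgrid(x, x)
        z = np.zeros((nx, nx))
        # well-separated bumps so each cut cross-section is one watershed hill
        centers = [(16 + 28 * i + rng.uniform(-4, 4), 16 + 28 * j + rng.uniform(-4, 4))
                   for i in range(3) for j in range(3)]
        for cx, cy in centers:
            z += rng.uniform(0.8, 1.2) * np.exp(-((X - cx) ** 2 + (Y - cy) ** 2) / (2 * 3.5**2))
        s = grid_surface(z, dx=1.0)
        assert iso.sha(s) == pytest.approx(sha_bruteforce(s), rel=0.05)

    def test_no_closed_hills_gives_nan(self):
        z = np.linspace(0, 1, 32)[None, :] * np.ones((32, 1))  # monotone ramp
        assert np.isnan(iso.sha(grid_surface(z)))


class TestSpc:
    def test_paraboloid_cap_equals_curvature_constant(self):
        c, dx = 0.05, 0.5
        x = (np.arange(65) - 32) * dx
        X, Y = np.meshgrid(x, x)
        z = 2.0 - (c / 2) * (X**2 + Y**2)
        assert iso.spc(grid_surface(z, dx=dx)) == pytest.approx(c, rel=1e-6)

    def test_egg_carton_curvature(self):
        A, dx = 0.5, 0.5
        lam = 16 * dx  # 16 samples per period
        k = 2 * np.pi / lam
        x = np.arange(96) * dx
        X, Y = np.meshgrid(x, x)
        z = A * np.sin(k * X) * np.sin(k * Y)
        # discrete Laplacian of a sinusoid underestimates k^2 by ~(kh)^2/12
        assert iso.spc(grid_surface(z, dx=dx)) == pytest.approx(A * k**2, rel=0.03)

    def test_height_scaling_is_linear(self, bone_surface):
        base = iso.spc(bone_surface)
        scaled = iso.spc(bone_surface.with_heights(bone_surface.heights * 3.0))
        assert scaled == pytest.approx(3.0 * base, rel=1e-9)


class TestInvariances:
    def test_translation_and_rotation(self, bone_surface):
        z = bone_surface.heights
        rot = grid_surface(np.rot90(z), dx=bone_surface.dx)
        base = grid_surface(z, dx=bone_surface.dx)
        assert iso.sa(rot) == pytest.approx(iso.sa(base), rel=1e-12)
        assert iso.smrk1(rot) == pytest.approx(iso.smrk1(base), abs=1e-9)
        assert iso.spc(rot) == pytest.approx(iso.spc(base), rel=1e-6)
        seg_a = iso.segment_hills(base)
        seg_b = iso.segment_hills(rot)
        assert len(seg_a.closed) == len(seg_b.closed)

    def test_smrk1_invariant_to_offset(self, bone_surface):
        shifted = bone_surface.with_heights(bone_surface.heights + 2.5)
        assert iso.smrk1(shifted) == pytest.approx(iso.smrk1(bone_surface), abs=1e-9)


class TestComputeTextureRecord:
    def test_study_surface_hits_target_sa(self):
        surf = generate_surface(SurfaceGenParams(target_Sa=0.6), seed=5)
        rec = iso.compute_texture_record(surf, ScanMetadata("S", "cut", 1, "before"))
        assert rec.Sa == pytest.approx(0.6, rel=0.10)

    def test_wear_raises_smrk1(self):
        surf = generate_surface(SurfaceGenParams(), seed=6)
        before = iso.compute_texture_record(surf, ScanMetadata("S", "cut", 1, "before"))
        worn = apply_eem_wear(surf, WearParams(), seed=7)
        after = iso.compute_texture_record(worn, ScanMetadata("S", "cut", 1, "after"))
        assert after.Smrk1 > before.Smrk1

    def test_flat_surface_degenerates_to_markers(self):
        rec = iso.compute_texture_record(
            grid_surface(np.zeros((32, 32))), ScanMetadata("S", "cut", 1, "before")
        )
        assert rec.Sa == 0.0
        assert np.isnan(rec.Smrk1) and np.isnan(rec.Spc) and np.isnan(rec.Sha)
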