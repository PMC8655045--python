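"""Synthetic surfaces, wear operator, study generation, traces and spectra."""

import numpy as np
import pytest

from eemtopo import iso25178 as iso
from eemtopo.force import detect_contact_events, summarize_peak_forces
from eemtopo.surfaces import Phase
from eemtopo.synthetic import (
    CutmarkParams,
    ResidueParams,
    StriationParams,
    StudyGenParams,
    SurfaceGenParams,
    WearParams,
    apply_eem_wear,
    generate_force_trace,
    generate_spectrum,
    generate_study,
    generate_surface,
)
from eemtopo.zooms import PeptideMarker, preprocess_spectrum, snr_at_markers


class TestGenerateSurface:
    def test_realized_sa_matches_target(self):
        surf = generate_surface(SurfaceGenParams(target_Sa=0.60), seed=1)
        assert iso.sa(surf) == pytest.approx(0.60, rel=0.10)

    def test_dropout_fraction_realized(self):
        surf = generate_surface(SurfaceGenParams(dropout_fraction=0.03), seed=2)
        n = surf.valid.size
        se = np.sqrt(0.03 * 0.97 / n)
        assert surf.measured_fraction == pytest.approx(0.97, abs=4 * se)

    def test_same_seed_reproducible(self):
        a = generate_surface(SurfaceGenParams(), seed=3)
        b = generate_surface(SurfaceGenParams(), seed=3)
        np.testing.assert_array_equal(a.heights, b.heights)
        np.testing.assert_array_equal(a.valid, b.valid)

    def test_grid_too_small_for_correlation_length(self):
        with pytest.raises(ValueError, match="correlation"):
            generate_surface(SurfaceGenParams(nx=16, ny=16, correlation_length=4.0), seed=0)

    def test_cutmark_removes_material(self):
        base = SurfaceGenParams(cutmark=None)
        marked = SurfaceGenParams(cutmark=CutmarkParams(depth=3.0, width=16.0, count=1))
        z0 = generate_surface(base, seed=4).heights
        z1 = generate_surface(marked, seed=4).heights
        # the V-groove removes a volume of ~depth*width/2 per unit length
        assert z0.mean() - z1.mean() > 0.1

    def test_residues_add_material(self):
        base = SurfaceGenParams(residues=None)
        res = SurfaceGenParams(residues=ResidueParams(count=10, radius=5.0, height=3.0))
        z0 = generate_surface(base, seed=5).heights
        z1 = generate_surface(res, seed=5).heights
        assert z1.mean() - z0.mean() > 0.1


class TestApplyEemWear:
    def test_identity_when_all_components_off(self, bone_surface):
        wear = WearParams(truncation_quantile=0.0, striation=None, remeasure_noise_sd=0.0)
        out = apply_eem_wear(bone_surface, wear, seed=0)
        np.testing.assert_array_equal(out.heights, bone_surface.heights)

    def test_plateau_raises_smrk1_and_lowers_sa(self, bone_surface):
        wear = WearParams(truncation_quantile=0.05)
        worn = apply_eem_wear(bone_surface, wear, seed=1)
        assert iso.smrk1(worn) > iso.smrk1(bone_surface)
        assert iso.sa(worn) <= iso.sa(bone_surface)

    def test_striation_periodicity(self):
        # quiet base so the groove comb dominates the mean profile
        params = SurfaceGenParams(target_Sa=0.05, correlation_length=3.0)
        surf = generate_surface(params, seed=6)
        spacing = 5.0
        wear = WearParams(
            truncation_quantile=0.0,
            striation=StriationParams(depth=0.3, width=1.6, spacing=spacing, orientation_deg=90.0),
            remeasure_noise_sd=0.0,
        )
        worn = apply_eem_wear(surf, wear, seed=7)
        # orientation 90 deg: stroke along y, grooves run along y and
        # repeat across x
        profile = (worn.heights - surf.heights).mean(axis=0)
        amp = np.abs(np.fft.rfft(profile - profile.mean()))
        freqs = np.fft.rfftfreq(profile.size, d=surf.dx)
        assert freqs[np.argmax(amp)] == pytest.approx(1 / spacing, rel=0.15)

    def test_monotone_in_truncation_quantile(self, bone_surface):
        smrk, sa_vals = [], []
        for q in (0.0, 0.05, 0.10, 0.20):
            wear = WearParams(truncation_quantile=q, striation=None, remeasure_noise_sd=0.0)
            worn = apply_eem_wear(bone_surface, wear, seed=2)
            smrk.append(iso.smrk1(worn))
            sa_vals.append(iso.sa(worn))
        assert np.all(np.diff(smrk) >= -1e-9)
        assert np.all(np.diff(sa_vals) <= 1e-9)

    def test_lateral_offset_recorded_and_applied(self, bone_surface):
        wear = WearParams(truncation_quantile=0.0, striation=None,
                          remeasure_noise_sd=0.0, lateral_offset=(2.0, -1.2))
        out = apply_eem_wear(bone_surface, wear, seed=3)
        assert out.origin_offset == (2.0, -1.2)
        # interior content is a pure shift of the input
        sy = int(round(-1.2 / bone_surface.dy))
        sx = int(round(2.0 / bone_surface.dx))
        np.testing.assert_allclose(
            out.heights[10:-10, 10:-10],
            bone_surface.heights[10 - sy : -10 - sy, 10 - sx : -10 - sx],
            atol=1e-12,
        )


class TestGenerateStudyModelLevel:
    def test_null_effects_centre_on_intercepts(self):
        B = np.zeros((3, 4))
        B[0] = [np.log(0.6), np.log(2.7), np.log(120.0), np.log(20.0)]
        params = StudyGenParams(fixed_effects=B)
        recs, truth = generate_study(params, mode="model_level", seed=21)
        logs = np.log([[r.Sa, r.Spc, r.Sha, r.Smrk1] for r in recs])
        total_sd = np.sqrt(
            params.specimen_sd**2 + params.location_sd**2 + np.diag(params.residual_cov)
        )
        se = total_sd / np.sqrt(len(recs) / 4)  # generous (ignores clustering)
        for j in range(4):
            assert logs[:, j].mean() == pytest.approx(B[0, j], abs=6 * se[j] + 0.1)

    def test_erasing_effect_recovered_in_paired_differences(self):
        recs, _ = generate_study(StudyGenParams(), mode="model_level", seed=22)
        by_phase = {}
        for r in recs:
            by_phase.setdefault(r.metadata.pair_key, {})[r.metadata.phase] = r
        diffs = [
            np.log(v[Phase.AFTER].Smrk1) - np.log(v[Phase.BEFORE].Smrk1)
            for v in by_phase.values()
            if len(v) == 2
        ]
        se = np.sqrt(2 * 0.025**2 / len(diffs))
        assert np.mean(diffs) == pytest.approx(np.log(1.02), abs=4 * se)

    def test_design_counts_with_and_without_dropped_pair(self):
        full, _ = generate_study(StudyGenParams(drop_pairs=0), mode="model_level", seed=1)
        dropped, _ = generate_study(StudyGenParams(drop_pairs=1), mode="model_level", seed=1)
        assert len(full) == 120
        assert len(dropped) == 118

    def test_nonpositive_definite_cov_rejected(self):
        bad = np.diag([1.0, 1.0, 1.0, -0.1])
        with pytest.raises(ValueError, match="positive definite"):
            StudyGenParams(residual_cov=bad)


class TestGenerateStudySurfaceLevel:
    def test_records_pair_up_and_smrk1_increases(self):
        params = StudyGenParams(n_specimens=2, n_locations_per_area=1)
        sp = SurfaceGenParams(nx=96, ny=96)
        recs, truth = generate_study(params, mode="surface_level", seed=30, surface_params=sp)
        assert len(recs) == 2 * 2 * 1 * 2
        by_pair = {}
        for r in recs:
            by_pair.setdefault(r.metadata.pair_key, {})[r.metadata.phase] = r
        ups = [v[Phase.AFTER].Smrk1 > v[Phase.BEFORE].Smrk1 for v in by_pair.values()]
        assert np.mean(ups) >= 0.75


class TestGenerateForceTrace:
    def test_no_events_stays_below_threshold(self):
        trace = generate_force_trace(0, seed=1)
        assert trace.f.max() < 0.5

    def test_event_round_trip_with_detector(self):
        trace = generate_force_trace(50, peak_mean=8.12, peak_sd=1.21, seed=2)
        events = detect_contact_events(trace)
        assert len(events) == 50
        summ = summarize_peak_forces(events, duration=trace.duration)
        se = 1.21 / np.sqrt(50)
        assert summ["mean"] == pytest.approx(8.12, abs=2 * se)

    def test_same_seed_identical(self):
        a = generate_force_trace(10, seed=3)
        b = generate_force_trace(10, seed=3)
        np.testing.assert_array_equal(a.f, b.f)

    def test_subthreshold_mean_rejected(self):
        with pytest.raises(ValueError, match="threshold"):
            generate_force_trace(5, peak_mean=0.4, seed=0)


class TestGenerateSpectrum:
    MARKER = PeptideMarker("COL1a2 978-990", 1208.0, frozenset({"Bos"}), "low")

    def test_snr_round_trip(self):
        spec = generate_spectrum([self.MARKER], snr=50.0, seed=1)
        out = snr_at_markers(preprocess_spectrum(spec), [self.MARKER])
        assert out[self.MARKER.name]["snr"] == pytest.approx(50.0, rel=0.2)

    def test_empty_marker_list_gives_no_peaks(self):
        spec = generate_spectrum([], snr=50.0, seed=2)
        out = snr_at_markers(preprocess_spectrum(spec), [self.MARKER])
        assert not out[self.MARKER.name]["present"]

    def test_baseline_slope_does_not_move_snr(self):
        flat = generate_spectrum([self.MARKER], baseline=(100.0, 0.0), seed=3)
        sloped = generate_spectrum([self.MARKER], baseline=(300.0, -0.08), seed=3)
        s1 = snr_at_markers(preprocess_spectrum(flat), [self.MARKER])[self.MARKER.name]["snr"]
        s2 = snr_at_markers(preprocess_spectrum(sloped), [self.MARKER])[self.MARKER.name]["snr"]
        assert s2 == pytest.approx(s1, rel=0.2)

    def test_duplicate_marker_mass_rejected(self):
        m2 = PeptideMarker("other", 1208.0, frozenset({"Ovis"}), "low")
        with pytest.raises(ValueError, match="distinct"):
            generate_spectrum([self.MARKER, m2], seed=0)
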