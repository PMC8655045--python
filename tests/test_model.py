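"""Design construction, Gibbs sampling, LOO, ratios, GOF and descriptives."""

import warnings

import numpy as np
import pytest

from eemtopo.model import (
    SurfaceTextureModel,
    build_design,
    compare_loo,
    descriptive_table,
    gof_mahalanobis,
)
from eemtopo.surfaces import ScanMetadata, TextureRecord
from eemtopo.synthetic import StudyGenParams, generate_study, _default_fixed_effects

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="module")
def full_design_records():
    recs, truth = generate_study(StudyGenParams(drop_pairs=1), mode="model_level", seed=7)
    return recs, truth


@pytest.fixture(scope="module")
def small_fit():
    """A quick fit on a reduced design, reused by several tests."""
    params = StudyGenParams(n_specimens=4, n_locations_per_area=3)
    recs, truth = generate_study(params, mode="model_level", seed=5)
    fit = SurfaceTextureModel.from_records(recs, "M1").fit(
        chains=2, draws=300, warmup=500, thin=2, seed=11
    )
    return fit, truth


class TestBuildDesign:
    def test_full_design_dimensions(self, full_design_records):
        recs, _ = full_design_records
        data = build_design(recs, "M1")
        assert data.Y.shape == (118, 4)
        assert data.X.shape == (118, 3)
        assert data.Z.shape == (118, 65)
        assert data.n_specimens == 6 and data.n_locations == 59

    def test_every_z_row_has_two_ones(self, full_design_records):
        recs, _ = full_design_records
        data = build_design(recs, "M1")
        assert np.all(data.Z.sum(axis=1) == 2)
        assert set(np.unique(data.Z)) == {0.0, 1.0}

    def test_m0_drops_erasing_column(self, full_design_records):
        recs, _ = full_design_records
        data = build_design(recs, "M0")
        assert data.X.shape == (118, 2)
        assert data.effects == ("intercept", "area")

    def test_zero_value_rejected_with_record_named(self, full_design_records):
        recs, _ = full_design_records
        broken = list(recs)
        meta = ScanMetadata("BAD-1", "cut", 1, "before")
        broken.append(TextureRecord(meta, Sa=0.0, Spc=1.0, Sha=1.0, Smrk1=20.0))
        with pytest.raises(ValueError, match="BAD-1"):
            build_design(broken, "M1")


class TestFit:
    def test_retained_draw_count(self, small_fit):
        fit, _ = small_fit
        assert fit.n_draws == 2 * 300

    def test_recovers_true_fixed_effects(self, small_fit):
        fit, truth = small_fit
        B_true = truth["fixed_effects"]
        for i, eff in enumerate(fit.data.effects):
            draws = fit._stack["B"][:, :, i, :].reshape(-1, 4)
            for j in range(4):
                m, s = draws[:, j].mean(), draws[:, j].std(ddof=1)
                assert abs(m - B_true[i, j]) < 4 * s + 1e-6

    def test_summary_has_all_terms(self, small_fit):
        fit, _ = small_fit
        s = fit.summary()
        assert len(s) == (3 + 3) * 4  # 3 effects + 3 SD blocks, 4 parameters each
        assert "erasing[Smrk1]" in s.index

    def test_interval_calibration_under_null(self):
        """With no erasing effect, the 95 % interval covers 0 most of the time."""
        B = _default_fixed_effects()
        B[2] = 0.0
        cover = 0
        n_rep = 6
        for rep in range(n_rep):
            recs, _ = generate_study(
                StudyGenParams(n_specimens=3, n_locations_per_area=2, fixed_effects=B),
                mode="model_level", seed=100 + rep,
            )
            fit = SurfaceTextureModel.from_records(recs, "M1").fit(
                chains=2, draws=250, warmup=400, thin=2, seed=rep
            )
            draws = fit.coefficient_draws("erasing")
            lo, hi = np.quantile(draws, [0.025, 0.975], axis=0)
            cover += int(np.all((lo <= 0) & (0 <= hi)))
        assert cover >= n_rep - 2  # 95 % nominal; allow small-sample slack


class TestPosteriorRatios:
    def test_exp_of_quantiles_consistency(self, small_fit):
        """Quantiles commute with the monotone exp transform."""
        fit, _ = small_fit
        ratios = fit.posterior_ratios("erasing")
        draws = fit.coefficient_draws("erasing")
        expected = np.exp(np.quantile(draws, [0.025, 0.5, 0.975], axis=0))
        np.testing.assert_allclose(ratios.to_numpy().T, expected, rtol=1e-12)

    def test_zero_coefficient_gives_unit_ratio(self, small_fit):
        fit, _ = small_fit
        fit2 = SurfaceTextureModel(data=fit.data, model_name="M1")
        res = fit2.fit(chains=1, draws=50, warmup=50, seed=0)
        res._stack["B"][:, :, 2, :] = 0.0
        ratios = res.posterior_ratios("erasing")
        assert np.all(ratios.to_numpy() == 1.0)

    def test_unknown_effect_rejected(self, small_fit):
        fit, _ = small_fit
        with pytest.raises(KeyError, match="unknown effect"):
            fit.posterior_ratios("polishing")


class TestLoo:
    def test_self_comparison_is_zero(self, small_fit):
        fit, _ = small_fit
        out = compare_loo(fit, fit)
        assert out["elpd_diff"] == pytest.approx(0.0, abs=1e-9)
        assert out["preferred"] is None

    def test_mismatched_responses_rejected(self, small_fit, full_design_records):
        fit, _ = small_fit
        recs, _ = full_design_records
        other = SurfaceTextureModel.from_records(recs, "M0").fit(
            chains=1, draws=50, warmup=50, seed=1
        )
        with pytest.raises(ValueError, match="identical"):
            compare_loo(fit, other)


class TestGof:
    def test_zero_residuals_give_zero_distances(self, small_fit):
        from dataclasses import replace

        fit, _ = small_fit
        data = replace(fit.data, Y=fit.fitted_values(level="specimen"))
        out = gof_mahalanobis(fit, data)
        assert np.all(out["distance"] == 0.0)

    def test_inflated_residuals_exceed_theoretical_quantiles(self, small_fit):
        from dataclasses import replace

        fit, _ = small_fit
        pred = fit.fitted_values(level="specimen")
        data = replace(fit.data, Y=pred + 3.0 * (fit.simulate(seed=0) - pred))
        out = gof_mahalanobis(fit, data)
        assert out.attrs["qq_slope"] > 3.0

    def test_simulated_data_qq_slope_near_one(self, small_fit):
        """Data simulated from the fitted model sits on the F reference line.

        The classical (n-p)/(p(n-1)) scaling is slightly conservative when
        the covariance is effectively known, so the line sits a little
        below 1; averaging a few replicates keeps the check stable.
        """
        from dataclasses import replace

        fit, _ = small_fit
        slopes = [
            gof_mahalanobis(fit, replace(fit.data, Y=fit.simulate(seed=s))).attrs["qq_slope"]
            for s in range(5)
        ]
        assert 0.7 < np.mean(slopes) < 1.15


class TestDescriptives:
    def test_closed_form_mean_sd(self):
        meta_b = ScanMetadata("S", "cut", 1, "before")
        meta_a = ScanMetadata("S", "cut", 1, "after")
        recs = [
            TextureRecord(meta_b, Sa=1.0, Spc=1.0, Sha=1.0, Smrk1=10.0),
            TextureRecord(ScanMetadata("S", "cut", 2, "before"), Sa=3.0, Spc=1.0, Sha=1.0, Smrk1=10.0),
            TextureRecord(meta_a, Sa=2.0, Spc=1.0, Sha=1.0, Smrk1=10.0),
            TextureRecord(ScanMetadata("S", "cut", 2, "after"), Sa=2.0, Spc=1.0, Sha=1.0, Smrk1=10.0),
        ]
        table = descriptive_table(recs)
        sa_before = table[(table["parameter"] == "Sa") & (table["phase"] == "before")].iloc[0]
        assert sa_before["mean"] == pytest.approx(2.0)
        assert sa_before["sd"] == pytest.approx(np.sqrt(2))

    def test_lognormal_means_match_expectation(self, full_design_records):
        recs, truth = full_design_records
        table = descriptive_table(recs)
        B = truth["fixed_effects"]
        # E[exp(y)] for lognormal: exp(mu + s^2/2); area effect is 0 by default
        total_var = (
            truth["specimen_sd"] ** 2
            + truth["location_sd"] ** 2
            + np.diag(truth["residual_cov"])
        )
        for j, par in enumerate(("Sa", "Spc", "Sha", "Smrk1")):
            row = table[(table["parameter"] == par) & (table["phase"] == "before")].iloc[0]
            expected = np.exp(B[0, j] + total_var[j] / 2)
            # wide tolerance: only 6 specimens drive the between-bone spread
            assert row["mean"] == pytest.approx(expected, rel=0.5)

    def test_missing_phase_rejected(self):
        recs = [
            TextureRecord(ScanMetadata("S", "cut", 1, "before"), Sa=1.0, Spc=1.0, Sha=1.0, Smrk1=10.0)
        ]
        with pytest.raises(ValueError, match="after"):
            descriptive_table(recs)
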