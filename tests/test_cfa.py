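import numpy as np
import pytest

import promstruct as ps
from promstruct.errors import (
    ConfigurationError,
    HeywoodWarning,
    IdentificationError,
    PromstructError,
)


def _moments_from_sigma(Sigma, n=500, ids=None):
    Sigma = np.asarray(Sigma, float)
    p = Sigma.shape[0]
    ids = ids or [f"i{k}" for k in range(p)]
    sd = np.sqrt(np.diag(Sigma))
    R = Sigma / np.outer(sd, sd)
    return ps.SampleMoments(Sigma, R, np.zeros(p), n, list(ids))


class TestModelSpec:
    @pytest.mark.parametrize(
        "fixture,df",
        [
            (ps.ikdc_one_factor, 135),
            (ps.ikdc_two_factor, 134),
            (ps.ikdc_four_factor, 129),
            (ps.ikdc_bifactor, 117),
        ],
    )
    def test_fixture_degrees_of_freedom(self, fixture, df):
        assert ps.model_df(fixture()) == df

    def test_df_equals_free_parameter_count(self, moments600):
        for make in ps.MODEL_FIXTURES.values():
            spec = make()
            fitted = ps.fit_ml(spec, moments600)
            assert fitted.n_free_parameters == spec.n_free_parameters()
            assert fitted.df == 171 - fitted.n_free_parameters

    def test_under_identified_model_rejected(self):
        spec = ps.FactorModelSpec(
            name="tiny", factors=(("g", ("a", "b")),), covariance="orthogonal"
        )
        with pytest.raises(IdentificationError):
            ps.model_df(spec)

    def test_bifactor_requires_orthogonality_and_coverage(self):
        with pytest.raises(ConfigurationError, match="orthogonal"):
            ps.FactorModelSpec(
                name="bad",
                factors=(("g", ("a", "b", "c")), ("s", ("a", "b"))),
                covariance="free",
                general_factor="g",
            )
        with pytest.raises(ConfigurationError, match="every item"):
            ps.FactorModelSpec(
                name="bad",
                factors=(("g", ("a", "b")), ("s", ("c",))),
                covariance="orthogonal",
                general_factor="g",
            )

    def test_spec_yaml_roundtrip(self, tmp_path):
        spec = ps.ikdc_bifactor()
        path = tmp_path / "bifactor.yaml"
        spec.save(path)
        assert ps.FactorModelSpec.load(path) == spec


class TestFitMl:
    def test_saturated_three_item_model(self):
        Sigma = np.array([[1, 0.49, 0.49], [0.49, 1, 0.49], [0.49, 0.49, 1.0]])
        spec = ps.FactorModelSpec(
            name="sat", factors=(("g", ("a", "b", "c")),), covariance="orthogonal"
        )
        fit = ps.fit_ml(spec, _moments_from_sigma(Sigma, ids=["a", "b", "c"]))
        assert fit.df == 0
        assert fit.discrepancy == pytest.approx(0.0, abs=1e-10)

    def test_zero_noise_parameter_recovery(self, population):
        """Fitting the generating spec to the exact population covariance
        returns the generating parameters."""
        mom = _moments_from_sigma(
            population.implied_covariance(), n=606, ids=list(population.item_ids)
        )
        fit = ps.fit_ml(population.model_spec(), mom)
        assert fit.discrepancy < 1e-10
        lam = fit.standardized_loadings
        gcol = fit.factor_index("general")
        np.testing.assert_allclose(lam[:, gcol], population.general_loadings, atol=1e-4)
        spec_lam = lam.copy()
        spec_lam[:, gcol] = 0.0
        np.testing.assert_allclose(
            np.abs(spec_lam).max(axis=1), population.specific_loadings, atol=1e-4
        )

    def test_identification_convention_invariance(self, moments600):
        for name in ("one_factor", "four_factor"):
            a = ps.fit_ml(ps.MODEL_FIXTURES[name](), moments600)
            b = ps.fit_ml(
                ps.MODEL_FIXTURES[name](), moments600, identification="marker"
            )
            assert a.discrepancy == pytest.approx(b.discrepancy, abs=1e-8)
            np.testing.assert_allclose(
                a.standardized_loadings, b.standardized_loadings, atol=1e-4
            )

    def test_standardized_solution_identity(self, moments600):
        fit = ps.fit_ml(ps.ikdc_four_factor(), moments600, identification="marker")
        Sigma = fit.implied_covariance
        expect = (
            fit.loadings
            * np.sqrt(np.diag(fit.phi))[None, :]
            / np.sqrt(np.diag(Sigma))[:, None]
        )
        np.testing.assert_allclose(fit.standardized_loadings, expect)

    def test_scale_invariance_of_discrepancy(self, moments600):
        """Rescaling an observed variable leaves F_ML unchanged."""
        fit = ps.fit_ml(ps.ikdc_one_factor(), moments600)
        scale = np.ones(18)
        scale[3] = 3.0
        S2 = moments600.covariance * np.outer(scale, scale)
        mom2 = _moments_from_sigma(S2, n=moments600.n, ids=moments600.item_ids)
        fit2 = ps.fit_ml(ps.ikdc_one_factor(), mom2)
        assert fit.discrepancy == pytest.approx(fit2.discrepancy, abs=1e-8)

    def test_sign_convention(self, moments600):
        fit = ps.fit_ml(ps.ikdc_bifactor(), moments600)
        assert (fit.loadings.sum(axis=0) > 0).all()

    def test_correlated_residual_recovery(self):
        lam = np.full((8, 1), 0.6)
        Sigma = lam @ lam.T
        np.fill_diagonal(Sigma, 1.0)
        Sigma[2, 5] = Sigma[5, 2] = 0.36 + 0.3  # planted residual covariance
        ids = [f"i{k}" for k in range(8)]
        spec = ps.FactorModelSpec(
            name="cr",
            factors=(("g", tuple(ids)),),
            covariance="orthogonal",
            correlated_residuals=(("i2", "i5"),),
        )
        fit = ps.fit_ml(spec, _moments_from_sigma(Sigma, ids=ids))
        assert fit.df == 8 * 9 // 2 - (8 + 8 + 1)
        assert fit.discrepancy < 1e-10
        assert fit.theta[2, 5] == pytest.approx(0.3, abs=1e-4)

    def test_heywood_case_flagged_not_silent(self):
        # inconsistent correlation triad: r_ab * r_ac / r_bc implies a
        # communality of 0.8 * 0.7 / 0.3 = 1.87 for item a, so its residual
        # variance is driven to the boundary
        Sigma = np.array(
            [
                [1.0, 0.8, 0.7, 0.4],
                [0.8, 1.0, 0.3, 0.3],
                [0.7, 0.3, 1.0, 0.3],
                [0.4, 0.3, 0.3, 1.0],
            ]
        )
        ids = ["a", "b", "c", "d"]
        spec = ps.FactorModelSpec(
            name="hw", factors=(("g", tuple(ids)),), covariance="orthogonal"
        )
        with pytest.warns(HeywoodWarning):
            fit = ps.fit_ml(spec, _moments_from_sigma(Sigma, ids=ids))
        assert fit.heywood

    def test_missing_item_in_moments(self, moments600):
        spec = ps.FactorModelSpec(
            name="x", factors=(("g", ("1", "2", "nope")),), covariance="orthogonal"
        )
        with pytest.raises(ConfigurationError, match="nope"):
            ps.fit_ml(spec, moments600)

    def test_fitted_model_json_roundtrip(self, moments600, tmp_path):
        fit = ps.fit_ml(ps.ikdc_bifactor(), moments600)
        path = tmp_path / "fit.json"
        fit.save(path)
        again = ps.FittedModel.load(path)
        np.testing.assert_allclose(again.loadings, fit.loadings)
        assert again.chisq == pytest.approx(fit.chisq)
        assert again.spec == fit.spec


class TestChisqDifference:
    def test_identical_models(self, moments600):
        fit = ps.fit_ml(ps.ikdc_four_factor(), moments600)
        res = ps.chisq_difference_test(fit, fit)
        assert (res.delta_chisq, res.delta_df, res.p_value) == (0.0, 0, 1.0)

    def test_four_factor_vs_bifactor_delta_df(self, moments600):
        nested = ps.fit_ml(ps.ikdc_four_factor(), moments600)
        parent = ps.fit_ml(ps.ikdc_bifactor(), moments600)
        res = ps.chisq_difference_test(nested, parent)
        assert res.delta_df == 12
        assert res.delta_chisq == pytest.approx(nested.chisq - parent.chisq, abs=1e-8)

    def test_wrong_direction_rejected(self, moments600):
        nested = ps.fit_ml(ps.ikdc_four_factor(), moments600)
        parent = ps.fit_ml(ps.ikdc_bifactor(), moments600)
        with pytest.raises(PromstructError):
            ps.chisq_difference_test(parent, nested)


class TestModificationIndices:
    def test_planted_residual_correlation_ranks_first(self):
        lam = np.full((8, 1), 0.6)
        Sigma = lam @ lam.T
        np.fill_diagonal(Sigma, 1.0)
        Sigma[2, 5] = Sigma[5, 2] = 0.36 + 0.35
        ids = [f"i{k}" for k in range(8)]
        spec = ps.FactorModelSpec(name="one", factors=(("g", tuple(ids)),), covariance="orthogonal")
        fit = ps.fit_ml(spec, _moments_from_sigma(Sigma, ids=ids))
        mis = ps.modification_indices(fit, _moments_from_sigma(Sigma, ids=ids))
        assert mis[0].parameter == "i2~~i5"
        assert all(m.expected_chisq_drop >= 0 for m in mis)

    def test_saturated_model_has_none(self):
        Sigma = np.array([[1, 0.49, 0.49], [0.49, 1, 0.49], [0.49, 0.49, 1.0]])
        spec = ps.FactorModelSpec(name="sat", factors=(("g", ("a", "b", "c")),), covariance="orthogonal")
        mom = _moments_from_sigma(Sigma, ids=["a", "b", "c"])
        assert ps.modification_indices(ps.fit_ml(spec, mom), mom) == []

    def test_score_statistic_tracks_actual_chisq_drop(self):
        """Freeing the top-ranked residual pair should drop chi-square by
        roughly the advertised amount."""
        lam = np.full((8, 1), 0.6)
        Sigma = lam @ lam.T
        np.fill_diagonal(Sigma, 1.0)
        Sigma[1, 4] = Sigma[4, 1] = 0.36 + 0.2
        ids = [f"i{k}" for k in range(8)]
        mom = _moments_from_sigma(Sigma, n=500, ids=ids)
        base_spec = ps.FactorModelSpec(name="one", factors=(("g", tuple(ids)),), covariance="orthogonal")
        fit = ps.fit_ml(base_spec, mom)
        mi = ps.modification_indices(fit, mom)[0]
        freed = ps.FactorModelSpec(
            name="one+cr",
            factors=(("g", tuple(ids)),),
            covariance="orthogonal",
            correlated_residuals=(("i1", "i4"),),
        )
        refit = ps.fit_ml(freed, mom)
        actual_drop = fit.chisq - refit.chisq
        assert mi.parameter == "i1~~i4"
        assert mi.expected_chisq_drop == pytest.approx(actual_drop, rel=0.25)


class TestAdequacy:
    def test_clean_model_passes(self, moments600):
        fit = ps.fit_ml(ps.ikdc_bifactor(), moments600)
        ix = ps.compute_indices(fit, moments600)
        report = ps.check_adequacy(fit, ix)
        assert report.passed["loadings"]
        assert report.passed["factor_covariances"]

    def test_low_loading_named(self, bifactor_6item):
        weak = bifactor_6item
        weak.loadings = weak.loadings.copy()
        weak.loadings[0, 0] = 0.1  # item "a" under the 0.3 floor
        report = ps.check_adequacy(weak)
        assert not report.passed["loadings"]
        assert report.offending_loadings[0][0] == "a"

    def test_excessive_factor_correlation_flagged(self, moments600):
        spec = ps.ikdc_four_factor()
        fit = ps.fit_ml(spec, moments600)
        fit.phi = fit.phi.copy()
        fit.phi[0, 1] = fit.phi[1, 0] = 0.9
        report = ps.check_adequacy(fit)
        assert not report.passed["factor_covariances"]
        assert ("symptoms", "activity") in [
            (a, b) for a, b, _ in report.offending_covariances
        ]
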