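import numpy as np
import pytest

import promstruct as ps
from promstruct.errors import ConfigurationError


def _bifactor_model(lam_g, groups, theta=None, n=500):
    """Build a FittedModel directly from standardized truth parameters.

    ``groups`` maps factor name -> (item indices, specific loadings).
    """
    p = len(lam_g)
    ids = [f"i{k}" for k in range(p)]
    k = 1 + len(groups)
    lam = np.zeros((p, k))
    lam[:, 0] = lam_g
    factors = [("g", tuple(ids))]
    for c, (name, (rows, ls)) in enumerate(groups.items(), start=1):
        lam[rows, c] = ls
        factors.append((name, tuple(ids[r] for r in rows)))
    if theta is None:
        theta = 1.0 - np.sum(lam**2, axis=1)
    spec = ps.FactorModelSpec(
        name="bi",
        factors=tuple(factors),
        covariance="orthogonal",
        general_factor="g",
        item_order=tuple(ids),
    )
    return ps.FittedModel(
        spec=spec,
        item_ids=ids,
        loadings=lam,
        phi=np.eye(k),
        theta=np.diag(theta),
        discrepancy=0.0,
        df=0,
        n_free_parameters=spec.n_free_parameters(),
        n_obs=n,
    )


class TestWorkedFixture:
    """6 items, lambda_g = 0.6, lambda_s = 0.4, theta = 0.48; all expected
    values recomputed inline by direct summation."""

    def test_omega_total(self, bifactor_6item):
        om = ps.omega_total(bifactor_6item)
        num = (6 * 0.6) ** 2 + 2 * (3 * 0.4) ** 2
        assert om["general"] == pytest.approx(num / (num + 6 * 0.48), abs=1e-12)
        sub_num = (3 * 0.6) ** 2 + (3 * 0.4) ** 2
        assert om["s1"] == pytest.approx(sub_num / (sub_num + 3 * 0.48), abs=1e-12)

    def test_omega_hierarchical(self, bifactor_6item):
        om_h = ps.omega_hierarchical(bifactor_6item)
        num = (6 * 0.6) ** 2 + 2 * (3 * 0.4) ** 2
        assert om_h["general"] == pytest.approx((6 * 0.6) ** 2 / (num + 6 * 0.48), abs=1e-12)
        sub_den = (3 * 0.6) ** 2 + (3 * 0.4) ** 2 + 3 * 0.48
        assert om_h["s1"] == pytest.approx((3 * 0.4) ** 2 / sub_den, abs=1e-12)

    def test_relative_omega_is_ratio(self, bifactor_6item):
        om = ps.omega_total(bifactor_6item)
        om_h = ps.omega_hierarchical(bifactor_6item)
        om_r = ps.relative_omega(om, om_h)
        for key in om:
            assert om_r[key] * om[key] == pytest.approx(om_h[key], abs=1e-12)

    def test_ecv_by_direct_summation(self, bifactor_6item):
        ev = ps.ecv(bifactor_6item)
        g2 = 6 * 0.36
        s2 = 3 * 0.16
        assert ev["general"] == pytest.approx(g2 / (g2 + 2 * s2), abs=1e-12)
        assert sum(ev.values()) == pytest.approx(1.0, abs=1e-12)

    def test_factor_determinacy_by_matrix_oracle(self, bifactor_6item):
        """Independent linear-algebra route: FD = sqrt(diag(L' Sigma^-1 L))
        for orthogonal factors with unit variance."""
        fd = ps.factor_determinacy(bifactor_6item)
        lam = bifactor_6item.loadings
        Sigma = lam @ lam.T + np.diag(np.full(6, 0.48))
        expect = np.sqrt(np.diag(lam.T @ np.linalg.inv(Sigma) @ lam))
        assert fd["general"] == pytest.approx(expect[0], abs=1e-12)
        assert fd["s1"] == pytest.approx(expect[1], abs=1e-12)


class TestLimitCases:
    def test_no_specific_variance_collapses_to_unidimensional(self):
        model = _bifactor_model(
            np.full(6, 0.7),
            {"s1": ([0, 1, 2], 0.0), "s2": ([3, 4, 5], 0.0)},
        )
        om = ps.omega_total(model)
        om_h = ps.omega_hierarchical(model)
        assert om_h["general"] == pytest.approx(om["general"], abs=1e-12)
        assert ps.ecv(model)["general"] == pytest.approx(1.0, abs=1e-12)

    def test_error_free_items_give_unit_omega(self):
        model = _bifactor_model(
            np.full(6, 0.8),
            {"s1": ([0, 1, 2], 0.6), "s2": ([3, 4, 5], 0.6)},
        )
        assert np.allclose(np.diag(model.theta), 0.0)
        assert ps.omega_total(model)["general"] == pytest.approx(1.0, abs=1e-12)

    def test_zero_loadings_give_zero_omega_and_fd(self):
        model = _bifactor_model(
            np.zeros(6), {"s1": ([0, 1, 2], 0.0), "s2": ([3, 4, 5], 0.0)}
        )
        assert ps.omega_total(model)["general"] == 0.0
        assert ps.factor_determinacy(model)["general"] == 0.0

    def test_relative_omega_undefined_at_zero(self):
        assert np.isnan(ps.relative_omega(0.0, 0.0))

    def test_non_bifactor_model_rejected(self, moments600):
        fit = ps.fit_ml(ps.ikdc_four_factor(), moments600)
        with pytest.raises(ConfigurationError, match="bifactor"):
            ps.report_table(fit)


class TestPuc:
    def test_ikdc_partition(self):
        assert round(ps.puc(ps.ikdc_bifactor()), 3) == 0.778

    def test_single_group_is_zero(self):
        model = _bifactor_model(np.full(4, 0.6), {"s1": ([0, 1, 2, 3], 0.3)})
        assert ps.puc(model.spec) == 0.0

    def test_singleton_groups_is_one(self):
        groups = {f"s{k}": ([k], 0.3) for k in range(5)}
        model = _bifactor_model(np.full(5, 0.6), groups)
        assert ps.puc(model.spec) == 1.0

    def test_structure_only(self):
        """PUC ignores the estimates entirely."""
        a = _bifactor_model(np.full(6, 0.3), {"s1": ([0, 1, 2], 0.2), "s2": ([3, 4, 5], 0.2)})
        b = _bifactor_model(np.full(6, 0.8), {"s1": ([0, 1, 2], 0.5), "s2": ([3, 4, 5], 0.3)})
        assert ps.puc(a.spec) == ps.puc(b.spec)


class TestPublishedArithmetic:
    def test_relative_omega_from_published_inputs(self):
        assert round(ps.relative_omega(0.932, 0.810), 3) == 0.869

    def test_variance_decomposition(self):
        parts = ps.variance_decomposition(0.93, 0.81)
        assert parts["error_pct"] == pytest.approx(7.0)
        assert parts["specific_pct"] == pytest.approx(12.0)


def _random_admissible_model(rng):
    n_groups = int(rng.integers(2, 5))
    sizes = rng.integers(2, 6, n_groups)
    p = int(sizes.sum())
    lam_g = rng.uniform(0.2, 0.75, p)
    groups = {}
    start = 0
    for g in range(n_groups):
        rows = list(range(start, start + sizes[g]))
        cap = np.sqrt(1 - lam_g[rows] ** 2)
        groups[f"s{g}"] = (rows, rng.uniform(0.1, 0.9) * cap)
        start += sizes[g]
    return _bifactor_model(lam_g, groups)


class TestIdentityBattery:
    def test_index_identities_on_random_models(self):
        """On random admissible bifactor parameterizations: omega_H <= omega,
        omega_R * omega = omega_H, ECV sums to 1, PUC and FD in [0, 1]."""
        rng = np.random.default_rng(123)
        for _ in range(60):
            model = _random_admissible_model(rng)
            om = ps.omega_total(model)
            om_h = ps.omega_hierarchical(model)
            om_r = ps.relative_omega(om, om_h)
            ev = ps.ecv(model)
            fd = ps.factor_determinacy(model)
            for key in om:
                assert 0.0 <= om_h[key] <= om[key] <= 1.0
                assert om_r[key] * om[key] == pytest.approx(om_h[key], abs=1e-12)
            assert sum(ev.values()) == pytest.approx(1.0, abs=1e-12)
            assert 0.0 <= ps.puc(model.spec) <= 1.0
            assert all(0.0 <= v <= 1.0 for v in fd.values())


class TestReportTable:
    def test_truth_parameters_report(self, population):
        mom_sigma = population.implied_covariance()
        mom = ps.SampleMoments(
            mom_sigma, mom_sigma, np.zeros(18), 606, list(population.item_ids)
        )
        fit = ps.fit_ml(population.model_spec(), mom)
        rep = ps.report_table(fit)
        assert rep.factor_order[0] == "general"
        assert sum(rep.ecv.values()) == pytest.approx(1.0, abs=1e-10)
        df = rep.to_dataframe(decimals=3)
        assert list(df["factor"]) == rep.factor_order

    def test_simulated_cohort_recovers_population_limit_report(self, population):
        """At N = 5000 the index report sits within 0.05 of its ordinal-scale
        population limit (approximated by a 100k cohort). The latent-scale
        truth differs additionally by the discretization attenuation, which
        is a property of the continuous-ML treatment of ordinal codes, not of
        the estimator."""
        limit_data = ps.simulate(ps.SimulationConfig(100000, 76, population))
        limit_rep = ps.report_table(
            ps.fit_ml(population.model_spec(), ps.sample_moments(limit_data))
        )
        data = ps.simulate(ps.SimulationConfig(5000, 77, population))
        fit = ps.fit_ml(population.model_spec(), ps.sample_moments(data))
        rep = ps.report_table(fit)
        for key in limit_rep.omega:
            assert rep.omega[key] == pytest.approx(limit_rep.omega[key], abs=0.05)
            assert rep.omega_hierarchical[key] == pytest.approx(
                limit_rep.omega_hierarchical[key], abs=0.05
            )

    def test_strong_general_factor_flagged_essentially_unidimensional(self):
        model = _bifactor_model(
            np.full(12, 0.75),
            {"s1": ([0, 1, 2, 3], 0.3), "s2": ([4, 5, 6, 7], 0.3), "s3": ([8, 9, 10, 11], 0.3)},
        )
        rep = ps.report_table(model)
        assert rep.essentially_unidimensional
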