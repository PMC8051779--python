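"""Quadratic response-surface fitting, ANOVA decomposition, adequacy."""

import numpy as np
import pytest

import phytorsm as pr
from phytorsm.rsm import FitError, ModelSpec, predict_many, term_names


def normal_equations_fit(X, y):
    """Brute-force OLS oracle: solve X'X b = X'y directly."""
    return np.linalg.solve(X.T @ X, X.T @ y)


def build_matrix_by_hand(data, include_block=True):
    """Assemble the blocked full-quadratic design matrix with plain loops,
    independently of the package's column builder."""
    x = data.design.coded_matrix()
    n, k = x.shape
    cols = [np.ones(n)]
    if include_block:
        cols.append(np.where(data.design.blocks() == 1, 1.0, -1.0))
    for j in range(k):
        cols.append(x[:, j])
    for i in range(k):
        for j in range(i + 1, k):
            cols.append(x[:, i] * x[:, j])
    for j in range(k):
        cols.append(x[:, j] ** 2)
    return np.column_stack(cols)


class TestFitQuadratic:
    def test_noiseless_simulation_recovers_generating_coefficients(self, design, surface_truth):
        truth = pr.SurfaceTruth(surface_truth.coefficients, noise_sd=0.0)
        data = pr.simulate_ccrd(design, truth, seed=3)
        m = pr.fit_quadratic(data)
        for term, b in truth.coefficients.items():
            assert m.coefficients[term] == pytest.approx(b, abs=1e-8)
        assert m.block_effects[1] == pytest.approx(0.0, abs=1e-8)

    def test_matches_normal_equations_oracle_on_published_runs(self, tpc_data):
        m = pr.fit_quadratic(tpc_data)
        X = build_matrix_by_hand(tpc_data)
        beta = normal_equations_fit(X, tpc_data.response)
        k = 3
        expected = dict(zip(["Intercept", "Block"] + term_names(k)[:k]
                            + [t for t in term_names(k) if len(t) == 2]
                            + [t for t in term_names(k) if t.endswith("^2")], beta))
        # column order above: intercept, block, linear, interactions, squares
        for t in ["Intercept"] + term_names(k):
            assert m.coefficients[t] == pytest.approx(expected[t], abs=1e-8)
        assert m.block_effects[1] == pytest.approx(expected["Block"], abs=1e-8)

    def test_fitted_plus_residuals_reproduce_observations(self, tpc_data):
        m = pr.fit_quadratic(tpc_data)
        np.testing.assert_allclose(m.fitted + m.residuals, tpc_data.response, atol=1e-10)

    def test_residuals_orthogonal_to_model_columns(self, tpc_data):
        m = pr.fit_quadratic(tpc_data)
        X = build_matrix_by_hand(tpc_data)
        np.testing.assert_allclose(X.T @ m.residuals, 0.0, atol=1e-8)

    def test_singular_fit_names_collinear_terms(self, factors):
        # duplicate centre-only design: squares are collinear with intercept
        d = pr.build_ccrd(factors, {1: 10, 2: 10}, seed=0)
        keep = [p for p in d.points if p.point_class != "factorial"]
        import dataclasses

        d2 = dataclasses.replace(d, points=tuple(keep))
        y = np.ones(len(keep))
        data = pr.ResponseData(design=d2, response=y)
        with pytest.raises(FitError, match="singular|n > p"):
            pr.fit_quadratic(data)

    def test_hierarchy_enforced(self):
        with pytest.raises(FitError, match="hierarchy"):
            ModelSpec(terms=("A", "B^2"))


class TestPredict:
    def test_published_optimum_prediction(self, printed_model):
        """The published equation at coded (-1, +1, +1) predicts ~22.163."""
        y = pr.predict(printed_model, [-1.0, 1.0, 1.0])
        assert y == pytest.approx(22.1659, abs=1e-9)   # exact printed arithmetic
        assert y == pytest.approx(22.163, abs=0.01)    # published rounded value

    def test_centre_prediction_is_intercept(self, printed_model):
        assert pr.predict(printed_model, [0, 0, 0]) == pytest.approx(14.75)

    def test_hand_evaluated_point(self, printed_model):
        assert pr.predict(printed_model, [1, -1, -1]) == pytest.approx(14.1733, abs=1e-9)

    def test_dimension_contract(self, printed_model):
        with pytest.raises(FitError):
            pr.predict(printed_model, [0.0, 0.0])

    def test_predict_many_consistent(self, printed_model):
        pts = np.random.default_rng(0).uniform(-1, 1, size=(50, 3))
        vec = predict_many(printed_model, pts)
        for p, v in zip(pts, vec):
            assert pr.predict(printed_model, p) == pytest.approx(v, abs=1e-12)


class TestFRatioAndR2:
    def test_lack_of_fit_row_arithmetic(self):
        f, p = pr.f_ratio(39.94, 5, 12.31, 4)
        assert f == pytest.approx(2.60, abs=0.01)
        assert p == pytest.approx(0.188, abs=0.005)

    def test_temperature_row_arithmetic(self):
        f, p = pr.f_ratio(55.69, 1, 52.25, 9)
        assert f == pytest.approx(9.59, abs=0.01)
        assert p == pytest.approx(0.0128, abs=0.0005)

    def test_equal_mean_squares_give_unit_f(self):
        f, _ = pr.f_ratio(10.0, 2, 15.0, 3)
        assert f == pytest.approx(1.0)

    def test_zero_denominator_flags_infinite_f(self):
        f, p = pr.f_ratio(1.0, 1, 0.0, 4)
        assert np.isinf(f) and p == 0.0

    def test_r_squared_published_value(self):
        assert pr.r_squared(299.84, 52.25) == pytest.approx(0.8516, abs=0.0005)

    @pytest.mark.parametrize("ssm,ssr,expected", [(3.7, 0.0, 1.0), (0.0, 2.2, 0.0)])
    def test_r_squared_limits(self, ssm, ssr, expected):
        assert pr.r_squared(ssm, ssr) == expected

    def test_r_squared_undefined(self):
        with pytest.raises(FitError):
            pr.r_squared(0.0, 0.0)


class TestPureError:
    def test_no_replicates_puts_all_residual_in_lack_of_fit(self, factors):
        # without centre runs the block indicator is collinear with the
        # square terms, so fit block-free
        d = pr.build_ccrd(factors, {1: 0, 2: 0}, seed=0)
        data = pr.simulate_ccrd(d, pr.default_surface_truth(), seed=5)
        m = pr.fit_quadratic(data, ModelSpec.full_quadratic(3, include_block=False))
        ss_r = float(m.residuals @ m.residuals)
        df_r = data.design.n_runs - m.p_params
        ss_pe, df_pe, ss_lof, df_lof = pr.pure_error_split(data, ss_r, df_r)
        assert (ss_pe, df_pe) == (0.0, 0)
        assert ss_lof == pytest.approx(ss_r)
        assert df_lof == df_r

    def test_published_centre_rows_within_block(self, tpc_data):
        """Brute-force within-block SS over the six printed centre runs is
        ~3.09 with 4 df — a documented mismatch with the published 12.31."""
        m = pr.fit_quadratic(tpc_data)
        ss_r = float(m.residuals @ m.residuals)
        ss_pe, df_pe, _, _ = pr.pure_error_split(tpc_data, ss_r, 20 - m.p_params)
        assert ss_pe == pytest.approx(3.088, abs=0.005)
        assert df_pe == 4

    def test_pooling_across_blocks_adds_between_block_centre_spread(self, tpc_data):
        m = pr.fit_quadratic(tpc_data)
        ss_r = float(m.residuals @ m.residuals)
        ss_pe, df_pe, _, _ = pr.pure_error_split(
            tpc_data, ss_r, 20 - m.p_params, policy="across_blocks"
        )
        assert ss_pe == pytest.approx(6.088, abs=0.005)
        assert df_pe == 5

    def test_ms_pe_estimates_noise_variance_unbiasedly(self, design, surface_truth):
        """Mean pure-error MS over 500 seeded simulations tracks the
        generating variance 5.81 within 5%."""
        vals = []
        for s in range(500):
            data = pr.simulate_ccrd(design, surface_truth, seed=77_000 + s)
            m = pr.fit_quadratic(data)
            ss_r = float(m.residuals @ m.residuals)
            ss_pe, df_pe, _, _ = pr.pure_error_split(data, ss_r, 20 - m.p_params)
            vals.append(ss_pe / df_pe)
        assert np.mean(vals) == pytest.approx(5.81, rel=0.05)


class TestAnova:
    def test_additivity_and_df_bookkeeping(self, design, surface_truth):
        data = pr.simulate_ccrd(design, surface_truth, seed=11)
        m = pr.fit_quadratic(data)
        tab = pr.anova(m, data)
        total = tab.ss("corrected_total")
        assert tab.ss("block") + tab.ss("model") + tab.ss("residual") == pytest.approx(
            total, rel=1e-8
        )
        assert tab.ss("lack_of_fit") + tab.ss("pure_error") == pytest.approx(
            tab.ss("residual"), rel=1e-8
        )
        assert tab.df("lack_of_fit") + tab.df("pure_error") == tab.df("residual")
        assert tab.df("block") + tab.df("model") + tab.df("residual") == tab.df(
            "corrected_total"
        )

    def test_ms_equals_ss_over_df(self, tpc_data):
        m = pr.fit_quadratic(tpc_data)
        tab = pr.anova(m, tpc_data).table
        rows = tab[(tab["df"] > 0) & tab["ms"].notna()]
        np.testing.assert_allclose(rows["ms"], rows["ss"] / rows["df"], rtol=1e-10)

    def test_single_df_ss_matches_contrast_arithmetic(self, tpc_data):
        """On the near-orthogonal CCRD, a linear term's partial SS is
        ~b^2 * sum(x^2); with the published b_B = 2.02 and
        sum(x^2) = 8 + 2*alpha^2 = 13.657 this arithmetic gives ~55.7,
        consistent with the published 55.69 temperature SS."""
        assert 2.02**2 * 13.657 == pytest.approx(55.69, rel=0.01)
        m = pr.fit_quadratic(tpc_data)
        tab = pr.anova(m, tpc_data)
        x = tpc_data.design.coded_matrix()
        b = m.coefficients["B"]
        assert tab.ss("B") == pytest.approx(b**2 * float((x[:, 1] ** 2).sum()), rel=0.01)

    def test_lack_of_fit_tested_against_pure_error(self, tpc_data):
        m = pr.fit_quadratic(tpc_data)
        tab = pr.anova(m, tpc_data)
        lof = tab.row("lack_of_fit")
        pe = tab.row("pure_error")
        assert lof["f"] == pytest.approx((lof["ss"] / lof["df"]) / (pe["ss"] / pe["df"]))


class TestAdequacy:
    def test_constant_surface_zero_signal(self, factors):
        d = pr.build_ccrd(factors, {1: 4, 2: 2}, seed=0)
        truth = pr.SurfaceTruth({"Intercept": 5.0}, noise_sd=1.0)
        data = pr.simulate_ccrd(d, truth, seed=9)
        m = pr.fit_quadratic(data, ModelSpec(terms=(), include_block=False))
        # intercept-only fit: every prediction identical
        assert pr.adequate_precision(m, data) == pytest.approx(0.0, abs=1e-9)

    def test_formula_matches_direct_reevaluation(self, tpc_data):
        m = pr.fit_quadratic(tpc_data)
        expected = (m.fitted.max() - m.fitted.min()) / np.sqrt(
            m.p_params * m.mse / m.n
        )
        assert pr.adequate_precision(m, tpc_data) == pytest.approx(expected, abs=1e-10)

    def test_doubling_noise_roughly_halves_adequate_precision(self, design, surface_truth):
        coef = surface_truth.coefficients

        def mean_adeq(sd):
            vals = []
            for s in range(200):
                data = pr.simulate_ccrd(design, pr.SurfaceTruth(coef, noise_sd=sd), seed=s)
                m = pr.fit_quadratic(data)
                vals.append(pr.adequate_precision(m, data))
            return np.mean(vals)

        ratio = mean_adeq(2.0) / mean_adeq(4.0)
        assert ratio == pytest.approx(2.0, rel=0.25)

    def test_adjusted_r2_below_r2(self, tpc_data):
        m = pr.fit_quadratic(tpc_data)
        a = pr.adequacy(m, tpc_data)
        assert a.adj_r2 <= a.r2 <= 1.0


class TestParameterRecovery:
    def test_refit_means_unbiased_over_seeded_simulations(self, design, surface_truth):
        """500 simulations at the published noise level: every mean
        refitted coefficient falls within 2 Monte-Carlo SEs of truth."""
        seeds = np.random.default_rng(0).integers(0, 2**31 - 1, size=500)
        names = ["Intercept"] + term_names(3)
        est = np.array(
            [
                [pr.fit_quadratic(pr.simulate_ccrd(design, surface_truth, seed=int(s))).coefficients[t]
                 for t in names]
                for s in seeds
            ]
        )
        mean = est.mean(axis=0)
        se = est.std(axis=0, ddof=1) / np.sqrt(len(seeds))
        truth = np.array([surface_truth.coefficients[t] for t in names])
        assert np.all(np.abs(mean - truth) <= 2 * se)
        # the temperature coefficient mean sits at the generating 2.02
        b_idx = names.index("B")
        assert mean[b_idx] == pytest.approx(2.02, abs=2 * se[b_idx])


class TestSurfaceGrid:
    def test_grid_cardinality_and_consistency(self, printed_model):
        g = pr.surface_grid(printed_model, (0, 1), {2: 0.5}, resolution=25)
        assert len(g) == 625
        row = g.iloc[137]
        assert pr.predict(printed_model, [row.x1, row.x2, 0.5]) == pytest.approx(
            row.yhat, abs=1e-12
        )

    def test_overlapping_indices_rejected(self, printed_model):
        with pytest.raises(FitError):
            pr.surface_grid(printed_model, (0, 1), {1: 0.0, 2: 0.0}, resolution=5)

    def test_resolution_contract(self, printed_model):
        with pytest.raises(FitError):
            pr.surface_grid(printed_model, (0, 1), {2: 0.0}, resolution=1)


def test_coded_equation_renders(printed_model):
    s = pr.coded_equation(printed_model)
    assert s.startswith("14.75") and "*AB" in s
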