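"""REML engine: likelihood, gradients, fits, EBLUPs, criteria."""

import numpy as np
import pandas as pd
import pytest

from metfa.data import Environment, METData
from metfa.errors import SpecError, ValidationError
from metfa.reml import (
    FitControl,
    _Core,
    _env_labels,
    build_design,
    component_blups,
    fa_eblups,
    info_criteria,
    reml_fit,
    remlrt,
    residual_loglik,
)
from metfa.variance import FAParameters, PeripheralTerm, VarianceModelSpec

from _oracle import brute_force_fit, dense_loglik
from conftest import make_met


def single_env(ys, ws):
    envs = [Environment("A_2020", "A", 2020, "R1")]
    rec = pd.DataFrame(
        {"variety": [f"v{i}" for i in range(len(ys))], "env_id": "A_2020",
         "mean": ys, "weight": ws}
    )
    return METData(envs, rec)


class TestBuildDesign:
    def test_complete_two_by_two_z_is_permutation(self):
        data, _ = make_met(t=2, m=2, seed=0)
        X, Z, Sigma = build_design(data)
        Zd = Z.toarray()
        assert Zd.shape == (4, 4)
        assert (Zd.sum(axis=0) == 1).all() and (Zd.sum(axis=1) == 1).all()

    def test_sigma_is_reciprocal_weight(self):
        data = single_env([1.0, 2.0], [4.0, 2.0])
        _, _, Sigma = build_design(data)
        np.testing.assert_allclose(np.diag(Sigma), [0.25, 0.5])

    def test_missing_cell_leaves_zero_column(self):
        data, _ = make_met(t=2, m=2, seed=0)
        rec = data.records[~((data.records["variety"] == "v01") & (data.records["env_id"] == data.env_ids[1]))]
        data2 = METData(data.environments, rec)
        X, Z, _ = build_design(data2)
        Zd = Z.toarray()
        assert Zd.shape == (3, 4)
        assert (Zd.sum(axis=0) == 0).sum() == 1  # exactly one empty cell


class TestResidualLoglik:
    def test_matches_dense_oracle_all_structures(self, met_missing):
        data = met_missing
        t = data.t
        rng = np.random.default_rng(3)
        L = rng.normal(0, 0.5, (t, 2))
        cases = [
            (VarianceModelSpec.diag(), {"gvar": rng.uniform(0.1, 0.5, t)}),
            (VarianceModelSpec.cs(), {"sigma2_g": 0.2, "sigma2_ge": 0.1}),
            (VarianceModelSpec.fa(1), FAParameters(L[:, :1], rng.uniform(0.05, 0.2, t))),
            (VarianceModelSpec.fa(2), FAParameters(np.tril(L), rng.uniform(0.05, 0.2, t))),
            (VarianceModelSpec.us(), {"G": L @ L.T + 0.3 * np.eye(t)}),
        ]
        for spec, params in cases:
            struct = spec.structure(t, _env_labels(data))
            G = struct.unpack(struct.pack(params))
            assert residual_loglik(params, data, spec) == pytest.approx(
                dense_loglik(data, G), abs=1e-8
            )

    def test_one_environment_equal_weights_closed_form(self):
        # y ~ N(tau 1, (s2 + 1/w) I): REML loglik of the one-way model
        ys, w = np.array([1.0, 2.4, 3.1, 4.2]), 2.5
        data = single_env(ys, [w] * 4)
        s2 = 0.7
        v = s2 + 1 / w
        n = 4
        expected = -0.5 * (
            (n - 1) * np.log(2 * np.pi) + n * np.log(v) + np.log(n / v)
            + np.sum((ys - ys.mean()) ** 2) / v
        )
        got = residual_loglik({"gvar": np.array([s2])}, data, VarianceModelSpec.diag())
        assert got == pytest.approx(expected, abs=1e-10)

    def test_scale_equivariance(self, met_small):
        # scaling y, loadings, sqrt(psi) and sqrt(Sigma) by c shifts the
        # log-likelihood by -(n - t) log c
        data = met_small
        t, n = data.t, data.n
        rng = np.random.default_rng(0)
        fa = FAParameters(rng.normal(0, 0.4, (t, 1)), rng.uniform(0.05, 0.2, t))
        base = residual_loglik(fa, data, VarianceModelSpec.fa(1))
        c = 3.7
        rec = data.records.copy()
        rec["mean"] *= c
        rec["weight"] /= c**2
        scaled_data = METData(data.environments, rec)
        fa_c = FAParameters(c * fa.loadings, c**2 * fa.specific_variances)
        scaled = residual_loglik(fa_c, scaled_data, VarianceModelSpec.fa(1))
        assert scaled - base == pytest.approx(-(n - t) * np.log(c), abs=1e-8)

    def test_gradient_matches_finite_differences(self, met_missing):
        data = met_missing
        core = _Core(data)
        rng = np.random.default_rng(1)
        for spec in [
            VarianceModelSpec.diag(), VarianceModelSpec.cs(),
            VarianceModelSpec.vc(("region", "year")),
            VarianceModelSpec.fa(2), VarianceModelSpec.us(),
        ]:
            struct = spec.structure(data.t, _env_labels(data))
            theta = struct.inits(core.sigma2_moment, rng)[0]
            theta = theta + 0.05 * rng.standard_normal(theta.size)
            res = core.loglik(struct.unpack(theta), want_grad=True)
            g = struct.grad(theta, res["M"])
            num = np.zeros_like(theta)
            for i in range(len(theta)):
                e = np.zeros_like(theta)
                e[i] = 1e-6
                num[i] = (
                    core.loglik(struct.unpack(theta + e))["ll"]
                    - core.loglik(struct.unpack(theta - e))["ll"]
                ) / 2e-6
            np.testing.assert_allclose(g, num, atol=5e-6, err_msg=spec.label())


class TestRemlFitClosedForms:
    def test_single_env_infinite_weights_sample_variance(self):
        fit = reml_fit(single_env([1.0, 2.0, 3.0, 4.0], [1e10] * 4), VarianceModelSpec.diag())
        assert fit.params["gvar"][0] == pytest.approx(5 / 3, abs=1e-6)

    def test_single_env_finite_weights_shrunk_variance(self):
        fit = reml_fit(single_env([1.0, 2.0, 3.0, 4.0], [2.0] * 4), VarianceModelSpec.diag())
        assert fit.params["gvar"][0] == pytest.approx(5 / 3 - 0.5, abs=1e-8)

    def test_single_env_variance_floored_at_zero(self):
        # sample variance below the known error variance: estimate pinned ~0
        fit = reml_fit(single_env([2.0, 2.01, 1.99, 2.0], [0.1] * 4), VarianceModelSpec.diag())
        assert fit.params["gvar"][0] <= 1e-6

    def test_eblup_shrinkage_closed_form(self):
        ys, w = np.array([1.0, 2.0, 3.0, 4.0]), 2.0
        fit = reml_fit(single_env(ys, [w] * 4), VarianceModelSpec.diag())
        s2 = fit.params["gvar"][0]
        shrink = s2 / (s2 + 1 / w)
        np.testing.assert_allclose(
            fit.u_blup.to_numpy().ravel(), (ys - ys.mean()) * shrink, atol=1e-8
        )

    def test_cs_assembly_exact(self, met_small):
        fit = reml_fit(met_small, VarianceModelSpec.cs())
        s2g, s2ge = fit.params["sigma2_g"], fit.params["sigma2_ge"]
        t = met_small.t
        np.testing.assert_allclose(
            fit.G.to_numpy(), s2g * np.ones((t, t)) + s2ge * np.eye(t), atol=1e-12
        )

    def test_fa_order_must_be_below_t(self, met_small):
        with pytest.raises(SpecError):
            reml_fit(met_small, VarianceModelSpec.fa(met_small.t))


class TestOracleEquivalence:
    @pytest.mark.parametrize("kind,k", [("DIAG", 0), ("CS", 0), ("FA", 1), ("US", 0)])
    def test_matches_brute_force_optimum(self, kind, k):
        data, _ = make_met(t=3, m=10, seed=7, frac_missing=0.2)
        spec = {"DIAG": VarianceModelSpec.diag(), "CS": VarianceModelSpec.cs(),
                "FA": VarianceModelSpec.fa(1), "US": VarianceModelSpec.us()}[kind]
        fit = reml_fit(data, spec, control=FitControl(extra_restarts=2))
        oracle = brute_force_fit(data, kind, k=max(k, 1), n_restarts=10, seed=1)
        assert fit.residual_loglik >= oracle["loglik"] - 1e-4
        if kind in ("DIAG", "CS"):
            np.testing.assert_allclose(
                np.diag(fit.G.to_numpy()), np.diag(oracle["G"]), atol=1e-3
            )


class TestFaProperties:
    def test_loglik_invariant_under_rotation(self, met_missing):
        fit = reml_fit(met_missing, VarianceModelSpec.fa(2))
        fa = fit.fa_parameters()
        ang = 0.6
        Q = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        rotated = FAParameters(fa.loadings @ Q, fa.specific_variances)
        ll_rot = residual_loglik(rotated, met_missing, VarianceModelSpec.fa(2))
        assert ll_rot == pytest.approx(fit.residual_loglik, abs=1e-8)

    def test_constraint_mask_entries_zero(self, met_missing):
        fit = reml_fit(met_missing, VarianceModelSpec.fa(2))
        fa = fit.fa_parameters()
        assert np.all(fa.loadings[fa.constraint_mask] == 0.0)

    def test_eq7_reassembly_exact(self, met_missing):
        fit = reml_fit(met_missing, VarianceModelSpec.fa(1))
        fa = fit.fa_parameters()
        u = fit.scores.to_numpy() @ fa.loadings.T + fit.delta.to_numpy()
        np.testing.assert_allclose(u, fit.u_blup.to_numpy(), atol=1e-12)

    def test_pev_decreases_with_weight(self):
        # raising one record's weight lowers that cell's prediction PEV
        base, _ = make_met(t=2, m=6, seed=9)
        fa = FAParameters(np.array([[0.5], [0.4]]), np.array([0.05, 0.08]))
        pevs = []
        for w in (1.0, 5.0, 50.0):
            rec = base.records.copy()
            sel = (rec["variety"] == "v00") & (rec["env_id"] == base.env_ids[0])
            rec.loc[sel, "weight"] = w
            ebl = fa_eblups(METData(base.environments, rec), fa.loadings, fa.specific_variances)
            i = list(ebl["u"].index).index("v00")
            pevs.append(ebl["u_blocks"][i, 0, 0])
        assert pevs[0] > pevs[1] > pevs[2]

    def test_fixed_parameter_eblups_match_fit(self, met_missing):
        fit = reml_fit(met_missing, VarianceModelSpec.fa(1))
        fa = fit.fa_parameters()
        ebl = fa_eblups(met_missing, fa.loadings, fa.specific_variances)
        pd.testing.assert_frame_equal(ebl["scores"], fit.scores)
        np.testing.assert_allclose(ebl["f_blocks"], fit.pev["f_blocks"], atol=1e-12)


class TestVcAndPeripheral:
    def test_vc_fit_block_correlation_structure(self):
        data, _ = make_met(t=6, m=20, seed=11, regions=["R1"] * 3 + ["R2"] * 3,
                           years=[2020, 2021, 2022] * 2)
        fit = reml_fit(data, VarianceModelSpec.vc(("region", "year")))
        G = fit.G.to_numpy()
        p = fit.params
        # covariance of two environments sharing only the region
        expected = p["sigma2_main"] + p["sigma2_region"]
        assert G[0, 1] == pytest.approx(expected, abs=1e-8)

    def test_component_blups_reassemble_cs_totals(self, met_small):
        fit = reml_fit(met_small, VarianceModelSpec.cs())
        comp = component_blups(fit, met_small)
        total = comp["main"]["effect"].to_numpy()[:, None] + comp["interaction"].to_numpy()
        np.testing.assert_allclose(total, fit.u_blup.to_numpy(), atol=1e-10)

    def test_peripheral_year_term_runs_and_is_nonnegative(self):
        data, _ = make_met(t=4, m=8, seed=13, years=[2020, 2020, 2021, 2021])
        spec = VarianceModelSpec.cs(peripheral_terms=(PeripheralTerm("year"),))
        fit = reml_fit(data, spec)
        assert fit.peripheral["year"] >= 0
        assert np.isfinite(fit.residual_loglik)
        assert fit.n_params == 3


class TestCriteriaAndTests:
    def test_aic_bic_formulas(self, met_small):
        fit = reml_fit(met_small, VarianceModelSpec.diag())
        aic, bic = info_criteria(fit)
        ll, p = fit.residual_loglik, fit.n_params
        assert aic == pytest.approx(-2 * ll + 2 * p)
        assert bic == pytest.approx(-2 * ll + p * np.log(fit.n - fit.t))

    def test_bic_with_explicit_residual_df(self, met_small):
        fit = reml_fit(met_small, VarianceModelSpec.cs())
        _, bic = info_criteria(fit, residual_df=int(np.e**2))
        # log(e^2 rounded to 7) fixes the penalty scale
        assert bic == pytest.approx(-2 * fit.residual_loglik + 2 * np.log(7))

    def test_nonpositive_residual_df_rejected(self, met_small):
        fit = reml_fit(met_small, VarianceModelSpec.diag())
        with pytest.raises(ValidationError):
            info_criteria(fit, residual_df=0)

    def test_remlrt_identical_fits(self, met_small):
        fit = reml_fit(met_small, VarianceModelSpec.fa(1))
        stat, df, p = remlrt(fit, fit)
        assert (stat, df, p) == (0.0, 0, 1.0)

    def test_remlrt_chi_square_arithmetic(self, met_small):
        from scipy import stats

        null = reml_fit(met_small, VarianceModelSpec.diag())
        alt = reml_fit(met_small, VarianceModelSpec.fa(1))
        stat, df, p = remlrt(null, alt)
        assert stat == pytest.approx(2 * (alt.residual_loglik - null.residual_loglik))
        assert df == alt.n_params - null.n_params
        assert p == pytest.approx(stats.chi2.sf(stat, df))

    def test_remlrt_rejects_non_nested(self, met_small):
        fa = reml_fit(met_small, VarianceModelSpec.fa(1))
        cs = reml_fit(met_small, VarianceModelSpec.cs())
        with pytest.raises(SpecError):
            remlrt(fa, cs)

    def test_remlrt_null_calibration_not_anticonservative(self):
        # data simulated under FA1: testing FA1 vs FA2 at nominal 5% should
        # reject rarely (the boundary chi-square mixture makes the plain
        # chi-square reference conservative)
        lam = np.array([0.5, 0.45, 0.4, 0.55])
        psi = np.array([0.05, 0.08, 0.04, 0.06])
        G = np.outer(lam, lam) + np.diag(psi)
        ctl = FitControl(max_starts=1)
        rejections = 0
        n_rep = 120
        for rep in range(n_rep):
            data, _ = make_met(t=4, m=30, seed=3000 + rep, G=G, weights=(8.0, 20.0))
            f1 = reml_fit(data, VarianceModelSpec.fa(1), control=ctl)
            f2 = reml_fit(data, VarianceModelSpec.fa(2), control=ctl)
            _, _, p = remlrt(f1, f2)
            rejections += p < 0.05
        assert rejections / n_rep <= 0.10

    def test_parameter_counts(self):
        t = 10
        assert VarianceModelSpec.diag().n_params(t) == 10
        assert VarianceModelSpec.cs().n_params(t) == 2
        assert VarianceModelSpec.vc(("region", "year", "region_year")).n_params(t) == 5
        assert VarianceModelSpec.fa(2).n_params(t) == 3 * t - 1
        assert VarianceModelSpec.us().n_params(t) == 55
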