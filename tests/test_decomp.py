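"""The three decompositions of GC: hand-checked values, exact additivity,
the zero-residual artefact, and cross-tab consistency."""

import numpy as np
import pandas as pd
import pytest

import rankdecomp as rd
from rankdecomp._weights import wcov

from conftest import random_dataset


def _wls(y, X, w=None):
    return rd.wls_fit(rd.DesignMatrix(pd.Series(np.asarray(y, float)), X, w))


class TestHealthOriented:
    def test_including_d_forces_zero_residual(self, fixture_a):
        """With d itself among the regressors the deterministic component
        equals GC — the decomposition 'explains' the index by one of its
        own components."""
        ranks = fixture_a["ranks"]
        fit = _wls(fixture_a["h"], rd.add_constant(pd.DataFrame({"d": ranks.d})))
        dec = rd.decompose_health(fit, ranks)
        assert dec.terms["d"] == pytest.approx(-0.15, abs=1e-12)
        assert dec.residual == pytest.approx(0.0, abs=1e-12)

    def test_intercept_only_puts_everything_in_residual(self, fixture_a):
        ranks = fixture_a["ranks"]
        fit = _wls(fixture_a["h"], pd.DataFrame({"const": np.ones(4)}))
        dec = rd.decompose_health(fit, ranks)
        assert len(dec.terms) == 0
        assert dec.residual == pytest.approx(-0.15, abs=1e-12)

    def test_single_covariate_hand_values(self, fixture_a):
        fit = _wls(fixture_a["h"], rd.add_constant(fixture_a["s"].copy()))
        dec = rd.decompose_health(fit, fixture_a["ranks"])
        assert dec.terms["s"] == pytest.approx(-0.14625, abs=1e-12)
        assert dec.residual == pytest.approx(-0.00375, abs=1e-12)


class TestRankOriented:
    def test_including_h_forces_zero_residual(self, fixture_a):
        ranks = fixture_a["ranks"]
        fit = _wls(ranks.d, rd.add_constant(pd.DataFrame({"h": fixture_a["h"]})))
        dec = rd.decompose_rank(fit, fixture_a["h"])
        assert dec.terms["h"] == pytest.approx(-0.15, abs=1e-12)
        assert dec.residual == pytest.approx(0.0, abs=1e-12)

    def test_intercept_only(self, fixture_a):
        ranks = fixture_a["ranks"]
        fit = _wls(ranks.d, pd.DataFrame({"const": np.ones(4)}))
        dec = rd.decompose_rank(fit, fixture_a["h"])
        assert dec.residual == pytest.approx(-0.15, abs=1e-12)

    def test_single_covariate_hand_values(self, fixture_a):
        fit = _wls(fixture_a["ranks"].d, rd.add_constant(fixture_a["s"].copy()))
        dec = rd.decompose_rank(fit, fixture_a["h"])
        assert dec.terms["s"] == pytest.approx(-0.14625, abs=1e-12)
        assert dec.residual == pytest.approx(-0.00375, abs=1e-12)


class TestSimultaneous:
    def test_p1_hand_values(self, fixture_a):
        S = rd.add_constant(fixture_a["s"].copy())
        fit_h = _wls(fixture_a["h"], S)
        fit_d = _wls(fixture_a["ranks"].d, S.copy())
        dec, ct, dc = rd.decompose_simultaneous(fit_h, fit_d)
        # 2 * lambda_1 * pi_1 * Var(s) = 2 * (-0.26) * 0.225 * 1.25
        assert dec.terms["s"] == pytest.approx(-0.14625, abs=1e-12)
        assert dec.residual == pytest.approx(-0.00375, abs=1e-12)
        assert dec.percentages["s"] == pytest.approx(97.5, abs=1e-9)
        assert dec.residual_pct == pytest.approx(2.5, abs=1e-9)
        assert ct.grand_total == pytest.approx(100.0, abs=1e-9)

    def test_orthogonal_response_puts_everything_in_residual(self):
        """When the fitted coefficients of one equation are all zero the
        structural cells vanish and the residual carries all of GC."""
        rng = np.random.default_rng(21)
        n = 50
        S = rd.add_constant(pd.DataFrame({"s1": rng.normal(size=n)}))
        noise = rng.normal(size=n)
        h = noise - _wls(noise, S).fitted + 0.3  # exactly orthogonal to s1
        d = rd.fractional_ranks(rng.normal(size=n)).d
        fit_h = _wls(h, S)
        fit_d = _wls(d, S.copy())
        assert abs(fit_h.coefficients["s1"]) < 1e-10
        dec, ct, dc = rd.decompose_simultaneous(fit_h, fit_d)
        np.testing.assert_allclose(dec.terms, 0, atol=1e-10)
        assert dec.residual == pytest.approx(dec.index_value, abs=1e-12)

    def test_regressor_order_permutation(self):
        rng = np.random.default_rng(22)
        h, y, w, X = random_dataset(rng, n=40, k=3)
        d = rd.fractional_ranks(y, w).d
        Xc = rd.add_constant(X)
        dec1, ct1, dc1 = rd.decompose_simultaneous(
            _wls(h, Xc, w), _wls(d, Xc.copy(), w)
        )
        perm = rd.add_constant(X[["s2", "s0", "s1"]])
        dec2, ct2, dc2 = rd.decompose_simultaneous(
            _wls(h, perm, w), _wls(d, perm.copy(), w)
        )
        assert dec2.index_value == pytest.approx(dec1.index_value, rel=1e-12)
        assert ct2.grand_total == pytest.approx(ct1.grand_total, abs=1e-9)
        for name in ["s0", "s1", "s2"]:
            assert ct2.matrix.loc[name, name] == pytest.approx(
                ct1.matrix.loc[name, name], rel=1e-9
            )

    def test_mismatched_regressor_sets_error(self, fixture_a):
        fit_h = _wls(fixture_a["h"], rd.add_constant(fixture_a["s"].copy()))
        other = rd.add_constant(pd.DataFrame({"t": [1.0, 0, 1, 0]}))
        fit_d = _wls(fixture_a["ranks"].d, other)
        with pytest.raises(ValueError, match="reduced_form"):
            rd.decompose_simultaneous(fit_h, fit_d)

    @pytest.mark.parametrize("seed", range(6))
    def test_crosstab_marginals_match_one_dimensional(self, seed):
        """Row totals of the cross-tab reproduce decomposition (I), column
        totals decomposition (II), on the shared regressor set."""
        rng = np.random.default_rng(seed)
        h, y, w, X = random_dataset(rng, n=60, k=3)
        d = rd.fractional_ranks(y, w).d
        Xc = rd.add_constant(X)
        fit_h = _wls(h, Xc, w)
        fit_d = _wls(d, Xc.copy(), w)
        dec3, ct, dc = rd.decompose_simultaneous(fit_h, fit_d)
        dec1 = rd.decompose_health(fit_h, d, w)
        dec2 = rd.decompose_rank(fit_d, h, w)
        gc = dec3.index_value
        for name in X.columns:
            assert ct.row_totals[name] == pytest.approx(
                100 * dec1.terms[name] / gc, abs=1e-8
            )
            assert ct.col_totals[name] == pytest.approx(
                100 * dec2.terms[name] / gc, abs=1e-8
            )
        assert ct.grand_total == pytest.approx(100.0, abs=1e-8)
        # direct + combined + residual closes to 100
        assert dc.total == pytest.approx(100.0, abs=1e-8)


class TestResidualEquality:
    @pytest.mark.parametrize("seed", range(6))
    def test_three_way_residual_coincidence(self, seed):
        """The residual share of (III) equals those of (I) excluding d and
        (II) excluding h whenever all three use the same regressors."""
        rng = np.random.default_rng(100 + seed)
        h, y, w, X = random_dataset(rng, n=45, k=2)
        d = rd.fractional_ranks(y, w).d
        Xc = rd.add_constant(X)
        fit_h = _wls(h, Xc, w)
        fit_d = _wls(d, Xc.copy(), w)
        dec1 = rd.decompose_health(fit_h, d, w)
        dec2 = rd.decompose_rank(fit_d, h, w)
        dec3, _, _ = rd.decompose_simultaneous(fit_h, fit_d)
        assert dec1.residual == pytest.approx(dec3.residual, rel=1e-9, abs=1e-13)
        assert dec2.residual == pytest.approx(dec3.residual, rel=1e-9, abs=1e-13)


class TestPercentages:
    def test_fifty_fifty(self):
        res = rd.DecompositionResult(
            kind="I",
            index_value=-0.15,
            terms=pd.Series({"x": -0.075}),
            residual=-0.075,
            method="WLS",
            n=4,
            weighted=False,
        )
        out = rd.percentages(res)
        assert out.percentages["x"] == pytest.approx(50.0)
        assert out.residual_pct == pytest.approx(50.0)

    def test_zero_index_refused(self):
        res = rd.DecompositionResult(
            kind="I",
            index_value=0.0,
            terms=pd.Series({"x": 0.0}),
            residual=0.0,
            method="WLS",
            n=4,
            weighted=False,
        )
        with pytest.raises(ValueError, match="undefined"):
            rd.percentages(res)

    def test_shares_sum_to_hundred(self, fixture_a):
        fit = _wls(fixture_a["h"], rd.add_constant(fixture_a["s"].copy()))
        dec = rd.decompose_health(fit, fixture_a["ranks"])
        assert dec.percentages.sum() + dec.residual_pct == pytest.approx(
            100.0, abs=1e-9
        )


class TestGMMDecomposition:
    def _pipeline_inputs(self, rho, seed, n=20_000):
        from rankdecomp.synthgen import DEFAULT_SEM_SPEC, GeneratorParams, generate

        df, truth = generate(
            GeneratorParams(n=n, seed=seed, rho=rho, censor=False)
        )
        w = df["weight"].to_numpy()
        spec = DEFAULT_SEM_SPEC
        X = rd.add_constant(df[list(spec.h_regressors)].copy())
        X["d"] = df["d"].to_numpy()
        design = rd.DesignMatrix(df["h"], X, w)
        gmm = rd.gmm_iv_fit(design, ["d"], df[list(spec.instruments_for_h)])
        ols = rd.wls_fit(design)
        Zfull = rd.add_constant(
            df[list(spec.h_regressors) + list(spec.instruments_for_h)].copy()
        )
        dhat = rd.first_stage_predict(df["d"].to_numpy(), Zfull, w)
        d = df["d"].to_numpy()
        dec_gmm = rd.gmm_decompose_health(gmm, dhat, d, w)
        dec_ols = rd.decompose_health(ols, d, w)
        return dec_gmm, dec_ols, gmm, ols

    def test_contribution_formula_matches_manual(self, fixture_a):
        """The endogenous contribution is 2 beta_k Cov(dhat, d) by
        definition; check against a direct covariance computation."""
        rng = np.random.default_rng(31)
        n = 400
        z = rng.binomial(1, 0.4, n).astype(float)
        d = rd.fractional_ranks(0.5 * z + rng.normal(size=n)).d
        h = 0.2 - 0.6 * d + rng.normal(size=n) * 0.1
        X = pd.DataFrame({"const": 1.0, "d": d})
        gmm = rd.gmm_iv_fit(
            rd.DesignMatrix(pd.Series(h), X), ["d"], pd.DataFrame({"z": z})
        )
        Zfull = pd.DataFrame({"const": 1.0, "z": z})
        dhat = rd.first_stage_predict(d, Zfull)
        dec = rd.gmm_decompose_health(gmm, dhat, d)
        w = np.ones(n)
        expected = 2 * gmm.coefficients["d"] * wcov(dhat, d, w)
        assert dec.terms["d"] == pytest.approx(expected, rel=1e-12)
        assert dec.residual == pytest.approx(
            dec.index_value - dec.terms.sum(), rel=1e-12
        )

    def test_exogenous_dgp_matches_ols_decomposition(self):
        """Without endogeneity the GMM coefficient and the contributions of
        the exogenous regressors agree with OLS up to Monte-Carlo error.
        The d term itself is structurally scaled by the first-stage fit
        (it uses Cov(dhat, d) = Var(dhat), not Var(d)), so it is compared
        after rescaling by that factor."""
        dec_gmm, dec_ols, gmm, ols = self._pipeline_inputs(rho=0.0, seed=41)
        assert gmm.coefficients["d"] == pytest.approx(
            ols.coefficients["d"], abs=3 * gmm.robust_se["d"]
        )
        for name in dec_ols.terms.index.drop("d"):
            assert dec_gmm.terms[name] == pytest.approx(
                dec_ols.terms[name], abs=5e-4
            )
        scale = dec_gmm.terms["d"] / (2 * gmm.coefficients["d"])  # Cov(dhat, d)
        ols_scale = dec_ols.terms["d"] / (2 * ols.coefficients["d"])  # Var(d)
        assert dec_gmm.terms["d"] / scale == pytest.approx(
            dec_ols.terms["d"] / ols_scale, abs=0.05
        )

    def test_endogenous_dgp_shrinks_rank_contribution(self):
        """With correlated errors the OLS contribution of d absorbs the
        residual; the instrument-based contribution is smaller in magnitude
        and leaves a nonzero residual share."""
        dec_gmm, dec_ols, *_ = self._pipeline_inputs(rho=-0.5, seed=42)
        assert abs(dec_gmm.terms["d"]) < abs(dec_ols.terms["d"])
        assert dec_ols.residual == pytest.approx(0.0, abs=1e-10)
        assert dec_gmm.residual_pct > 0


class TestAdditivity:
    @pytest.mark.parametrize("seed", range(8))
    def test_terms_plus_residual_equal_gc(self, seed):
        rng = np.random.default_rng(300 + seed)
        h, y, w, X = random_dataset(rng, k=int(rng.integers(1, 4)))
        d = rd.fractional_ranks(y, w).d
        Xc = rd.add_constant(X)
        fit_h = _wls(h, Xc, w)
        fit_d = _wls(d, Xc.copy(), w)
        gc = 2 * wcov(h, d, w)
        for dec in (
            rd.decompose_health(fit_h, d, w),
            rd.decompose_rank(fit_d, h, w),
            rd.decompose_simultaneous(fit_h, fit_d)[0],
        ):
            assert dec.total == pytest.approx(gc, rel=1e-10, abs=1e-14)
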