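import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from pnb import habitat as habitat_mod
from pnb import indices as indices_mod
from pnb import model as M
from pnb.phylogeny import patristic_matrix


@pytest.fixture(scope="module")
def pipeline_dataset(small_sim):
    _, plot, phylo, _ = small_sim
    dmat = patristic_matrix(phylo)
    cov = indices_mod.compute_covariate_table(
        plot, dmat, plot.census_years[:-1], master_seed=2, n_null=49
    )
    pca = habitat_mod.habitat_pca(habitat_mod.assemble_habitat(plot))
    return plot, cov, pca


def _glmm_dataset(df, effects):
    return M.SurvivalDataset(
        df=df, variant="apd", interval=(0, 1), window_label="full",
        fixed_effects=effects, standardization={}, n_dropped=0,
    )


def _simulate_glmm(rng, n=600, nq=30, ns=15, beta=(0.5, 0.7, -0.3), sq=0.0, ss=0.0):
    gq = rng.integers(0, nq, n)
    gs = rng.integers(0, ns, n)
    u = sq * rng.normal(size=nq)
    v = ss * rng.normal(size=ns)
    x1, x2 = rng.normal(size=n), rng.normal(size=n)
    eta = beta[0] + beta[1] * x1 + beta[2] * x2 + u[gq] + v[gs]
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    return pd.DataFrame(
        {"quadrat_id": gq, "species": gs, "x1": x1, "x2": x2, "y": y}
    )


class TestBuildDataset:
    def test_standardized_columns(self, pipeline_dataset):
        plot, cov, pca = pipeline_dataset
        ds = M.build_dataset(plot, cov, pca.scores, (2020, 2021), None, "apd")
        for col in ds.fixed_effects:
            vals = ds.df[col].to_numpy()
            assert abs(vals.mean()) < 1e-10
            assert abs(vals.std(ddof=1) - 1) < 1e-10

    def test_eligibility_and_outcomes(self, pipeline_dataset):
        plot, cov, pca = pipeline_dataset
        ds = M.build_dataset(plot, cov, pca.scores, (2020, 2021), None, "apd")
        by_tag = {s.tag: s for s in plot.seedlings}
        for r in ds.df.itertuples():
            s = by_tag[r.tag]
            assert s.is_alive(2020)
            assert r.y == (1 if s.is_alive(2021) else 0)

    def test_absorbing_death_multi_year(self, pipeline_dataset):
        plot, cov, pca = pipeline_dataset
        died = [
            s.tag for s in plot.seedlings
            if s.is_alive(2020) and s.status.get(2021) == "dead"
        ]
        assert died, "fixture should contain first-interval deaths"
        ds1 = M.build_dataset(plot, cov, pca.scores, (2020, 2021), None, "apd")
        ds2 = M.build_dataset(plot, cov, pca.scores, (2020, 2022), None, "apd")
        for tag in died:
            for ds in (ds1, ds2):
                rows = ds.df[ds.df["tag"] == tag]
                if len(rows):
                    assert (rows["y"] == 0).all()

    def test_unknown_variant(self, pipeline_dataset):
        plot, cov, pca = pipeline_dataset
        with pytest.raises(ValueError, match="variant"):
            M.build_dataset(plot, cov, pca.scores, (2020, 2021), None, "nope")

    def test_empty_interval_error(self, pipeline_dataset):
        plot, cov, pca = pipeline_dataset
        with pytest.raises(M.ModelDataError):
            M.build_dataset(plot, cov, pca.scores, (1999, 2000), None, "apd")

    def test_dropped_rows_counted(self, pipeline_dataset):
        plot, cov, pca = pipeline_dataset
        ds = M.build_dataset(plot, cov, pca.scores, (2020, 2021), None, "apd")
        n_start = sum(s.is_alive(2020) for s in plot.seedlings)
        assert ds.n_obs + ds.n_dropped == n_start


class TestFitGLMM:
    def test_degenerate_limit_matches_logistic_oracle(self):
        rng = np.random.default_rng(5)
        df = _simulate_glmm(rng, n=800)
        ds = _glmm_dataset(df, ["x1", "x2"])
        fit = M.fit_glmm(ds, fix_lambda=(0.0, 0.0))
        X = sm.add_constant(df[["x1", "x2"]].to_numpy())
        oracle = sm.Logit(df["y"], X).fit(disp=0)
        assert np.max(np.abs(fit.estimates - oracle.params.to_numpy())) < 1e-3
        assert np.max(np.abs(fit.se - oracle.bse.to_numpy())) < 1e-3
        assert fit.k == 3  # no variance components counted when pinned

    def test_zero_variance_data_free_fit_near_logistic(self):
        rng = np.random.default_rng(6)
        df = _simulate_glmm(rng, n=800)
        ds = _glmm_dataset(df, ["x1", "x2"])
        fit = M.fit_glmm(ds)
        X = sm.add_constant(df[["x1", "x2"]].to_numpy())
        oracle = sm.Logit(df["y"], X).fit(disp=0)
        assert np.max(np.abs(fit.estimates - oracle.params.to_numpy())) < 0.05

    def test_all_survivors_flags_separation(self):
        rng = np.random.default_rng(0)
        df = _simulate_glmm(rng, n=100)
        df["y"] = 1
        fit = M.fit_glmm(_glmm_dataset(df, ["x1", "x2"]))
        assert fit.separation
        assert not fit.converged

    def test_aic_identity(self):
        rng = np.random.default_rng(7)
        df = _simulate_glmm(rng, n=300, sq=0.5, ss=0.5)
        fit = M.fit_glmm(_glmm_dataset(df, ["x1", "x2"]))
        assert fit.aic == pytest.approx(2 * fit.k - 2 * fit.loglik)
        assert fit.k == 5

    def test_recovers_variance_components(self):
        rng = np.random.default_rng(11)
        df = _simulate_glmm(rng, n=2000, nq=80, ns=40, sq=0.8, ss=0.5)
        fit = M.fit_glmm(_glmm_dataset(df, ["x1", "x2"]))
        assert fit.converged
        assert 0.2 < fit.sigma2_quadrat < 1.5  # true 0.64
        assert 0.02 < fit.sigma2_species < 0.9  # true 0.25

    def test_needs_two_groups(self):
        rng = np.random.default_rng(1)
        df = _simulate_glmm(rng, n=50, nq=1, ns=5)
        with pytest.raises(M.ModelDataError):
            M.fit_glmm(_glmm_dataset(df, ["x1", "x2"]))

    def test_aic_prefers_true_covariate(self):
        """Adding a truly predictive covariate lowers AIC (majority over reps)."""
        rng = np.random.default_rng(21)
        wins = 0
        reps = 15
        for _ in range(reps):
            df = _simulate_glmm(rng, n=400, beta=(0.3, 0.8, 0.0), sq=0.3, ss=0.3)
            full = M.fit_glmm(_glmm_dataset(df, ["x1"]))
            null = M.fit_glmm(_glmm_dataset(df.assign(x1=0.0 * df.x1 + 1e-9 * rng.normal(size=len(df))), ["x1"]))
            if full.aic < null.aic:
                wins += 1
        assert wins > reps / 2

    def test_permuted_outcome_type_one(self):
        """Refit on permuted outcomes: >= 90% of slopes have |z| < 1.96."""
        rng = np.random.default_rng(31)
        zvals = []
        for _ in range(15):
            df = _simulate_glmm(rng, n=300, beta=(0.3, 0.6, -0.4), sq=0.4, ss=0.4)
            df["y"] = rng.permutation(df["y"].to_numpy())
            fit = M.fit_glmm(_glmm_dataset(df, ["x1", "x2"]))
            zvals.extend(np.abs(fit.zvalues[1:]))
        assert np.mean(np.array(zvals) < 1.96) >= 0.9


class TestR2AndClassification:
    def test_null_model_zero(self):
        fit = M.ModelFit(
            terms=["(Intercept)"], estimates=np.zeros(1), se=np.ones(1),
            zvalues=np.zeros(1), pvalues=np.ones(1), lambda_q=0.0, lambda_s=0.0,
            sigma2_quadrat=0.0, sigma2_species=0.0, loglik=0.0, aic=0.0, k=1,
            n_obs=10, converged=True, separation=False,
            fixed_linear_predictor_var=0.0,
        )
        assert M.conditional_r2(fit) == 0.0

    def test_closed_form(self):
        fit = M.ModelFit(
            terms=["(Intercept)"], estimates=np.zeros(1), se=np.ones(1),
            zvalues=np.zeros(1), pvalues=np.ones(1), lambda_q=0.5, lambda_s=0.5,
            sigma2_quadrat=0.25, sigma2_species=0.25, loglik=0.0, aic=0.0, k=1,
            n_obs=10, converged=True, separation=False,
            fixed_linear_predictor_var=1.0,
        )
        expect = 1.5 / (1.5 + math.pi**2 / 3)
        assert M.conditional_r2(fit) == pytest.approx(expect, abs=1e-12)
        assert expect == pytest.approx(0.313, abs=5e-4)

    def test_monotone_in_re_variance(self):
        base = dict(
            terms=["(Intercept)"], estimates=np.zeros(1), se=np.ones(1),
            zvalues=np.zeros(1), pvalues=np.ones(1), lambda_q=0.0, lambda_s=0.0,
            sigma2_species=0.1, loglik=0.0, aic=0.0, k=1, n_obs=10,
            converged=True, separation=False, fixed_linear_predictor_var=0.5,
        )
        lo = M.ModelFit(sigma2_quadrat=0.1, **base)
        hi = M.ModelFit(sigma2_quadrat=0.6, **base)
        assert M.conditional_r2(hi) > M.conditional_r2(lo)

    @pytest.mark.parametrize(
        "p,est,expect",
        [
            (0.03, 0.4, ("significant", "positive")),
            (0.07, -0.2, ("marginal", "negative")),
            (0.5, 0.1, ("none", "positive")),
            (0.049999, -1.0, ("significant", "negative")),
            (0.05, 1.0, ("marginal", "positive")),
        ],
    )
    def test_classify(self, p, est, expect):
        assert M.classify_effect(p, est) == expect

    def test_classify_rejects_bad_p(self):
        with pytest.raises(ValueError):
            M.classify_effect(1.5, 0.0)

    def test_positive_index_reads_as_pndd(self):
        band, sign = M.classify_effect(0.01, 0.8)
        assert (band, sign) == ("significant", "positive")


def test_fit_on_pipeline_dataset(pipeline_dataset):
    plot, cov, pca = pipeline_dataset
    ds = M.build_dataset(plot, cov, pca.scores, (2020, 2021), None, "apd")
    fit = M.fit_glmm(ds)
    assert fit.n_obs == ds.n_obs
    assert len(fit.terms) == 10
    assert fit.k == 12
    assert 0.0 <= M.conditional_r2(fit, ds) <= 1.0
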