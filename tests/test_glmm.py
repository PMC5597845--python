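import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import gammaln

from patfit.glmm import (
    ModelSpec,
    build_design,
    cauchit_inverse,
    cauchit_link,
    fit_glmm,
    hurdle_poisson_logpmf,
    logistic,
    marginal_loglik,
    spline_basis,
)
from patfit.glmm.spline import SplineError

from conftest import grid_marginal_loglik


class TestCauchitLink:
    def test_symmetry_and_closed_forms(self):
        assert cauchit_link(0.0) == pytest.approx(0.5)
        assert cauchit_link(1.0) == pytest.approx(0.75)  # arctan(1) = pi/4

    @settings(max_examples=100, deadline=None)
    @given(st.floats(-50, 50))
    def test_roundtrip_bijection(self, eta):
        assert cauchit_inverse(cauchit_link(eta)) == pytest.approx(eta, abs=1e-9)

    def test_roundtrip_example(self):
        assert abs(cauchit_inverse(cauchit_link(-3.7)) + 3.7) < 1e-12

    def test_heavier_tails_than_logit(self):
        # Cauchy tails dominate: more mass remains above a large predictor
        assert 1.0 - cauchit_link(10.0) > 1.0 - logistic(10.0)
        assert cauchit_link(10.0) == pytest.approx(0.5 + np.arctan(10.0) / np.pi)

    def test_strictly_increasing(self):
        eta = np.linspace(-30, 30, 301)
        assert np.all(np.diff(cauchit_link(eta)) > 0)

    def test_boundary_signals(self):
        with pytest.raises(ValueError):
            cauchit_inverse(0.0)
        with pytest.raises(ValueError):
            cauchit_inverse(1.0)


class TestHurdlePoissonPmf:
    def test_zero_mass_is_exactly_pi0(self):
        assert hurdle_poisson_logpmf(0, 0.37, 5.0) == pytest.approx(np.log(0.37))

    def test_positive_mass_hand_arithmetic(self):
        # P(1) = (1-pi0) * lam * e^-lam / (1 - e^-lam) at pi0=.5, lam=1
        expected = 0.5 * np.exp(-1.0) / (1.0 - np.exp(-1.0))
        assert hurdle_poisson_logpmf(1, 0.5, 1.0) == pytest.approx(np.log(expected))
        assert expected == pytest.approx(0.290988, abs=1e-6)

    @pytest.mark.parametrize("pi0,lam", [(0.3, 4.0), (0.05, 0.5), (0.9, 25.0), (0.5, 1.0)])
    def test_normalizes_over_support(self, pi0, lam):
        y = np.arange(0, 200)
        total = np.exp(hurdle_poisson_logpmf(y, pi0, lam)).sum()
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_reduces_to_poisson_when_pi0_matches(self):
        # with pi0 = e^-lam the hurdle pmf equals an ordinary Poisson pmf
        lam = 3.0
        y = np.arange(0, 30)
        hp = hurdle_poisson_logpmf(y, np.exp(-lam), lam)
        pois = y * np.log(lam) - lam - gammaln(y + 1.0)
        assert np.allclose(hp, pois, atol=1e-12)

    def test_stable_for_large_rates(self):
        val = hurdle_poisson_logpmf(150, 0.2, 180.0)
        assert np.isfinite(val)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            hurdle_poisson_logpmf(-1, 0.5, 1.0)
        with pytest.raises(ValueError):
            hurdle_poisson_logpmf(1, 1.5, 1.0)


def _grouped_testdata(seed=5, F=24, per=4, sigma=0.6):
    rng = np.random.default_rng(seed)
    n = F * per
    groups = np.repeat(np.arange(F), per)
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    beta = np.array([0.4, 0.3])
    u = rng.normal(0, sigma, F)
    lam = np.exp(X @ beta + u[groups])
    return X, groups, beta, sigma, rng.poisson(lam)


class TestMarginalLikelihood:
    @pytest.mark.parametrize("family", ["poisson_log", "ztpoisson_log", "bernoulli_cauchit"])
    def test_agrees_with_dense_grid_oracle(self, family):
        X, groups, beta, sigma, y = _grouped_testdata()
        if family == "ztpoisson_log":
            y = np.maximum(y, 1)
        elif family == "bernoulli_cauchit":
            y = (y > 0).astype(float)
        agh = marginal_loglik(family, y, X, groups, beta, np.array([sigma]), n_nodes=15)
        grid = grid_marginal_loglik(family, y, X, groups, beta, sigma)
        assert abs(agh - grid) / abs(grid) < 1e-8

    def test_sigma_zero_is_plain_loglik(self):
        from patfit.glmm.families import PoissonLog

        X, groups, beta, _, y = _grouped_testdata()
        a = marginal_loglik("poisson_log", y, X, groups, beta, np.array([0.0]))
        assert a == pytest.approx(PoissonLog.loglik(y, X @ beta).sum())

    def test_node_doubling_changes_little(self):
        X, groups, beta, sigma, y = _grouped_testdata()
        a = marginal_loglik("poisson_log", y, X, groups, beta, np.array([sigma]), n_nodes=21)
        b = marginal_loglik("poisson_log", y, X, groups, beta, np.array([sigma]), n_nodes=42)
        assert abs(a - b) < 1e-9

    def test_hurdle_splits_into_logit_plus_truncated_poisson(self):
        X, groups, beta, sigma, y = _grouped_testdata(seed=8)
        total = marginal_loglik(
            "hurdle_poisson_log", y, X, groups, beta, np.array([sigma]),
            X_hurdle=X, beta_hurdle=np.array([0.2, -0.1]),
        )
        from patfit.glmm.families import BernoulliLogit

        pos = y > 0
        part1 = BernoulliLogit.loglik(pos.astype(float), X @ np.array([0.2, -0.1])).sum()
        part2 = grid_marginal_loglik(
            "ztpoisson_log", y[pos], X[pos], groups[pos], beta, sigma
        )
        assert total == pytest.approx(part1 + part2, rel=1e-9)


def _toy_anchor_frame(seed=3, F=400, per=4, sigma=0.5, beta=(0.3, 0.25)):
    rng = np.random.default_rng(seed)
    n = F * per
    fam = np.repeat(np.arange(F), per)
    x = rng.normal(size=n)
    u = rng.normal(0, sigma, F)
    y = rng.poisson(np.exp(beta[0] + beta[1] * x + u[fam]))
    return pd.DataFrame({"y": y, "x": x, "family_id": [f"f{i:04d}" for i in fam]})


BARE_SPEC = ModelSpec(
    outcome="y", family="poisson_log", fixed_terms=("x",),
    paternal_age_term="none", group_term="family_intercept",
)


class TestFitting:
    def test_flat_prior_no_group_matches_statsmodels_glm(self):
        import statsmodels.api as sm

        df = _toy_anchor_frame()
        spec = BARE_SPEC.with_(group_term="none", priors="flat")
        fit = fit_glmm(spec, df)
        d = build_design(df, spec)
        ref = sm.GLM(d.y, d.X, family=sm.families.Poisson()).fit()
        assert np.allclose(fit.count_part.beta, ref.params, atol=1e-6)
        assert np.allclose(fit.count_part.se(), ref.bse, rtol=1e-3)

    def test_recovers_variance_and_slope(self):
        df = _toy_anchor_frame(seed=10, F=800)
        fit = fit_glmm(BARE_SPEC, df)
        part = fit.count_part
        # slope
        j = part.names.index("x")
        assert abs(part.beta[j] - 0.25) < 3 * part.se()[j]
        # family sd (truth 0.5)
        log_sig_se = np.sqrt(part.cov[-1, -1])
        assert abs(np.log(part.sigma[0]) - np.log(0.5)) < 3 * log_sig_se

    def test_matches_lme4_on_shared_data(self, tmp_path):
        """Independent cross-check: same Poisson GLMM fitted by lme4."""
        df = _toy_anchor_frame(seed=6, F=300)
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        rfile = tmp_path / "fit.R"
        rfile.write_text(
            f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- glmer(y ~ x + (1|family_id), data=d, family=poisson, nAGQ=15)
            cat(fixef(m)[1], fixef(m)[2],
                sqrt(unlist(VarCorr(m))[1]), sep="\\n")
            """
        )
        try:
            out = subprocess.run(
                ["Rscript", "--vanilla", str(rfile)], capture_output=True,
                text=True, timeout=240, check=True,
            )
        except (FileNotFoundError, subprocess.SubprocessError) as exc:
            pytest.skip(f"Rscript unavailable: {exc}")
        b0, b1, sig = (float(v) for v in out.stdout.strip().splitlines())
        fit = fit_glmm(BARE_SPEC.with_(priors="flat"), df)
        part = fit.count_part
        assert part.beta[0] == pytest.approx(b0, abs=0.01)
        assert part.beta[part.names.index("x")] == pytest.approx(b1, abs=0.01)
        assert part.sigma[0] == pytest.approx(sig, rel=0.05)

    def test_random_slope_model_fits(self):
        rng = np.random.default_rng(4)
        F, per = 300, 5
        fam = np.repeat(np.arange(F), per)
        dev = rng.normal(0, 5, F * per)
        u = rng.normal(0, 0.4, F)
        s = rng.normal(0, 0.02, F)
        y = rng.poisson(np.exp(0.5 + u[fam] + (0.01 + s[fam]) * dev))
        df = pd.DataFrame({
            "n_children": y, "paternal_age_dev": dev,
            "paternal_age_fam_mean": 30.0 + rng.normal(0, 2, F)[fam],
            "family_id": fam,
        })
        spec = ModelSpec(
            outcome="n_children", family="poisson_log", fixed_terms=(),
            paternal_age_term="linear_dev_plus_mean",
            group_term="family_intercept_and_slope",
        )
        fit = fit_glmm(spec, df)
        assert fit.count_part.sigma.shape == (2,)
        b, se = fit.beta_pa()
        assert abs(b - 0.01) < 3 * se


class TestSpline:
    def test_constant_ages_rejected(self):
        with pytest.raises(SplineError):
            spline_basis(np.full(100, 30.0), df=4)

    def test_columns_centered_and_orthogonal_to_linear(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(-10, 10, 500)
        B = spline_basis(x, df=6).transform(x)
        assert B.shape == (500, 6)
        assert np.allclose(B.sum(axis=0), 0.0, atol=1e-8)
        assert np.allclose(x @ B, 0.0, atol=1e-6)

    def test_transform_consistent_on_new_points(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(-8, 8, 400)
        sb = spline_basis(x, df=5)
        B1 = sb.transform(x[:50])
        B2 = sb.transform(x)[:50]
        assert np.allclose(B1, B2)


def test_modelspec_yaml_roundtrip():
    spec = ModelSpec(
        family="poisson_log", fixed_terms=("cohort_bin", "sex"),
        interactions=(("sex", "paternal_age_dev"),), priors="tight",
        spline_df=6, tag="custom",
    )
    assert ModelSpec.from_yaml(spec.to_yaml()) == spec


def test_design_drops_empty_levels_and_scales_priors(null_anchor_table):
    anchors, _ = null_anchor_table
    spec = ModelSpec(tag="m3")
    d = build_design(anchors, spec)
    # no all-zero indicator columns
    assert all(d.X[:, j].std() > 0 for j in range(1, d.X.shape[1]))
    assert d.names[0] == "intercept"
    assert d.pa_dev_col is not None and d.pa_mean_col is not None
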