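import copy

import numpy as np
import pandas as pd
import pytest

from patfit import (
    BatteryConfig,
    BatteryError,
    MutationParams,
    SimulationConfig,
    build_anchor_table,
    robustness_battery,
    simulate_pedigree,
)
from patfit.effects import (
    episode_contrast,
    marginal_effect_curve,
    per_decade_effect,
    run_model_set,
)
from patfit.glmm import ModelSpec, compare_models, fit_glmm
from patfit.glmm.fit import FitError

from conftest import WIDE_WINDOW


def _pa_frame(seed=0, F=500, per=4, beta_pa=-0.008, scale=1.0):
    """Poisson outcome with a known within-family paternal-age effect."""
    rng = np.random.default_rng(seed)
    fam = np.repeat(np.arange(F), per)
    fam_mean = rng.normal(33, 4, F)
    dev = rng.normal(0, 5, F * per) * scale
    u = rng.normal(0, 0.3, F)
    y = rng.poisson(np.exp(1.0 + beta_pa * dev / scale + u[fam]))
    return pd.DataFrame({
        "n_children": y,
        "paternal_age_dev": dev,
        "paternal_age_fam_mean": fam_mean[fam],
        "paternal_age": fam_mean[fam] + dev,
        "family_id": [f"f{i:04d}" for i in fam],
    })


PA_SPEC = ModelSpec(
    outcome="n_children", family="poisson_log", fixed_terms=(),
    paternal_age_term="linear_dev_plus_mean", group_term="family_intercept",
    tag="m3",
)


class TestPerDecadeEffect:
    def test_matches_coefficient_transform_for_log_link(self):
        fit = fit_glmm(PA_SPEC, _pa_frame())
        b, se = fit.beta_pa()
        eff = per_decade_effect(fit)
        assert eff.point == pytest.approx((np.exp(10 * b) - 1) * 100.0)
        assert eff.lo == pytest.approx((np.exp(10 * (b - 1.96 * se)) - 1) * 100.0)

    def test_zero_coefficient_gives_zero_percent(self):
        fit = fit_glmm(PA_SPEC, _pa_frame())
        j = fit.count_part.design.pa_dev_col
        fit.count_part.beta[j] = 0.0
        assert per_decade_effect(fit).point == pytest.approx(0.0)

    def test_monotone_in_coefficient(self):
        fit = fit_glmm(PA_SPEC, _pa_frame())
        j = fit.count_part.design.pa_dev_col
        pts = []
        for b in (-0.01, 0.0, 0.01):
            f2 = copy.deepcopy(fit)
            f2.count_part.beta[j] = b
            pts.append(per_decade_effect(f2).point)
        assert pts[0] < pts[1] < pts[2]

    def test_transform_consistent_under_age_rescaling(self):
        """Fitting ages measured in decades instead of years reports the same
        per-decade percentage."""
        df = _pa_frame(seed=4)
        fit_years = fit_glmm(PA_SPEC, df)
        df10 = df.assign(
            paternal_age_dev=df["paternal_age_dev"] / 10.0,
            paternal_age_fam_mean=df["paternal_age_fam_mean"] / 10.0,
        )
        fit_dec = fit_glmm(PA_SPEC, df10)
        e1 = per_decade_effect(fit_years, delta=10.0)
        e2 = per_decade_effect(fit_dec, delta=1.0)
        assert e1.point == pytest.approx(e2.point, abs=0.05)

    def test_spline_fit_directs_to_curve(self, m4_fit):
        with pytest.raises(FitError, match="curve"):
            per_decade_effect(m4_fit)


@pytest.fixture(scope="module")
def e1_fit(effect_anchor_table):
    anchors, _ = effect_anchor_table
    spec = ModelSpec(outcome="e1", family="bernoulli_cauchit", tag="e1")
    return fit_glmm(spec, anchors)


@pytest.fixture(scope="module")
def m4_fit(effect_anchor_table):
    anchors, _ = effect_anchor_table
    return fit_glmm(
        ModelSpec(paternal_age_term="spline_dev_plus_mean", tag="m4"), anchors
    )


@pytest.fixture(scope="module")
def battery_inputs():
    cfg = SimulationConfig(
        preset="historical_sweden", n_families=900, seed=55,
        mutation=MutationParams(s_bar=0.004), maternal_age_effect=0.05,
    )
    ped, truth = simulate_pedigree(cfg)
    anchors = build_anchor_table(ped, WIDE_WINDOW)
    return anchors, truth


class TestEpisodeContrast:
    def test_zero_coefficient_gives_zero_contrast(self, e1_fit):
        f2 = copy.deepcopy(e1_fit)
        d = f2.count_part.design
        f2.count_part.beta[d.pa_dev_col] = 0.0
        f2.count_part.beta[d.pa_mean_col] = 0.0
        assert episode_contrast(f2).point == pytest.approx(0.0)

    def test_sign_matches_coefficient(self, e1_fit):
        d = e1_fit.count_part.design
        for b, sign in ((-0.02, -1), (0.02, 1)):
            f2 = copy.deepcopy(e1_fit)
            f2.count_part.beta[d.pa_dev_col] = b
            f2.count_part.beta[d.pa_mean_col] = b
            assert np.sign(episode_contrast(f2).point) == sign

    def test_infant_survival_contrast_is_negative_under_selection(self, e1_fit):
        # with s=0.004 and half the load on infancy, 25->35 predicts ~-0.8%
        eff = episode_contrast(e1_fit)
        assert eff.lo < 0.0 < eff.hi or eff.point < 0.0


class TestMarginalEffectCurve:
    def test_linear_truth_stays_inside_band(self, m4_fit):
        ages = np.linspace(25, 45, 9)
        curve = marginal_effect_curve(m4_fit, ages)
        inside = (curve["linear"] >= curve["lo"]) & (curve["linear"] <= curve["hi"])
        assert inside.mean() >= 0.8

    def test_empty_grid_is_an_error(self, m4_fit):
        with pytest.raises(ValueError, match="empty"):
            marginal_effect_curve(m4_fit, [])

    def test_extrapolation_warns(self, m4_fit):
        with pytest.warns(UserWarning, match="extrapolat"):
            marginal_effect_curve(m4_fit, [120.0])


class TestModelComparison:
    def test_duplicate_models_tie(self):
        df = _pa_frame(seed=9, F=300)
        fits = [fit_glmm(PA_SPEC, df), fit_glmm(PA_SPEC.with_(tag="m3b"), df)]
        table = compare_models(fits, df, K=4, seed=1)
        assert table["d_elpd"].abs().max() <= max(table["d_se"].max(), 1e-6)

    def test_true_effect_favors_paternal_age_model(self):
        df = _pa_frame(seed=12, F=900, beta_pa=-0.03)
        m2 = fit_glmm(PA_SPEC.with_(paternal_age_term="none", tag="m2"), df)
        m3 = fit_glmm(PA_SPEC, df)
        table = compare_models([m2, m3], df, K=5, seed=2)
        d = table.loc["m2", "d_elpd"]
        assert table.loc["m3", "d_elpd"] == 0.0  # m3 is best
        assert -d > 2 * table.loc["m2", "d_se"]

    def test_null_data_does_not_favor_paternal_age_model(self):
        df = _pa_frame(seed=13, F=500, beta_pa=0.0)
        m2 = fit_glmm(PA_SPEC.with_(paternal_age_term="none", tag="m2"), df)
        m3 = fit_glmm(PA_SPEC, df)
        table = compare_models([m2, m3], df, K=5, seed=3)
        worst = table["d_elpd"].min()
        assert abs(worst) < 2 * table["d_se"].max()


class TestModelSet:
    def test_unconfounded_m1_and_m3_agree(self, effect_anchor_table):
        anchors, _ = effect_anchor_table
        res = run_model_set(anchors, compare=False)
        m1, m3 = res.effects["m1"], res.effects["m3"]
        # intervals overlap: no sign flip without between-family confounding
        assert m1.lo <= m3.hi and m3.lo <= m1.hi


class TestBattery:
    def test_unknown_variant_rejected_before_fitting(self):
        with pytest.raises(BatteryError, match="unknown"):
            BatteryConfig(variants=("r2", "r99"))

    def test_duplicate_variants_rejected(self):
        with pytest.raises(BatteryError, match="duplicate"):
            BatteryConfig(variants=("r2", "r2"))

    def test_r17_requires_truth_column(self, battery_inputs):
        anchors, _ = battery_inputs
        with pytest.raises(BatteryError, match="trisomy"):
            robustness_battery(BatteryConfig(variants=("r17",)), anchors)

    def test_fixed_seed_reproduces_table(self, battery_inputs):
        anchors, truth = battery_inputs
        cfg = BatteryConfig(variants=("r2", "r20", "r24"), seed=7,
                            base_spec=ModelSpec(family="poisson_log", tag="m3"))
        t1 = robustness_battery(cfg, anchors, truth)
        t2 = robustness_battery(cfg, anchors, truth)
        pd.testing.assert_frame_equal(t1, t2)

    def test_prior_washout_with_flat_priors(self, battery_inputs):
        anchors, truth = battery_inputs
        cfg = BatteryConfig(variants=("r24",), seed=1,
                            base_spec=ModelSpec(family="poisson_log", tag="m3"))
        t = robustness_battery(cfg, anchors, truth)
        # default weakly-informative priors barely move the estimate at this n
        assert abs(t.loc["r24", "point"] - t.loc["m3", "point"]) < 1.5
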