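"""Mixed-model estimation, inference, bootstrap, reporting."""

import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phenosense import (
    MLMSpec,
    SimulationTruth,
    WindowSimConfig,
    bootstrap_varcomp_ci,
    fit_lmm,
    generate_window_level,
    report_tables,
    restricted_loglik,
)
from phenosense.disaggregate import PREDICTORS

STD_MOMENTS = {m: (0.0, 1.0, 1.0) for m in PREDICTORS}


def _zero_var_truth(**kw):
    return SimulationTruth(
        var_intercept=0.0,
        var_slopes={m: 0.0 for m in PREDICTORS},
        var_residual=kw.pop("var_residual", 0.25),
        **kw,
    )


def test_ols_limit_when_no_random_variation():
    """With every variance component forced to 0 the GLS solution is OLS."""
    from phenosense import fixed_effects_at

    for seed in (1, 2, 3):
        design, _ = generate_window_level(
            WindowSimConfig(
                n_persons=10,
                windows_per_person=3,
                moments=STD_MOMENTS,
                truth=_zero_var_truth(),
                seed=seed,
            )
        )
        gamma = fixed_effects_at(
            design, MLMSpec(), np.array([0.0] * 6 + [0.25])
        )
        X = np.column_stack(
            [np.ones(len(design))]
            + [design[f"wp_{m}"] for m in PREDICTORS]
            + [design[f"bp_{m}"] for m in PREDICTORS]
        )
        beta, *_ = np.linalg.lstsq(X, design["loss_of_interest"], rcond=None)
        assert np.abs(gamma.to_numpy() - beta).max() < 1e-3


def test_single_person_is_unidentifiable(small_design):
    design, _ = small_design
    one = design[design["person_id"] == design["person_id"].iloc[0]]
    with pytest.raises(ValueError, match="unidentifiable"):
        fit_lmm(one)


def test_rank_deficient_design_rejected():
    """Too few rows for the fixed effects raises instead of emitting garbage."""
    design, _ = generate_window_level(
        WindowSimConfig(n_persons=4, windows_per_person=2, seed=1)
    )
    with pytest.raises(ValueError, match="rank-deficient"):
        fit_lmm(design)


def test_all_missing_predictor_named(small_design):
    design, _ = small_design
    broken = design.copy()
    broken["wp_nighttime"] = np.nan
    with pytest.raises(ValueError, match="wp_nighttime"):
        fit_lmm(broken)


def test_listwise_deletion_counts(small_design):
    design, _ = small_design
    holey = design.copy()
    holey.loc[holey.index[:7], "wp_app_count"] = np.nan
    fit = fit_lmm(holey)
    assert fit.n_obs == len(design) - 7


def test_row_order_invariance(small_design):
    design, _ = small_design
    fit1 = fit_lmm(design)
    shuffled = design.sample(frac=1.0, random_state=9).reset_index(drop=True)
    fit2 = fit_lmm(shuffled)
    assert np.abs(fit1.fixed["estimate"] - fit2.fixed["estimate"]).max() < 1e-6
    assert np.abs(fit1.varcomp - fit2.varcomp).max() < 1e-6


def test_wald_p_is_two_sided_normal(small_design):
    design, _ = small_design
    fit = fit_lmm(design)
    z = fit.fixed["estimate"] / fit.fixed["se"]
    expect = 2 * stats.norm.sf(np.abs(z))
    assert np.allclose(fit.fixed["p"], expect, atol=1e-12)
    # reference points of the normal approximation
    assert 2 * stats.norm.sf(1.96) == pytest.approx(0.05, abs=5e-4)
    assert 2 * stats.norm.sf(2.576) == pytest.approx(0.01, abs=5e-5)


def test_agreement_with_statsmodels():
    """Independent REML route (statsmodels MixedLM) lands on the same fit."""
    import statsmodels.api as sm

    design, _ = generate_window_level(
        WindowSimConfig(
            n_persons=60, windows_per_person=5, moments=STD_MOMENTS, seed=404
        )
    )
    fit = fit_lmm(design)
    fe = " + ".join([f"wp_{m}" for m in PREDICTORS] + [f"bp_{m}" for m in PREDICTORS])
    model = sm.MixedLM.from_formula(
        f"loss_of_interest ~ {fe}",
        groups="person_id",
        re_formula="1",
        vc_formula={m: f"0 + wp_{m}" for m in PREDICTORS},
        data=design,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ref = model.fit(reml=True, method="powell", maxiter=2000)
    # same restricted-likelihood definition; our optimum must not be worse
    assert fit.loglik >= ref.llf - 1e-3
    assert np.abs(fit.fixed["estimate"].to_numpy() - ref.fe_params.to_numpy()).max() < 0.01
    assert fit.varcomp["var_residual"] == pytest.approx(ref.scale, abs=0.02)
    assert fit.varcomp["var_intercept"] == pytest.approx(
        float(ref.cov_re.iloc[0, 0]), abs=0.02
    )


def test_optimum_dominates_random_perturbations(small_design):
    design, _ = small_design
    spec = MLMSpec()
    fit = fit_lmm(design, spec)
    rng = np.random.default_rng(17)
    base = np.maximum(fit.varcomp.to_numpy(), 1e-8)
    for _ in range(100):
        cand = base * rng.lognormal(0.0, 0.4, base.size)
        assert restricted_loglik(design, spec, cand) <= fit.loglik + 1e-6


def test_ml_estimation_also_supported(small_design):
    design, _ = small_design
    reml = fit_lmm(design, MLMSpec(reml=True))
    ml = fit_lmm(design, MLMSpec(reml=False))
    assert ml.method == "ML" and reml.method == "REML"
    assert ml.loglik != pytest.approx(reml.loglik)
    # ML shrinks variance estimates relative to REML on average
    assert ml.varcomp["var_residual"] <= reml.varcomp["var_residual"] + 0.05


@pytest.fixture(scope="module")
def tiny_one_predictor():
    """Small random-intercept design for bootstrap tests (fast refits)."""
    design, truth = generate_window_level(
        WindowSimConfig(
            n_persons=25,
            windows_per_person=4,
            moments=STD_MOMENTS,
            truth=SimulationTruth(
                gamma_wp={m: 0.0 for m in PREDICTORS},
                gamma_bp={m: 0.0 for m in PREDICTORS},
                var_intercept=0.5,
                var_slopes={m: 0.0 for m in PREDICTORS},
                var_residual=0.5,
            ),
            seed=303,
        )
    )
    return design, MLMSpec(predictors=("app_count",), random_slopes=())


def test_bootstrap_refuses_tiny_replicate_counts(tiny_one_predictor):
    design, spec = tiny_one_predictor
    with pytest.raises(ValueError, match="[Bb]"):
        bootstrap_varcomp_ci(design, spec, B=49, seed=1)


def test_bootstrap_deterministic_under_seed(tiny_one_predictor):
    design, spec = tiny_one_predictor
    ci1 = bootstrap_varcomp_ci(design, spec, B=60, seed=5)
    ci2 = bootstrap_varcomp_ci(design, spec, B=60, seed=5)
    pd.testing.assert_frame_equal(ci1, ci2)
    assert (ci1["lower"] <= ci1["estimate"] + 1e-12).all()
    assert (ci1["upper"] >= ci1["estimate"] - 1e-12).all()


def test_bootstrap_boundary_variance_piles_at_zero():
    """A truth-zero slope variance gives a bootstrap CI touching 0."""
    design, _ = generate_window_level(
        WindowSimConfig(
            n_persons=30,
            windows_per_person=4,
            moments=STD_MOMENTS,
            truth=SimulationTruth(
                gamma_wp={m: 0.0 for m in PREDICTORS},
                gamma_bp={m: 0.0 for m in PREDICTORS},
                var_intercept=0.4,
                var_slopes={m: 0.0 for m in PREDICTORS},
                var_residual=0.5,
            ),
            seed=71,
        )
    )
    spec = MLMSpec(predictors=("app_count",), random_slopes=("app_count",))
    ci = bootstrap_varcomp_ci(design, spec, B=60, seed=2)
    assert ci.loc["var_wp_app_count", "lower"] == 0.0


def test_report_tables_layout(small_design):
    design, _ = small_design
    f1 = fit_lmm(design, MLMSpec(outcome="loss_of_interest"))
    design2 = design.rename(columns={"loss_of_interest": "depressed_mood"})
    f2 = fit_lmm(design2, MLMSpec(outcome="depressed_mood"))
    fixed, var = report_tables(f1, f2)
    assert len(fixed) == 11 and fixed.index[0] == "Intercept"
    assert fixed.shape[1] == 6  # estimate, SE, p for each of two models
    assert len(var) == 7
    assert fixed.attrs["footnotes"] == []
    # two-decimal formatting
    assert all("." in v for v in fixed["Model 1 estimate"])

    broken = dataclasses.replace(f2, converged=False)
    fixed2, _ = report_tables(f1, broken)
    assert any("not converge" in n for n in fixed2.attrs["footnotes"])
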