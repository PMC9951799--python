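"""Spline basis, Student-t likelihood, design assembly and small MCMC fits."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from allelometa.model import (ModelSpec, Priors, build_design,
                              log_likelihood_point, fit, spline_basis)
from allelometa.phylo import parse_newick


# ---------------------------------------------------------------- smooth basis

def test_basis_columns_are_centered():
    rng = np.random.default_rng(0)
    x = rng.uniform(0, 3, 200)
    lin, Z, _ = spline_basis(x, k=10)
    assert abs(lin.sum()) < 1e-8
    assert np.allclose(Z.sum(axis=0), 0.0, atol=1e-8)
    # wiggly columns carry no linear trend (orthogonalized against [1, x])
    for j in range(Z.shape[1]):
        slope = np.polyfit(x, Z[:, j], 1)[0]
        assert abs(slope) < 1e-8


def test_two_distinct_values_degrade_to_linear():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lin, Z, basis = spline_basis(np.array([0.0, 1.0] * 10), k=10)
    assert Z.shape[1] == 0
    assert basis.n_wiggly == 0


def test_constant_covariate_is_an_error():
    with pytest.raises(ValueError, match="constant"):
        spline_basis(np.ones(50))


def test_linear_signal_loads_on_the_linear_column():
    """Least-squares oracle: y = 2x + noise recovers the linear coefficient
    on the basis' reportable column, with negligible wiggle."""
    rng = np.random.default_rng(42)
    x = rng.uniform(0, 2, 300)
    y = 2.0 * x + rng.normal(0, 0.05, 300)
    lin, Z, _ = spline_basis(x, k=10)
    X = np.column_stack([np.ones_like(x), lin, Z])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    assert coef[1] == pytest.approx(2.0, abs=0.02)
    wiggle = Z @ coef[2:]
    assert float(np.sqrt((wiggle ** 2).mean())) < 0.02


def test_basis_evaluates_consistently_at_new_points():
    rng = np.random.default_rng(1)
    x = rng.uniform(0, 3, 150)
    _, _, basis = spline_basis(x, k=8)
    lin, Z = basis.evaluate(x[:10])
    assert np.allclose(lin, basis.x_lin[:10])
    assert np.allclose(Z, basis.Z[:10])


# ----------------------------------------------------------------- likelihood

def test_likelihood_normal_limit():
    ll = log_likelihood_point(0.3, 0.1, 0.5, 1e6, 0.2)
    ref = stats.norm.logpdf(0.3, 0.1, math.sqrt(0.5 ** 2 + 0.2 ** 2))
    assert ll == pytest.approx(ref, abs=1e-6)


def test_likelihood_zero_se_is_plain_student_t():
    ll = log_likelihood_point(1.2, 0.0, 0.7, 5.0, 0.0)
    assert ll == pytest.approx(stats.t.logpdf(1.2, df=5, scale=0.7), abs=1e-12)


def test_likelihood_matches_explicit_density_formula():
    """Independent oracle: the Student-t log density written from gamma
    functions, on a 100-point grid."""
    rng = np.random.default_rng(3)
    y = rng.normal(size=100)
    mu, sigma, nu, se = 0.2, 0.4, 7.3, 0.3
    s = math.sqrt(sigma ** 2 + se ** 2)
    z = (y - mu) / s
    ref = (math.lgamma((nu + 1) / 2) - math.lgamma(nu / 2)
           - 0.5 * math.log(nu * math.pi) - math.log(s)
           - (nu + 1) / 2 * np.log1p(z ** 2 / nu))
    assert np.allclose(log_likelihood_point(y, mu, sigma, nu, se), ref,
                       atol=1e-10)


# --------------------------------------------------------------------- design

def _toy_effects(n_per=6):
    rows = []
    rng = np.random.default_rng(0)
    for s, (g, r, go, ro) in enumerate([("A", "C", "native", "native"),
                                        ("B", "D", "native", "native")]):
        for i in range(n_per):
            rows.append(dict(
                study_id=f"s{s}", substudy_id=f"b{i % 2}", trait="germination",
                method_category="m1" if i % 2 else "m2", duration_days=7.0,
                dose_category=f"g/L:{1 + i % 3}", grass_species=g,
                recipient_species=r, grass_origin=go, recipient_origin=ro,
                year_published=2000 + s, d=rng.normal(0, 0.2), se=0.15,
                keep=True))
    return pd.DataFrame(rows)


TOY_TREE = "((A:0.5,B:0.5):0.5,(C:0.7,D:0.3):0.5);"


def test_design_reference_coding_and_partition():
    effects = _toy_effects()
    spec = ModelSpec(kind="full", k_smooth=5)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        design = build_design(effects, parse_newick(TOY_TREE), spec)
    # all-native rows: both origin indicator columns are zero
    assert not design.fixed["beta_grass"].any()
    assert not design.fixed["beta_recipient"].any()
    # group index vectors partition all rows
    for f in design.factors:
        assert f.idx.min() >= 0 and f.idx.max() < f.q
        assert len(f.idx) == design.n


def test_design_rejects_missing_species():
    effects = _toy_effects()
    spec = ModelSpec(kind="full")
    with pytest.raises(ValueError, match="absent from tree"):
        build_design(effects, parse_newick("(A:1,B:1);"), spec)


def test_conspecific_rows_have_zero_distance_covariate():
    effects = _toy_effects()
    effects.loc[:3, "recipient_species"] = effects.loc[:3, "grass_species"]
    spec = ModelSpec(kind="full", k_smooth=5)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        design = build_design(effects, parse_newick(TOY_TREE), spec)
    assert np.allclose(design.logpd[:4], 0.0)


# ------------------------------------------------------------------- sampling

def _flat_effects(y, se):
    n = len(y)
    half = n // 2
    return pd.DataFrame(dict(
        study_id=["s1"] * half + ["s2"] * (n - half),
        substudy_id="b", trait="germination", method_category="m",
        duration_days=7.0, dose_category="g/L:1",
        grass_species=["A"] * half + ["B"] * (n - half),
        recipient_species=["C"] * half + ["D"] * (n - half),
        grass_origin="native", recipient_origin="native",
        year_published=2000, d=y, se=se, keep=True))


def test_normal_limit_matches_inverse_variance_weighted_mean():
    """Conjugate oracle: with nu pinned large, sigma pinned near zero and no
    real heterogeneity, the posterior mean of the summed intercept equals the
    inverse-variance-weighted mean of the observations."""
    rng = np.random.default_rng(9)
    n = 60
    se = rng.uniform(0.1, 0.4, n)
    y = rng.normal(-0.3, 1.0, n) * se / 3 - 0.3  # centred near -0.3
    effects = _flat_effects(y, se)
    priors = Priors(nu_shape=4000.0, nu_rate=4.0,     # nu ~ 1000, Student-t -> normal
                    sigma_scale=1e-3,                 # residual scale pinned ~ 0
                    tau_scale=1e-3)                   # taus pinned ~ 0
    spec = ModelSpec(kind="intercept_only", chains=2, iterations=1500,
                     warmup=500, seed=4, priors=priors)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        design = build_design(effects, parse_newick(TOY_TREE), spec)
        draws = fit(design, spec)
    w = 1.0 / se ** 2
    ivw = float((w * y).sum() / w.sum())
    # prior N(0, 2) on the summed intercept barely shrinks at this precision
    post = draws.stacked("b0_sum")
    assert post.mean() == pytest.approx(ivw, abs=0.02)
    assert post.std() == pytest.approx(math.sqrt(1 / w.sum()), rel=0.35)


def test_zero_heterogeneity_data_yield_small_tau_intervals():
    """On data simulated with no true heterogeneity beyond tiny residual
    noise, every tau's 95% interval reaches below 0.05."""
    from allelometa.simulate import SyntheticConfig, simulate_tree, \
        simulate_dataset
    from allelometa.effects import effect_table
    from allelometa.impute import impute_dose, add_dose_categories

    cfg = SyntheticConfig(seed=21, n_grass=8, n_recipient=12,
                          target_effects=150, sigma=0.02,
                          true_b0_study=0.0, true_b0_species=0.0,
                          true_beta_grass=0.0, true_beta_recipient=0.0,
                          smooth_slope=0.0,
                          taus={k: 0.0 for k in cfg_tau_names()},
                          n_geary_fail=0, missing_dose_frac=0.0)
    tree = simulate_tree(cfg.n_grass + cfg.n_recipient, seed=21)
    records, _ = simulate_dataset(cfg, tree)
    table = effect_table(records)
    kept = table.loc[table["keep"]].reset_index(drop=True)
    completed = add_dose_categories(kept, impute_dose(kept, seed=1)) \
        if kept["dose_value"].isna().any() else kept.assign(
            dose_imputed=False,
            dose_category=[f"g/L:{v:g}" for v in kept["dose_value"]])
    spec = ModelSpec(kind="intercept_only", chains=2, iterations=900,
                     warmup=400, seed=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        design = build_design(completed, tree, spec)
        draws = fit(design, spec)
    for f in design.factors:
        lo = np.quantile(draws.stacked(f"tau_{f.name}"), 0.025)
        assert lo < 0.05, f.name


def cfg_tau_names():
    from allelometa.simulate import DEFAULT_SHARES
    return DEFAULT_SHARES


def test_intercept_sum_recovery():
    """Parameter recovery: data simulated with b0_study + b0_species = -0.3
    returns a posterior mean of the SUM within 0.05 (the addends are only
    prior-identified)."""
    from allelometa.simulate import SyntheticConfig, simulate_tree, \
        simulate_dataset
    from allelometa.effects import effect_table

    cfg = SyntheticConfig(seed=8, n_grass=8, n_recipient=12,
                          target_effects=400, sigma=0.05,
                          true_b0_study=-0.1, true_b0_species=-0.2,
                          true_beta_grass=0.0, true_beta_recipient=0.0,
                          smooth_slope=0.0,
                          taus={k: 0.0 for k in cfg_tau_names()},
                          n_geary_fail=0, missing_dose_frac=0.0)
    tree = simulate_tree(cfg.n_grass + cfg.n_recipient, seed=8)
    records, _ = simulate_dataset(cfg, tree)
    table = effect_table(records)
    kept = table.loc[table["keep"]].reset_index(drop=True)
    kept = kept.assign(dose_imputed=False,
                       dose_category=[f"g/L:{v:g}" for v in kept["dose_value"]])
    spec = ModelSpec(kind="intercept_only", chains=2, iterations=900,
                     warmup=400, seed=3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        design = build_design(kept, tree, spec)
        draws = fit(design, spec)
    assert draws.stacked("b0_sum").mean() == pytest.approx(-0.3, abs=0.05)
    # the run surface reports the sum next to the addends
    names = draws.summary()["parameter"].tolist()
    assert {"b0_sum", "b0_study", "b0_species"} <= set(names)


def test_diagnostics_attached(fitted_full):
    draws, _ = fitted_full
    assert "rhat" in draws.diagnostics and draws.diagnostics["rhat"]
    assert all(np.isfinite(v) for v in draws.diagnostics["rhat"].values())
    assert draws.params["sigma"].shape == (2, 400)
    assert (draws.stacked("nu") > 1).all()
    assert (draws.stacked("sigma") > 0).all()
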