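"""Egger regression, funnel export, year trend, and meta-analytic power."""

import numpy as np
import pytest

from allelometa.bias import (PowerSpec, egger_test, funnel_table,
                             meta_residuals, power_curve, power_meta)


# ----------------------------------------------------------------- residuals

def test_residual_vector_shape_and_centering(fitted_intercept):
    draws, design = fitted_intercept
    resid = meta_residuals(draws, design)
    assert resid.shape == (design.n,)
    # random effects absorb structure; residuals are near-centred
    assert abs(resid.mean()) < 0.05


# --------------------------------------------------------------------- Egger

def test_zero_residuals_give_zero_intercept_and_slope():
    se = np.linspace(0.1, 0.5, 20)
    res = egger_test(np.zeros(20), se)
    assert res.intercept == pytest.approx(0.0, abs=1e-12)
    assert res.slope == pytest.approx(0.0, abs=1e-12)
    assert res.intercept_ci[0] <= 0 <= res.intercept_ci[1]
    assert not res.bias_flagged


def test_egger_matches_normal_equations_oracle():
    """Independently coded weighted normal equations on random datasets."""
    rng = np.random.default_rng(4)
    for _ in range(20):
        n = int(rng.integers(5, 40))
        se = rng.uniform(0.05, 0.6, n)
        e = rng.normal(0, 0.2, n) + 0.3 * se
        res = egger_test(e, se)
        w = 1.0 / se ** 2
        X = np.column_stack([np.ones(n), se])
        beta = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * e))
        assert res.intercept == pytest.approx(beta[0], rel=1e-8, abs=1e-10)
        assert res.slope == pytest.approx(beta[1], rel=1e-8, abs=1e-10)


def test_suppression_asymmetry_is_flagged():
    """Censoring negative low-precision effects shifts the Egger intercept."""
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        se = rng.uniform(0.05, 0.8, 400)
        e = rng.normal(0, se)
        keep = (e > 0) | (se < 0.15)    # negative imprecise studies unpublished
        res = egger_test(e[keep], se[keep])
        hits += res.bias_flagged
    assert hits >= 15


def test_symmetric_funnel_is_usually_clean():
    hits = 0
    for seed in range(20):
        rng = np.random.default_rng(1000 + seed)
        se = rng.uniform(0.05, 0.8, 200)
        e = rng.normal(0, se)
        res = egger_test(e, se)
        hits += not res.bias_flagged
    assert hits >= 18


def test_egger_input_validation():
    with pytest.raises(ValueError, match="at least 3"):
        egger_test(np.zeros(2), np.ones(2))
    with pytest.raises(ValueError, match="> 0"):
        egger_test(np.zeros(5), np.zeros(5))


def test_funnel_contours_collapse_at_zero_se():
    tbl = funnel_table(np.array([0.1, -0.2, 0.0]), np.array([0.0, 0.3, 0.5]))
    assert tbl.loc[0, "lower_95"] == tbl.loc[0, "upper_95"] == 0.0
    assert (tbl["upper_99"] >= tbl["upper_95"]).all()
    assert np.allclose(tbl["upper_95"], -tbl["lower_95"])


# ---------------------------------------------------------------- year trend

def test_year_trend_detects_and_rejects_trends():
    """Simulated no-trend data usually gives a slope CI containing zero; a
    strong trend on log-year is detected."""
    import warnings

    from allelometa.bias import year_trend_fit
    from allelometa.effects import effect_table
    from allelometa.impute import add_dose_categories, impute_dose
    from allelometa.model import ModelSpec
    from allelometa.simulate import SyntheticConfig, simulate_dataset, \
        simulate_tree

    def run(seed, slope):
        cfg = SyntheticConfig(seed=seed, n_grass=10, n_recipient=16,
                              target_effects=220, year_slope=slope)
        tree = simulate_tree(26, seed=seed)
        records, _ = simulate_dataset(cfg, tree)
        table = effect_table(records)
        kept = table.loc[table["keep"]].reset_index(drop=True)
        completed = add_dose_categories(kept, impute_dose(kept, seed=1))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            yt = year_trend_fit(completed, tree,
                                spec=ModelSpec(kind="intercept_only",
                                               chains=2, iterations=700,
                                               warmup=300, seed=seed))
        return yt["slope_ci"]

    null_cis = [run(100 + s, 0.0) for s in range(3)]
    assert sum(lo <= 0 <= hi for lo, hi in null_cis) >= 2
    lo, hi = run(7, 0.8)
    assert lo > 0 or hi < 0


# --------------------------------------------------------------------- power

def test_null_effect_power_equals_alpha():
    spec = PowerSpec(k=23, n1=20, n2=20, d=0.0)
    assert power_meta(spec) == pytest.approx(0.05, abs=1e-9)


def test_power_monotonicity():
    base = dict(n1=20, n2=20, d=0.288)
    powers_k = [power_meta(PowerSpec(k=k, **base)) for k in (2, 5, 10, 23, 50)]
    assert all(a <= b for a, b in zip(powers_k, powers_k[1:]))
    powers_d = [power_meta(PowerSpec(k=23, n1=20, n2=20, d=d))
                for d in (0.0, 0.1, 0.3, 0.6)]
    assert all(a <= b for a, b in zip(powers_d, powers_d[1:]))
    by_het = [power_meta(PowerSpec(k=23, n1=20, n2=20, d=0.288,
                                   heterogeneity=h))
              for h in ("low", "moderate", "high")]
    assert all(a >= b for a, b in zip(by_het, by_het[1:]))


def test_power_approaches_one_with_many_studies():
    assert power_meta(PowerSpec(k=10 ** 6, n1=20, n2=20, d=0.1)) > 0.9999


def test_power_spec_validation():
    with pytest.raises(ValueError):
        power_meta(PowerSpec(k=1, n1=20, n2=20, d=0.2))
    with pytest.raises(ValueError):
        power_meta(PowerSpec(k=10, n1=20, n2=20, d=-0.2))
    with pytest.raises(ValueError):
        power_meta(PowerSpec(k=10, n1=20, n2=20, d=0.2, heterogeneity="huge"))


def test_power_curve_covers_requested_k():
    spec = PowerSpec(k=23, n1=20, n2=20, d=0.288)
    curve = power_curve(spec)
    assert curve["k"].min() == 2
    assert (curve["power"].diff().dropna() >= -1e-12).all()
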