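"""Hypothesis contrasts, cell predictions, variance shares, LOO/WAIC."""

import math
from types import SimpleNamespace

import numpy as np
import pytest
from scipy import stats

from allelometa.inference import (compare_models, contrast_draws,
                                  hypothesis_test, hypotheses_table, loo_waic,
                                  predict_cell, variance_decomposition)
from allelometa.model import PosteriorDraws


def _draws(**params):
    shaped = {k: np.asarray(v)[None, :] if np.asarray(v).ndim == 1
              else np.asarray(v) for k, v in params.items()}
    factor_names = [k.removeprefix("tau_") for k in params if
                    k.startswith("tau_")]
    return PosteriorDraws(params=shaped, group_labels={},
                          design_meta={"factor_names": factor_names,
                                       "smooth_names": []})


def test_degenerate_draws_give_certain_result():
    d = _draws(beta_grass=np.full(500, -0.2))
    h = hypothesis_test(d, "NWH")
    assert h.estimate == pytest.approx(-0.2)
    assert h.ci_low == h.ci_high == pytest.approx(-0.2)
    assert h.p_direction == 1.0 and h.supported


def test_symmetric_draws_are_not_supported():
    rng = np.random.default_rng(0)
    vals = rng.normal(0, 1, 20_000)
    h = hypothesis_test(_draws(beta_recipient=vals), "BRH")
    assert h.p_direction == pytest.approx(0.5, abs=0.02)
    assert h.ci_low < 0 < h.ci_high
    assert not h.supported


def test_quantiles_match_sorting_oracle():
    rng = np.random.default_rng(5)
    vals = rng.standard_t(4, 9999)
    h = hypothesis_test(_draws(gamma_smooth_linear=vals), "PDH")
    srt = np.sort(vals)
    lo_idx = 0.025 * (len(srt) - 1)
    hi_idx = 0.975 * (len(srt) - 1)

    def interp(q_idx):
        f = int(math.floor(q_idx))
        frac = q_idx - f
        return srt[f] * (1 - frac) + srt[min(f + 1, len(srt) - 1)] * frac
    assert h.ci_low == pytest.approx(interp(lo_idx), rel=1e-10)
    assert h.ci_high == pytest.approx(interp(hi_idx), rel=1e-10)
    assert h.p_direction == pytest.approx((vals < 0).mean())


def test_interval_endpoints_monotone_in_level():
    rng = np.random.default_rng(1)
    d = _draws(beta_grass=rng.normal(size=5000))
    levels = [0.5, 0.8, 0.9, 0.95, 0.99]
    results = [hypothesis_test(d, "NWH", level=lv) for lv in levels]
    los = [r.ci_low for r in results]
    his = [r.ci_high for r in results]
    assert all(a >= b for a, b in zip(los, los[1:]))
    assert all(a <= b for a, b in zip(his, his[1:]))


def test_unknown_parameter_errors():
    with pytest.raises(KeyError):
        contrast_draws(_draws(beta_grass=np.ones(10)), {"nope": 1.0})


def test_variance_decomposition_closed_cases():
    n = 400
    d = _draws(tau_study=np.ones(n), sigma=np.ones(n))
    vd = variance_decomposition(d)
    assert vd.proportions["study"] == pytest.approx(0.5)
    assert vd.residual_proportion == pytest.approx(0.5)

    d2 = _draws(tau_a=np.full(n, 3.0), tau_b=np.full(n, 4.0),
                sigma=np.zeros(n))
    vd2 = variance_decomposition(d2)
    assert vd2.proportions["a"] == pytest.approx(9 / 25)
    assert vd2.proportions["b"] == pytest.approx(16 / 25)


def test_variance_proportions_sum_to_one(fitted_intercept):
    draws, _ = fitted_intercept
    vd = variance_decomposition(draws)
    total = sum(vd.proportions.values()) + vd.residual_proportion
    assert total == pytest.approx(1.0, abs=1e-9)
    rom_total = sum(vd.ratio_of_means.values())
    assert rom_total == pytest.approx(1.0, abs=1e-9)


def test_cell_prediction_additivity(fitted_full):
    draws, design = fitted_full
    nn = predict_cell(draws, design, "nonnative", "native")
    nat = predict_cell(draws, design, "native", "native")
    # same-cell difference is identically zero per draw
    assert np.allclose(nat.draws - nat.draws, 0.0)
    # (nonnative x native) - (native x native) equals the grass-origin
    # contrast plus the smooth offset between the two cells' mean distances
    from allelometa.inference import _smooth_value
    contrast = draws.stacked("beta_grass") \
        + _smooth_value(draws, design, nn.logpd_used) \
        - _smooth_value(draws, design, nat.logpd_used)
    assert np.allclose(nn.draws - nat.draws, contrast)


def test_hypotheses_table_layout(fitted_full):
    draws, _ = fitted_full
    tbl = hypotheses_table(draws)
    assert list(tbl["hypothesis"]) == ["NWH", "BRH", "PDH"]
    assert ((tbl["ci_low"] < tbl["ci_high"]).all())
    assert tbl["p_direction"].between(0, 1).all()


def test_loo_of_model_against_itself_has_zero_elpd_difference(fitted_full):
    draws, design = fitted_full
    cmp = compare_models(draws, design, draws, design, names=("a", "b"))
    assert cmp["elpd_diff"].abs().max() == pytest.approx(0.0, abs=1e-7)


def test_waic_matches_closed_form_for_conjugate_normal():
    """Analytic oracle: iid N(mu, 1) data with mu | y ~ N(m, v).  Then
    elpd_waic_i = log phi(y_i; m, sqrt(1+v)) - [v^2/2 + v (y_i - m)^2]."""
    rng = np.random.default_rng(12)
    n, true_mu = 40, 0.3
    y = rng.normal(true_mu, 1.0, n)
    m, v = y.mean(), 1.0 / n
    S = 8000
    mu_draws = rng.normal(m, math.sqrt(v), S)
    params = {"mu": np.broadcast_to(mu_draws[None, :, None], (1, S, n)).copy(),
              "sigma": np.full((1, S), 1.0),
              "nu": np.full((1, S), 1e7),
              "b0_sum": mu_draws[None, :]}
    draws = PosteriorDraws(params=params, group_labels={},
                           design_meta={"factor_names": [],
                                        "smooth_names": []})
    design = SimpleNamespace(y=y, se_obs=np.zeros(n))
    res = loo_waic(draws, design)
    lppd = stats.norm.logpdf(y, m, math.sqrt(1 + v))
    p_waic = v ** 2 / 2 + v * (y - m) ** 2
    closed = float((lppd - p_waic).sum())
    assert res["elpd_waic"] == pytest.approx(closed, abs=0.15)
    assert res["elpd_loo"] == pytest.approx(closed, abs=0.3)
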