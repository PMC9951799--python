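"""Posterior inference: directional hypothesis tests, cell-mean predictions,
variance decomposition and LOO/WAIC model comparison.

The three invasion-biology hypotheses map onto single model coefficients, all
predicted negative a priori:

* Novel Weapons (NWH): effect of grass origin (non-native vs native) on
  allelopathic impact — ``beta_grass``.
* Biotic Resistance (BRH): effect of recipient origin — ``beta_recipient``.
* Phylogenetic Distance (PDH): the linear (unpenalized) coefficient of the
  smoothed log phylogenetic distance — ``gamma_smooth_linear``.

Intervals are equal-tailed posterior quantiles; the directional evidence is
the posterior probability of the predicted sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ModelDesign, PosteriorDraws, log_likelihood_point

#: hypothesis name -> (contrast, predicted sign)
STANDARD_HYPOTHESES: dict[str, tuple[dict[str, float], str]] = {
    "NWH": ({"beta_grass": 1.0}, "negative"),
    "BRH": ({"beta_recipient": 1.0}, "negative"),
    "PDH": ({"gamma_smooth_linear": 1.0}, "negative"),
}


@dataclass(frozen=True)
class HypothesisResult:
    name: str
    estimate: float
    ci_low: float
    ci_high: float
    level: float
    p_direction: float
    direction: str
    supported: bool


@dataclass(frozen=True)
class VarianceDecomposition:
    proportions: dict[str, float]       # posterior mean of per-draw ratios
    residual_proportion: float
    ratio_of_means: dict[str, float]    # alternative: ratios of posterior means

    def to_frame(self) -> pd.DataFrame:
        rows = [{"component": k, "proportion": v, "percent": 100 * v}
                for k, v in self.proportions.items()]
        rows.append({"component": "residual", "proportion": self.residual_proportion,
                     "percent": 100 * self.residual_proportion})
        return pd.DataFrame(rows)


def contrast_draws(draws: PosteriorDraws, contrast: dict[str, float]) -> np.ndarray:
    out = None
    for name, weight in contrast.items():
        if name not in draws.params:
            raise KeyError(f"parameter {name!r} not found in draws")
        term = weight * draws.stacked(name)
        out = term if out is None else out + term
    return out


def hypothesis_test(draws: PosteriorDraws,
                    contrast: str | dict[str, float],
                    level: float = 0.95,
                    direction: str = "negative",
                    name: str | None = None) -> HypothesisResult:
    """Evaluate a named or explicit linear contrast of posterior draws.

    ``supported`` is True when the bound on the predicted side excludes zero
    at the requested level (for a negative prediction: upper bound < 0).
    """
    if isinstance(contrast, str):
        name = name or contrast
        contrast, direction = STANDARD_HYPOTHESES[contrast]
    vals = contrast_draws(draws, contrast)
    alpha = 1.0 - level
    lo, hi = np.quantile(vals, [alpha / 2, 1 - alpha / 2])
    if direction == "negative":
        p_dir = float((vals < 0).mean())
        supported = hi < 0
    else:
        p_dir = float((vals > 0).mean())
        supported = lo > 0
    return HypothesisResult(name or "contrast", float(vals.mean()),
                            float(lo), float(hi), level, p_dir, direction,
                            bool(supported))


def hypotheses_table(draws: PosteriorDraws, level: float = 0.95) -> pd.DataFrame:
    """All three standard hypotheses in the layout of the published table."""
    rows = []
    for name in STANDARD_HYPOTHESES:
        h = hypothesis_test(draws, name, level=level)
        rows.append({"hypothesis": name, "estimate": h.estimate,
                     "ci_low": h.ci_low, "ci_high": h.ci_high,
                     "p_direction": h.p_direction, "supported": h.supported})
    return pd.DataFrame(rows)


def _smooth_value(draws: PosteriorDraws, design: ModelDesign, x: float) -> np.ndarray:
    term = next((s for s in design.smooths if s.name == "gamma_smooth_linear"), None)
    if term is None:
        return np.zeros(draws.n_chains * draws.n_draws)
    lin, Z = term.basis.evaluate(np.array([x]))
    glin = draws.stacked("gamma_smooth_linear")
    wig = draws.stacked("wiggly_gamma_smooth_linear")
    return glin * lin[0] + wig @ Z[0]


@dataclass(frozen=True)
class CellPrediction:
    grass_origin: str
    recipient_origin: str
    draws: np.ndarray
    mean: float
    ci_low: float
    ci_high: float
    p_negative: float
    logpd_used: float


def predict_cell(draws: PosteriorDraws, design: ModelDesign,
                 grass_origin: str, recipient_origin: str,
                 level: float = 0.95) -> CellPrediction:
    """Posterior distribution of the average effect size in one origin cell.

    The cell mean combines both intercepts, the origin coefficients and the
    distance smooth evaluated at the mean log-distance of the cell's rows
    (overall mean with a warning if the cell is empty).
    """
    rows = design.rows
    mask = ((rows["grass_origin"].astype(str) == grass_origin)
            & (rows["recipient_origin"].astype(str) == recipient_origin))
    if mask.any():
        logpd = float(design.logpd[mask.to_numpy()].mean())
    else:
        import warnings
        warnings.warn(f"no rows in cell {grass_origin} x {recipient_origin}; "
                      "using overall mean log-distance", stacklevel=2)
        logpd = float(design.logpd.mean())
    vals = draws.stacked("b0_sum").copy()
    if "beta_grass" in draws.params and grass_origin == "nonnative":
        vals = vals + draws.stacked("beta_grass")
    if "beta_recipient" in draws.params and recipient_origin == "nonnative":
        vals = vals + draws.stacked("beta_recipient")
    vals = vals + _smooth_value(draws, design, logpd)
    alpha = 1.0 - level
    lo, hi = np.quantile(vals, [alpha / 2, 1 - alpha / 2])
    return CellPrediction(grass_origin, recipient_origin, vals,
                          float(vals.mean()), float(lo), float(hi),
                          float((vals < 0).mean()), logpd)


def variance_decomposition(draws: PosteriorDraws,
                           inflate_residual: bool = False) -> VarianceDecomposition:
    """Share of variance attributed to each random effect and the residual.

    Per draw, component r contributes tau_r^2 / (sum_r tau_r^2 + sigma^2);
    reported values are posterior means of these ratios (the ratio-of-
    posterior-means variant is also returned).  ``inflate_residual`` swaps
    sigma^2 for the Student-t variance sigma^2 * nu/(nu-2).
    """
    names = [f"tau_{f}" for f in draws.design_meta["factor_names"]]
    taus2 = {n: draws.stacked(n) ** 2 for n in names}
    sig2 = draws.stacked("sigma") ** 2
    if inflate_residual:
        nu = draws.stacked("nu")
        sig2 = sig2 * np.where(nu > 2, nu / (nu - 2), np.inf)
    total = sum(taus2.values()) + sig2
    props = {n.removeprefix("tau_"): float((t2 / total).mean())
             for n, t2 in taus2.items()}
    resid = float((sig2 / total).mean())
    mean_t2 = {n: t2.mean() for n, t2 in taus2.items()}
    mean_total = sum(mean_t2.values()) + sig2.mean()
    rom = {n.removeprefix("tau_"): float(t2 / mean_total)
           for n, t2 in mean_t2.items()}
    rom["residual"] = float(sig2.mean() / mean_total)
    return VarianceDecomposition(props, resid, rom)


def pointwise_log_likelihood(draws: PosteriorDraws,
                             design: ModelDesign) -> np.ndarray:
    """(chain, draw, obs) log-likelihood matrix from stored mu draws."""
    if "mu" not in draws.params:
        raise ValueError("fit was run with store_mu=False; cannot compute LOO")
    mu = draws.params["mu"]
    sigma = draws.params["sigma"][..., None]
    nu = draws.params["nu"][..., None]
    return log_likelihood_point(design.y[None, None, :], mu, sigma, nu,
                                design.se_obs[None, None, :])


def _to_idata(draws: PosteriorDraws, design: ModelDesign):
    import arviz as az
    ll = pointwise_log_likelihood(draws, design)
    return az.from_dict(posterior={"b0_sum": draws.params["b0_sum"]},
                        log_likelihood={"y": ll})


def loo_waic(draws: PosteriorDraws, design: ModelDesign) -> dict:
    """PSIS-LOO and WAIC with standard errors and Pareto-k diagnostics."""
    import arviz as az
    idata = _to_idata(draws, design)
    loo = az.loo(idata, pointwise=True)
    waic = az.waic(idata, pointwise=True)
    k = np.asarray(loo.pareto_k)
    frac_bad = float((k > 0.7).mean())
    result = {"elpd_loo": float(loo.elpd_loo), "se_loo": float(loo.se),
              "p_loo": float(loo.p_loo),
              "elpd_waic": float(waic.elpd_waic), "se_waic": float(waic.se),
              "p_waic": float(waic.p_waic),
              "pareto_k": k, "frac_pareto_k_above_0.7": frac_bad,
              "loo_pointwise": np.asarray(loo.loo_i),
              "warnings": []}
    if frac_bad > 0.10:
        result["warnings"].append(
            f"{100 * frac_bad:.0f}% of Pareto-k values exceed 0.7")
    return result


def compare_models(draws_a: PosteriorDraws, design_a: ModelDesign,
                   draws_b: PosteriorDraws, design_b: ModelDesign,
                   names: tuple[str, str] = ("full", "intercept")) -> pd.DataFrame:
    """LOO comparison table (elpd difference and its SE) for two fitted models."""
    import arviz as az
    cmp = az.compare({names[0]: _to_idata(draws_a, design_a),
                      names[1]: _to_idata(draws_b, design_b)}, ic="loo")
    return cmp.reset_index().rename(columns={"index": "model"})
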