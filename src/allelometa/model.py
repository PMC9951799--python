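"""The two-component hierarchical Bayesian meta-analytic model.

The observed effect size of row i is modelled with a Student-t
measurement-error likelihood,

    y_i ~ Student-t(nu, mu_i, sqrt(sigma^2 + se_i^2))

where se_i is the known sampling SE of the delta log response ratio, sigma is
the residual heterogeneity scale and one nu is shared across the likelihood
(heavy tails absorb outliers).  The linear predictor is the sum of a *study*
component and a *species* component,

    mu_i = [b0_study + sum of study-design random effects]
         + [b0_species + beta_grass * NNg_i + beta_recipient * NNr_i
            + f(logPD_i) + species random effects]

Study-side random effects: study ID, sub-study nested in study, trait nested
in sub-study; method category, duration nested in method; dose category.
Species-side random effects: grass species, recipient species, and both
species again with covariance constrained by the phylogenetic correlation
matrix, u ~ MVN(0, tau^2 A).  f is a low-rank penalized spline of log-scaled
phylogenetic distance whose unpenalized linear component is a single
reportable coefficient; the wiggly coefficients share one smoothing SD
treated as another tau.

Because mu is a sum of two intercepts, only b0_study + b0_species is
data-identified; each addend is identified only through its normal(0, 1)
prior.  Summaries therefore always report the sum alongside the addends.

Fitting uses a blocked Gibbs sampler: the Student-t is represented as a
normal scale mixture (per-observation gamma weights), all location blocks
then have conjugate normal conditionals, variance components get half-t
priors via the inverse-gamma parameter expansion, and sigma and nu are
updated by adaptive random-walk Metropolis on the log scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline
from scipy.linalg import cho_solve, cholesky, solve_triangular

from .phylo import Phylogeny, PhyloCovariance, DistanceCovariate, \
    log_scaled_distance, patristic_matrix, phylo_correlation, check_coverage, jittered

STUDY_SIDE = ("study", "substudy", "trait_in_substudy", "method",
              "duration_in_method", "dose")
SPECIES_SIDE = ("grass_species", "recipient_species",
                "grass_species_tree", "recipient_species_tree")


# --------------------------------------------------------------------------
# specification


@dataclass
class Priors:
    """Weakly-informative defaults mirroring the usual meta-analytic choices."""

    intercept_sd: float = 1.0
    beta_sd: float = 1.0
    tau_df: float = 3.0
    tau_scale: float = 2.5
    sigma_df: float = 3.0
    sigma_scale: float = 2.5
    nu_shape: float = 2.0
    nu_rate: float = 0.1
    nu_min: float = 1.0


@dataclass
class ModelSpec:
    kind: Literal["full", "intercept_only"] = "full"
    chains: int = 4
    iterations: int = 2000      # per chain, including warmup
    warmup: int = 1000
    seed: int = 1
    k_smooth: int = 10
    priors: Priors = field(default_factory=Priors)
    store_mu: bool = True


# --------------------------------------------------------------------------
# penalized spline basis


class SmoothBasis:
    """Low-rank penalized spline of one covariate.

    A cubic B-spline basis with quantile knots is penalized by second
    differences of its coefficients; eigen-decomposing the penalty splits the
    fit into an unpenalized linear column (the reportable coefficient) and
    penalized "wiggly" columns orthogonalized against the linear trend, whose
    coefficients are exchangeable N(0, tau_smooth^2).
    """

    def __init__(self, x: np.ndarray, k: int = 10):
        x = np.asarray(x, dtype=float)
        distinct = np.unique(x)
        if distinct.size < 2:
            raise ValueError("smooth covariate is constant; basis degenerates")
        k_eff = int(min(k, distinct.size))
        if k_eff < k:
            warnings.warn(f"smooth basis reduced from k={k} to k={k_eff} "
                          f"({distinct.size} distinct covariate values)",
                          stacklevel=2)
        self.x_min = float(distinct[0])
        self.x_max = float(distinct[-1])
        self.x_mean = float(x.mean())
        self.k = k_eff
        if k_eff < 4:
            # too few distinct values for a cubic wiggle: linear only
            self._knots = None
            self._transform = None
            self._proj = None
        else:
            degree = 3
            n_interior = k_eff - degree - 1
            if n_interior > 0:
                qs = np.linspace(0, 1, n_interior + 2)[1:-1]
                interior = np.quantile(distinct, qs)
            else:
                interior = np.array([])
            t = np.concatenate([[self.x_min] * (degree + 1), interior,
                                [self.x_max] * (degree + 1)])
            self._knots = (t, degree)
            B = BSpline.design_matrix(np.clip(x, self.x_min, self.x_max),
                                      t, degree).toarray()
            K = B.shape[1]
            D = np.diff(np.eye(K), n=2, axis=0)
            S = D.T @ D
            vals, vecs = np.linalg.eigh(S)
            keep = vals > 1e-10 * vals.max()
            self._transform = vecs[:, keep] / np.sqrt(vals[keep])
            Zraw = B @ self._transform
            C = np.column_stack([np.ones_like(x), x])
            self._proj, *_ = np.linalg.lstsq(C, Zraw, rcond=None)
        self.x_lin, self.Z = self.evaluate(x)

    @property
    def n_wiggly(self) -> int:
        return 0 if self._transform is None else self._transform.shape[1]

    def evaluate(self, x_new) -> tuple[np.ndarray, np.ndarray]:
        """Linear column and wiggly columns at new covariate values
        (clamped to the training range)."""
        x_new = np.atleast_1d(np.asarray(x_new, dtype=float))
        lin = x_new - self.x_mean
        if self._transform is None:
            return lin, np.zeros((x_new.size, 0))
        t, degree = self._knots
        xc = np.clip(x_new, self.x_min, self.x_max)
        B = BSpline.design_matrix(xc, t, degree).toarray()
        Zraw = B @ self._transform
        C = np.column_stack([np.ones_like(x_new), x_new])
        return lin, Zraw - C @ self._proj


def spline_basis(x, k: int = 10) -> tuple[np.ndarray, np.ndarray, SmoothBasis]:
    """Convenience wrapper returning (linear column, wiggly columns, basis)."""
    basis = SmoothBasis(np.asarray(x, dtype=float), k=k)
    return basis.x_lin, basis.Z, basis


# --------------------------------------------------------------------------
# design


@dataclass
class Factor:
    name: str
    side: str                      # "study" or "species"
    levels: list
    idx: np.ndarray                # row -> level index
    A: np.ndarray | None = None    # phylogenetic correlation (tree factors)
    #: coefficient name -> boolean mask over levels; a shift of the
    #: coefficient is exactly compensated by shifting these levels' effects
    #: (used by the sampler's recentering sweeps)
    alignments: dict = field(default_factory=dict)

    @property
    def q(self) -> int:
        return len(self.levels)


@dataclass
class SmoothTerm:
    name: str                      # reportable linear coefficient name
    tau_name: str
    side: str
    basis: SmoothBasis
    x_lin: np.ndarray
    Z: np.ndarray


@dataclass
class ModelDesign:
    y: np.ndarray
    se_obs: np.ndarray
    fixed: dict[str, np.ndarray]
    smooths: list[SmoothTerm]
    factors: list[Factor]
    logpd: np.ndarray
    rows: pd.DataFrame
    phylo_cov: PhyloCovariance | None

    @property
    def n(self) -> int:
        return self.y.size


def _nested(*cols) -> pd.Series:
    out = cols[0].astype(str)
    for c in cols[1:]:
        out = out + "/" + c.astype(str)
    return out


def build_design(effects: pd.DataFrame, phylo: Phylogeny, spec: ModelSpec,
                 year_smooth: bool = False) -> ModelDesign:
    """Assemble the model design from a completed effect table and a tree.

    Expects the table produced by :func:`allelometa.effects.effect_table`
    after dose imputation (``dose_category`` complete); only rows flagged
    ``keep`` enter.  Origin factors are dummy-coded with native as reference.
    """
    df = effects.loc[effects.get("keep", True) & effects["d"].notna()].copy()
    if "dose_category" not in df.columns:
        raise ValueError("dose_category missing: run dose imputation first")
    species = set(df["grass_species"]) | set(df["recipient_species"])
    check_coverage(phylo, species)
    dist = patristic_matrix(phylo)
    cov = phylo_correlation(phylo)
    order = {s: i for i, s in enumerate(cov.species_order)}
    pd_vals = np.array([dist.pd_matrix[order[g], order[r]]
                        for g, r in zip(df["grass_species"], df["recipient_species"])])
    logpd = log_scaled_distance(pd_vals)

    factor_defs = {
        "study": ("study", df["study_id"].astype(str)),
        "substudy": ("study", _nested(df["study_id"], df["substudy_id"])),
        "trait_in_substudy": ("study", _nested(df["study_id"], df["substudy_id"],
                                               df["trait"])),
        "method": ("study", df["method_category"].astype(str)),
        "duration_in_method": ("study", _nested(df["method_category"],
                                                df["duration_days"])),
        "dose": ("study", df["dose_category"].astype(str)),
        "grass_species": ("species", df["grass_species"].astype(str)),
        "recipient_species": ("species", df["recipient_species"].astype(str)),
    }
    factors: list[Factor] = []
    for name, (side, series) in factor_defs.items():
        codes, levels = pd.factorize(series, sort=True)
        if len(levels) < 2:
            warnings.warn(f"random effect {name!r} has a single level; dropped",
                          stacklevel=2)
            continue
        factors.append(Factor(name, side, list(levels), codes.astype(np.int64)))

    # tree-linked species effects share the full species panel so that the
    # phylogenetic correlation applies across grasses and recipients alike
    for name, col in (("grass_species_tree", "grass_species"),
                      ("recipient_species_tree", "recipient_species")):
        codes = df[col].map(order).to_numpy(dtype=np.int64)
        factors.append(Factor(name, "species", list(cov.species_order), codes,
                              A=cov.A))

    fixed: dict[str, np.ndarray] = {}
    smooths: list[SmoothTerm] = []
    if spec.kind == "full":
        fixed["beta_grass"] = (df["grass_origin"].astype(str) == "nonnative"
                               ).to_numpy(dtype=float)
        fixed["beta_recipient"] = (df["recipient_origin"].astype(str) == "nonnative"
                                   ).to_numpy(dtype=float)
        lin, Z, basis = spline_basis(logpd, k=spec.k_smooth)
        smooths.append(SmoothTerm("gamma_smooth_linear", "tau_smooth",
                                  "species", basis, lin, Z))
    if year_smooth:
        yr = df["year_published"].astype(float)
        if yr.nunique() < 2:
            raise ValueError("year smooth requires at least two distinct years")
        x = np.log(yr - yr.min() + 1.0)
        lin, Z, basis = spline_basis(x.to_numpy(), k=spec.k_smooth)
        smooths.append(SmoothTerm("gamma_year_linear", "tau_year_smooth",
                                  "study", basis, lin, Z))

    # recentering metadata: every factor is aligned with its side's intercept
    # (all levels); the origin coefficients are additionally aligned with the
    # non-native subset of the matching species factors
    for f in factors:
        b0_name = "b0_study" if f.side == "study" else "b0_species"
        f.alignments[b0_name] = np.ones(f.q, dtype=bool)
    if fixed:
        nn_grass = set(df.loc[df["grass_origin"].astype(str) == "nonnative",
                              "grass_species"].astype(str))
        nn_recip = set(df.loc[df["recipient_origin"].astype(str) == "nonnative",
                              "recipient_species"].astype(str))
        targets = {"grass_species": ("beta_grass", nn_grass),
                   "grass_species_tree": ("beta_grass", nn_grass),
                   "recipient_species": ("beta_recipient", nn_recip),
                   "recipient_species_tree": ("beta_recipient", nn_recip)}
        for f in factors:
            if f.name in targets:
                coef, subset = targets[f.name]
                mask = np.array([str(l) in subset for l in f.levels])
                if mask.any():
                    f.alignments[coef] = mask

    return ModelDesign(
        y=df["d"].to_numpy(dtype=float),
        se_obs=df["se"].to_numpy(dtype=float),
        fixed=fixed, smooths=smooths, factors=factors, logpd=logpd,
        rows=df.reset_index(drop=True), phylo_cov=cov,
    )


# --------------------------------------------------------------------------
# likelihood


def log_likelihood_point(y, mu, sigma, nu, se):
    """Pointwise log density: Student-t(nu, mu, sqrt(sigma^2 + se^2)) at y."""
    scale = np.sqrt(np.asarray(sigma) ** 2 + np.asarray(se) ** 2)
    return stats.t.logpdf(np.asarray(y), df=nu, loc=mu, scale=scale)


# --------------------------------------------------------------------------
# posterior container


@dataclass
class PosteriorDraws:
    """Labelled MCMC draws: scalars as (chain, draw), blocks as (chain, draw, dim)."""

    params: dict[str, np.ndarray]
    group_labels: dict[str, list]
    design_meta: dict
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return next(iter(self.params.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.params.values())).shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """Draws for one parameter flattened across chains."""
        arr = self.params[name]
        return arr.reshape(-1, *arr.shape[2:])

    def scalar_names(self) -> list[str]:
        return [k for k, v in self.params.items() if v.ndim == 2]

    def summary(self) -> pd.DataFrame:
        rows = []
        for name in self.scalar_names():
            s = self.stacked(name)
            lo, hi = np.quantile(s, [0.025, 0.975])
            rows.append({"parameter": name, "mean": s.mean(), "sd": s.std(),
                         "q2.5": lo, "q97.5": hi,
                         "rhat": self.diagnostics.get("rhat", {}).get(name, np.nan)})
        return pd.DataFrame(rows)

    def to_long_frame(self) -> pd.DataFrame:
        """Columnar (chain, draw, parameter, value) export for scalars."""
        rows = []
        for name in self.scalar_names():
            arr = self.params[name]
            for c in range(arr.shape[0]):
                for d in range(arr.shape[1]):
                    rows.append((c, d, name, arr[c, d]))
        return pd.DataFrame(rows, columns=["chain", "draw", "parameter", "value"])


# --------------------------------------------------------------------------
# sampler internals


def _half_t_logpdf(x, df, scale):
    if x <= 0:
        return -np.inf
    return math.log(2.0) + stats.t.logpdf(x, df=df, scale=scale)


def _inv_gamma(rng, shape, rate):
    return rate / rng.gamma(shape)


class _Adaptive:
    """Log-scale random-walk Metropolis step with Robbins-Monro adaptation."""

    def __init__(self, value, step=0.3, target=0.44):
        self.value = value
        self.step = step
        self.target = target
        self.accepted = 0
        self.tried = 0

    def propose(self, rng):
        return self.value * math.exp(self.step * rng.standard_normal())

    def update(self, accepted, adapting, it):
        self.tried += 1
        self.accepted += accepted
        if adapting:
            rate = 1.0 / max(10, it) ** 0.6
            self.step *= math.exp(rate * ((1.0 if accepted else 0.0) - self.target))
            self.step = min(max(self.step, 1e-3), 5.0)


def _run_chain(design: ModelDesign, spec: ModelSpec, seed: int):
    rng = np.random.default_rng(seed)
    y, se = design.y, design.se_obs
    n = y.size
    pri = spec.priors
    se2 = se ** 2

    factors = design.factors
    A_chol_inv = {}
    for f in factors:
        if f.A is not None:
            L = cholesky(jittered(f.A), lower=True)
            Ainv = cho_solve((L, True), np.eye(f.q))
            A_chol_inv[f.name] = Ainv

    # scalar coefficient block: intercept pair, fixed effects, smooth linears
    coef_cols: dict[str, np.ndarray] = {"b0_study": np.ones(n),
                                        "b0_species": np.ones(n)}
    coef_prior_sd: dict[str, float] = {"b0_study": pri.intercept_sd,
                                       "b0_species": pri.intercept_sd}
    for k, x in design.fixed.items():
        coef_cols[k] = x
        coef_prior_sd[k] = pri.beta_sd
    for s in design.smooths:
        coef_cols[s.name] = s.x_lin
        coef_prior_sd[s.name] = pri.beta_sd
    coef_names = list(coef_cols)
    Xs = np.column_stack([coef_cols[k] for k in coef_names])
    prior_prec_diag = np.array([1.0 / coef_prior_sd[k] ** 2 for k in coef_names])

    coef = {k: 0.0 for k in coef_names}
    coef["b0_study"] = coef["b0_species"] = float(y.mean()) / 2.0
    gwig = {s.name: np.zeros(s.Z.shape[1]) for s in design.smooths}
    u = {f.name: np.zeros(f.q) for f in factors}
    tau = {f.name: 0.25 for f in factors}
    a_aux = {f.name: 1.0 for f in factors}
    # smooths degraded to linear-only have no wiggly block, hence no
    # smoothing SD to sample
    tau_s = {s.tau_name: 0.25 for s in design.smooths if s.Z.shape[1]}
    a_s = {s.tau_name: 1.0 for s in design.smooths if s.Z.shape[1]}
    sigma = _Adaptive(max(0.1, float(y.std()) / 2.0))
    nu = _Adaptive(10.0)
    nc_steps = {f.name: _Adaptive(0.25) for f in factors}
    lam = np.ones(n)

    fitted = np.full(n, coef["b0_study"] + coef["b0_species"])

    n_keep = spec.iterations - spec.warmup
    out = {name: np.empty(n_keep) for name in
           coef_names + ["sigma", "nu", "b0_sum"]
           + [f"tau_{f.name}" for f in factors] + list(tau_s)}
    out_wig = {s.name: np.empty((n_keep, s.Z.shape[1])) for s in design.smooths}
    out_u = {f.name: np.empty((n_keep, f.q)) for f in factors}
    out_mu = np.empty((n_keep, n)) if spec.store_mu else None

    for it in range(spec.iterations):
        s2 = sigma.value ** 2 + se2
        w = lam / s2

        # joint conditional for the whole scalar block: the two intercepts
        # (identified only as a sum) and any correlated fixed effects mix in
        # one multivariate normal draw instead of a sequential random walk
        theta = np.array([coef[k] for k in coef_names])
        block = Xs @ theta
        r = y - (fitted - block)
        M = Xs.T @ (w[:, None] * Xs) + np.diag(prior_prec_diag)
        b = Xs.T @ (w * r)
        L = cholesky(M, lower=True)
        mean = cho_solve((L, True), b)
        theta_new = mean + solve_triangular(L.T, rng.standard_normal(len(theta)))
        fitted += Xs @ theta_new - block
        coef.update(zip(coef_names, theta_new))

        for s in design.smooths:
            m = s.Z.shape[1]
            if m:
                r = y - (fitted - s.Z @ gwig[s.name])
                M = s.Z.T @ (w[:, None] * s.Z) + np.eye(m) / tau_s[s.tau_name] ** 2
                b = s.Z.T @ (w * r)
                L = cholesky(M, lower=True)
                mean = cho_solve((L, True), b)
                new_w = mean + solve_triangular(L.T, rng.standard_normal(m))
                fitted += s.Z @ (new_w - gwig[s.name])
                gwig[s.name] = new_w
                ss = float(new_w @ new_w)
                t2 = _inv_gamma(rng, (pri.tau_df + m) / 2.0,
                                pri.tau_df / a_s[s.tau_name] + ss / 2.0)
                tau_s[s.tau_name] = math.sqrt(max(t2, 1e-12))
                a_s[s.tau_name] = _inv_gamma(rng, (pri.tau_df + 1) / 2.0,
                                             pri.tau_df / t2 + 1.0 / pri.tau_scale ** 2)

        for f in factors:
            uf = u[f.name]
            r = y - (fitted - uf[f.idx])
            wsum = np.bincount(f.idx, weights=w, minlength=f.q)
            wr = np.bincount(f.idx, weights=w * r, minlength=f.q)
            Ainv = A_chol_inv.get(f.name)
            if Ainv is None:
                prec = wsum + 1.0 / tau[f.name] ** 2
                new_u = wr / prec + rng.standard_normal(f.q) / np.sqrt(prec)
            else:
                P = np.diag(wsum) + Ainv / tau[f.name] ** 2
                L = cholesky(P, lower=True)
                mean = cho_solve((L, True), wr)
                new_u = mean + solve_triangular(L.T, rng.standard_normal(f.q))
            fitted += new_u[f.idx] - uf[f.idx]

            # recentering sweeps: a shift of an aligned coefficient (the
            # side's intercept, or an origin coefficient over the non-native
            # species subset) is likelihood-invariant when compensated by the
            # factor effects, so sample that direction exactly from the
            # priors; plain Gibbs alone random-walks these redundancies
            t2f = tau[f.name] ** 2
            for cname, mask in f.alignments.items():
                c_prec = 1.0 / coef_prior_sd[cname] ** 2
                if Ainv is None:
                    pr = c_prec + mask.sum() / t2f
                    mn = (new_u[mask].sum() / t2f - coef[cname] * c_prec) / pr
                else:
                    am = Ainv[:, mask].sum(axis=1)
                    pr = c_prec + float(am[mask].sum()) / t2f
                    mn = (float(am @ new_u) / t2f - coef[cname] * c_prec) / pr
                delta = mn + rng.standard_normal() / math.sqrt(pr)
                coef[cname] += delta
                new_u = np.where(mask, new_u - delta, new_u)
            u[f.name] = new_u

            ss = float(new_u @ new_u) if Ainv is None \
                else float(new_u @ Ainv @ new_u)
            t2 = _inv_gamma(rng, (pri.tau_df + f.q) / 2.0,
                            pri.tau_df / a_aux[f.name] + ss / 2.0)
            tau[f.name] = math.sqrt(max(t2, 1e-12))

            # interweaving (non-centered) move: rescale tau with the
            # standardized effects u/tau held fixed, which mixes tau through
            # the funnel that the centered conjugate update alone cannot
            tv = tau[f.name]
            stepper = nc_steps[f.name]
            stepper.value = tv
            tprop = stepper.propose(rng)
            fac = tprop / tv
            du = (fac - 1.0) * u[f.name]
            dfit = du[f.idx]
            rcur = y - fitted
            dll = -0.5 * float((w * ((rcur - dfit) ** 2 - rcur ** 2)).sum())

            def _tau_cond_logprior(t, a):
                # conditional prior given the PX auxiliary: tau^2 ~ IG(df/2, df/a)
                return (-(pri.tau_df + 2.0) * math.log(t)
                        - pri.tau_df / (a * t * t) + math.log(2.0 * t))
            dlp = _tau_cond_logprior(tprop, a_aux[f.name]) \
                - _tau_cond_logprior(tv, a_aux[f.name]) \
                + math.log(tprop) - math.log(tv)
            acc_nc = math.log(rng.uniform()) < dll + dlp
            if acc_nc:
                tau[f.name] = tprop
                u[f.name] = u[f.name] * fac
                fitted += dfit
            stepper.update(acc_nc, it < spec.warmup, it + 1)

            a_aux[f.name] = _inv_gamma(rng, (pri.tau_df + 1) / 2.0,
                                       pri.tau_df / tau[f.name] ** 2
                                       + 1.0 / pri.tau_scale ** 2)

        # sigma and nu: adaptive MH on the log scale against the MARGINAL
        # Student-t likelihood (scale-mixture weights integrated out), then
        # the weights are redrawn from their conditional — a partially
        # collapsed step that decouples (sigma, nu) from lambda
        resid = y - fitted

        def marginal_loglik(s, v):
            sc = np.sqrt(s ** 2 + se2)
            return float(stats.t.logpdf(resid, df=v, scale=sc).sum())

        def sigma_logpost(s):
            return marginal_loglik(s, nu.value) \
                + _half_t_logpdf(s, pri.sigma_df, pri.sigma_scale) + math.log(s)
        prop = sigma.propose(rng)
        acc = math.log(rng.uniform()) < sigma_logpost(prop) - sigma_logpost(sigma.value)
        if acc:
            sigma.value = prop
        sigma.update(acc, it < spec.warmup, it + 1)

        def nu_logpost(v):
            if v <= pri.nu_min:
                return -np.inf
            return marginal_loglik(sigma.value, v) \
                + stats.gamma.logpdf(v, a=pri.nu_shape, scale=1.0 / pri.nu_rate) \
                + math.log(v)
        prop = nu.propose(rng)
        acc = math.log(rng.uniform()) < nu_logpost(prop) - nu_logpost(nu.value)
        if acc:
            nu.value = prop
        nu.update(acc, it < spec.warmup, it + 1)

        # latent scale-mixture weights given the fresh (sigma, nu)
        s2 = sigma.value ** 2 + se2
        lam = rng.gamma((nu.value + 1.0) / 2.0,
                        2.0 / (nu.value + resid ** 2 / s2))

        j = it - spec.warmup
        if j >= 0:
            for name in coef_names:
                out[name][j] = coef[name]
            out["b0_sum"][j] = coef["b0_study"] + coef["b0_species"]
            for s in design.smooths:
                out_wig[s.name][j] = gwig[s.name]
            for f in factors:
                out[f"tau_{f.name}"][j] = tau[f.name]
                out_u[f.name][j] = u[f.name]
            for name in tau_s:
                out[name][j] = tau_s[name]
            out["sigma"][j] = sigma.value
            out["nu"][j] = nu.value
            if out_mu is not None:
                out_mu[j] = fitted

    accept = {"sigma": sigma.accepted / max(sigma.tried, 1),
              "nu": nu.accepted / max(nu.tried, 1)}
    return out, out_wig, out_u, out_mu, accept


def fit(design: ModelDesign, spec: ModelSpec) -> PosteriorDraws:
    """Sample the posterior by blocked Gibbs; attach convergence diagnostics."""
    if spec.warmup >= spec.iterations:
        raise ValueError("iterations must exceed warmup")
    chain_results = []
    for c in range(spec.chains):
        chain_results.append(_run_chain(design, spec, seed=spec.seed + 1000 * c))

    params: dict[str, np.ndarray] = {}
    scalars = chain_results[0][0].keys()
    for name in scalars:
        params[name] = np.stack([res[0][name] for res in chain_results])
    for s in design.smooths:
        params[f"wiggly_{s.name}"] = np.stack(
            [res[1][s.name] for res in chain_results])
    for f in design.factors:
        params[f"u_{f.name}"] = np.stack([res[2][f.name] for res in chain_results])
    if spec.store_mu:
        params["mu"] = np.stack([res[3] for res in chain_results])

    group_labels = {f.name: f.levels for f in design.factors}
    draws = PosteriorDraws(
        params=params, group_labels=group_labels,
        design_meta={"kind": spec.kind, "n": design.n,
                     "factor_names": [f.name for f in design.factors],
                     "smooth_names": [s.name for s in design.smooths]},
    )
    draws.diagnostics = _diagnostics(draws, chain_results)
    return draws


def _diagnostics(draws: PosteriorDraws, chain_results) -> dict:
    import arviz as az
    rhat: dict[str, float] = {}
    ess: dict[str, float] = {}
    if draws.n_chains >= 2:
        for name in draws.scalar_names():
            arr = az.convert_to_dataset(draws.params[name])
            rhat[name] = float(az.rhat(arr)["x"].values)
            ess[name] = float(az.ess(arr)["x"].values)
    bad = {k: v for k, v in rhat.items() if v > 1.05}
    if bad:
        warnings.warn(f"R-hat above 1.05 for: {sorted(bad)}", stacklevel=2)
    return {"rhat": rhat, "ess": ess,
            "mh_acceptance": [res[4] for res in chain_results],
            "rhat_warnings": sorted(bad)}
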