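"""End-to-end orchestration: raw table + tree in, every analysis table out.

Stages run in the order of the underlying analysis: read and validate the
study table; screen with the Geary check and compute delta-LRR effect sizes;
impute missing doses and categorize; fit the intercept model, then the full
model; test the three hypotheses; decompose variance (intercept model);
compare the models by LOO/WAIC; run the Egger and year-published bias checks;
and evaluate the a-priori power case.  A JSON run report carries every seed,
count and diagnostic needed to re-run the analysis from the report alone.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bias as bias_mod
from . import effects as eff_mod
from . import inference as inf_mod
from . import records as rec_mod
from .impute import add_dose_categories, draws_audit_frame, impute_dose
from .model import ModelSpec, Priors, build_design, fit
from .phylo import read_newick

log = logging.getLogger("allelometa")


@dataclass
class RunConfig:
    input_table: str
    tree_file: str
    out_dir: str
    tsv: bool = False
    seed: int = 1
    chains: int = 4
    iterations: int = 2000
    warmup: int = 1000
    k_smooth: int = 10
    geary_threshold: float = 3.0
    geary_rule: str = "both"            # or "either"
    variance_order: str = "second"      # delta-LRR variance order
    imputations: int = 25
    egger_variant: str = "weighted"     # or "snd"
    decomposition_inflate_residual: bool = False
    run_year_trend: bool = True
    power_k: int = 23
    power_n1: int = 20
    power_n2: int = 20
    power_d: float = 0.288
    power_heterogeneity: str = "high"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def model_spec(self, kind: str) -> ModelSpec:
        return ModelSpec(kind=kind, chains=self.chains,
                         iterations=self.iterations, warmup=self.warmup,
                         seed=self.seed, k_smooth=self.k_smooth,
                         priors=Priors())


def run_all(config: RunConfig) -> dict:
    """Execute the whole pipeline; returns (and writes) the run report."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": asdict(config), "stages": {}}

    def stage(name):
        log.info("stage %s", name)
        report["stages"][name] = {"t_start": round(time.time() - t0, 2)}
        return report["stages"][name]

    s = stage("read")
    result = rec_mod.read_study_table(config.input_table, tsv=config.tsv)
    rec_mod.write_rejects(result.rejects, out / "rejects.csv")
    s.update(rows_in=len(result.records) + len(result.rejects),
             validated=len(result.records), rejected=len(result.rejects))

    s = stage("effects")
    table = eff_mod.effect_table(result.records,
                                 threshold=config.geary_threshold,
                                 rule=config.geary_rule,
                                 variance_order=config.variance_order)
    n_dropped = int((~table["keep"]).sum())
    s.update(geary_dropped=n_dropped, effects=int(table["keep"].sum()))

    s = stage("impute")
    kept = table.loc[table["keep"]].reset_index(drop=True)
    n_missing = int(kept["dose_value"].isna().sum())
    if n_missing:
        imp = impute_dose(kept, m=config.imputations, seed=config.seed)
        completed = add_dose_categories(kept, imp)
        draws_audit_frame(imp).to_csv(out / "dose_imputation_audit.csv",
                                      index=False)
    else:
        from .impute import dose_to_category
        completed = kept.assign(
            dose_imputed=False,
            dose_category=[dose_to_category(v, u) for v, u in
                           zip(kept["dose_value"], kept["dose_unit"].astype(str))])
    completed.to_csv(out / "effect_table.csv", index=False)
    s.update(dose_missing=n_missing,
             pct_dose_imputed=round(100.0 * n_missing / max(len(kept), 1), 1))

    tree = read_newick(config.tree_file)

    s = stage("fit_intercept")
    spec_i = config.model_spec("intercept_only")
    design_i = build_design(completed, tree, spec_i)
    draws_i = fit(design_i, spec_i)
    draws_i.to_long_frame().to_csv(out / "draws_intercept.csv", index=False)
    draws_i.summary().to_csv(out / "summary_intercept.csv", index=False)
    s.update(rhat_warnings=draws_i.diagnostics["rhat_warnings"])

    s = stage("fit_full")
    spec_f = config.model_spec("full")
    design_f = build_design(completed, tree, spec_f)
    draws_f = fit(design_f, spec_f)
    draws_f.to_long_frame().to_csv(out / "draws_full.csv", index=False)
    draws_f.summary().to_csv(out / "summary_full.csv", index=False)
    s.update(rhat_warnings=draws_f.diagnostics["rhat_warnings"])

    s = stage("hypotheses")
    hyp = inf_mod.hypotheses_table(draws_f)
    hyp.to_csv(out / "hypotheses.csv", index=False)
    cells = []
    for g in ("native", "nonnative"):
        for r in ("native", "nonnative"):
            c = inf_mod.predict_cell(draws_f, design_f, g, r)
            cells.append({"grass_origin": g, "recipient_origin": r,
                          "mean": c.mean, "ci_low": c.ci_low,
                          "ci_high": c.ci_high, "p_negative": c.p_negative,
                          "percent_change": eff_mod.percent_change(c.mean)})
    pd.DataFrame(cells).to_csv(out / "cell_predictions.csv", index=False)
    s.update(hypotheses=hyp.to_dict("records"))

    s = stage("variance")
    vd = inf_mod.variance_decomposition(
        draws_i, inflate_residual=config.decomposition_inflate_residual)
    vd.to_frame().to_csv(out / "variance_decomposition.csv", index=False)
    s.update(percent={k: round(100 * v, 1) for k, v in vd.proportions.items()},
             residual_percent=round(100 * vd.residual_proportion, 1))

    s = stage("compare")
    cmp = inf_mod.compare_models(draws_f, design_f, draws_i, design_i)
    cmp.to_csv(out / "model_comparison.csv", index=False)
    s.update(best=str(cmp.iloc[0]["model"]))

    s = stage("bias")
    resid = bias_mod.meta_residuals(draws_i, design_i)
    egger = bias_mod.egger_test(resid, design_i.se_obs,
                                variant=config.egger_variant)
    bias_mod.funnel_table(resid, design_i.se_obs).to_csv(
        out / "funnel.csv", index=False)
    s.update(egger_intercept=egger.intercept,
             egger_intercept_ci=list(egger.intercept_ci),
             bias_flagged=egger.bias_flagged)
    if config.run_year_trend:
        yt = bias_mod.year_trend_fit(completed, tree,
                                     spec=config.model_spec("intercept_only"))
        s.update(year_slope_ci=list(yt["slope_ci"]),
                 year_intercept_ci=list(yt["intercept_ci"]))

    s = stage("power")
    pspec = bias_mod.PowerSpec(k=config.power_k, n1=config.power_n1,
                               n2=config.power_n2, d=config.power_d,
                               heterogeneity=config.power_heterogeneity)
    power = bias_mod.power_meta(pspec)
    bias_mod.power_curve(pspec).to_csv(out / "power_curve.csv", index=False)
    s.update(power=power, power_percent=round(100 * power))

    report["counts_balance"] = {
        "input": report["stages"]["read"]["rows_in"],
        "analyzed": report["stages"]["effects"]["effects"],
        "geary_dropped": report["stages"]["effects"]["geary_dropped"],
        "validation_rejected": report["stages"]["read"]["rejected"],
    }
    cb = report["counts_balance"]
    assert cb["input"] == cb["analyzed"] + cb["geary_dropped"] + cb["validation_rejected"]
    report["elapsed_s"] = round(time.time() - t0, 2)
    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default)
    return report


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return str(obj)
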