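"""End-to-end driver: simulate, fit, correlate, predict, score.

Stages (all intermediates persisted as CSV, parameters and seed recorded in
a JSON manifest):

1. per-group pH-solubility points are generated from the preset fits and
   re-fitted;
2. the three-cup transfer simulation produces aqueous/organic curves and
   supersaturation metrics;
3. the combined organic-phase absorbed fraction is fitted with the double
   Weibull model;
4. ground-truth in vivo absorbed fractions are built from the correlation
   parameters and each group's Weibull curve, plasma profiles are generated
   by convolution with the disposition kernel (plus optional noise);
5. the i.v. kernel is fitted, oral curves are deconvolved, and the
   correlation is fitted on the training groups;
6. plasma is predicted for every group (external groups included) and the
   prediction-error report is scored against the qualification limits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .. import __version__
from ..dgim_transfer import DGIMConfig
from ..dissolution_models import fit_dissolution
from ..errors import MulticupError
from ..ivivc import (
    IVIVCParams,
    UIRParams,
    convolve_predict_plasma,
    deconvolve,
    fit_correlation,
    fit_uir,
    pe_report,
    predict_fabs,
    validate_ivivc,
)
from ..pk_nca import auc_linear_trapezoid, cmax_tmax
from ..solubility import SolubilityPoint, eval_solubility, fit_ph_solubility
from ..supersaturation import ds_metrics, ds_profile
from ..synthetic_data import (
    DEFAULT_SOLUBILITY_FITS,
    PKDispositionParams,
    add_noise,
    default_kinetics,
    default_scenario,
    simulate_dgim,
    simulate_usp2_ph_shift,
)
from ..timeseries import TimeSeries
from .io import write_manifest, write_timeseries, write_timeseries_bundle

DEFAULT_INVIVO_TIMES = (0.083, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 10.0)


@dataclass(frozen=True)
class PipelineConfig:
    groups: Tuple[str, ...] = ("control", "PVPVA", "HPMC")
    training_groups: Tuple[str, ...] = ("control", "PVPVA")
    external_groups: Tuple[str, ...] = ("HPMC",)
    apparatus: str = "dgim"                      # "dgim" or "usp2"
    noise_sigma: float = 0.0
    # correlation ground truth used by the generator
    abs_scale_true: float = 0.9757
    t_scale_true: float = 1.629
    t_shift_true: float = 4.397e-5               # hours
    invivo_times: Tuple[float, ...] = DEFAULT_INVIVO_TIMES
    invitro_step_min: float = 1.0
    solubility_pH_grid: Tuple[float, ...] = (2.0, 3.0, 4.0, 4.7, 5.0, 6.0, 6.5)
    dose_oral: float = 10.0                      # mg/kg
    dose_iv: float = 2.5                         # mg/kg
    kernel_terms: Tuple[Tuple[float, float], ...] = ((6500.0, 1.1), (2800.0, 0.28))
    weibull_starts: int = 10

    def __post_init__(self):
        if self.apparatus not in ("dgim", "usp2"):
            raise MulticupError(f"unknown apparatus {self.apparatus!r}")
        unknown = set(self.training_groups + self.external_groups) - set(self.groups)
        if unknown:
            raise MulticupError(f"groups {sorted(unknown)} not in {self.groups}")


class PipelineStageError(MulticupError):
    def __init__(self, stage, cause):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _invitro_absorbed_fraction(cfg: PipelineConfig, dgim_cfg, group, seed):
    grid = np.arange(0.0, dgim_cfg.duration + 1e-9, cfg.invitro_step_min)
    scenario = default_scenario(group)
    kin = default_kinetics(group)
    if cfg.apparatus == "dgim":
        sim = simulate_dgim(dgim_cfg, scenario, kin, grid)
    else:
        sim = simulate_usp2_ph_shift(scenario, kin, grid)
    frac = sim.absorbed_fraction
    if cfg.noise_sigma > 0:
        noisy = add_noise(frac, cfg.noise_sigma, seed=seed)
        # noise must not break the fraction-model preconditions
        frac = noisy.with_values(np.clip(np.maximum.accumulate(noisy.value), 0.0, 1.05))
    return sim, frac


def run_pipeline(
    config: PipelineConfig,
    outdir,
    seed: int = 0,
) -> dict:
    """Run the full chain; returns a results dict and persists artifacts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    stage_seeds = {name: int(rng.integers(2 ** 31)) for name in
                   ("invitro", "plasma", "solubility")}
    dgim_cfg = DGIMConfig()
    manifest: Dict[str, object] = {
        "seed": seed,
        "stage_seeds": stage_seeds,
        "version": __version__,
        "config": vars(config) if not hasattr(config, "__dataclass_fields__")
        else {k: getattr(config, k) for k in config.__dataclass_fields__},
        "stages": {},
    }
    results: Dict[str, object] = {"config": config, "seed": seed}

    def record(stage, **paths):
        manifest["stages"][stage] = {k: str(v) for k, v in paths.items()}

    # -- stage 1: solubility fits ------------------------------------------
    stage = "solubility"
    try:
        sol_fits, sol_rss = {}, {}
        for group in config.groups:
            truth = DEFAULT_SOLUBILITY_FITS[group]
            pts = [SolubilityPoint(ph, eval_solubility(truth, ph))
                   for ph in config.solubility_pH_grid]
            fit, diag = fit_ph_solubility(pts)
            sol_fits[group] = fit
            sol_rss[group] = diag.rss
        results["solubility_fits"] = sol_fits
        path = outdir / "solubility_fits.csv"
        with open(path, "w") as fh:
            fh.write("group,C_U_ug_per_ml,pKa,rss\n")
            for group, fit in sol_fits.items():
                fh.write(f"{group},{fit.C_U:.10g},{fit.pKa:.10g},"
                         f"{sol_rss[group]:.6g}\n")
        record(stage, fits=path)
    except MulticupError as exc:
        write_manifest(outdir / "manifest.json", **manifest)
        raise PipelineStageError(stage, exc) from exc

    # -- stage 2+3: in vitro simulation and Weibull fits -------------------
    stage = "invitro"
    try:
        sims, fracs, weibulls = {}, {}, {}
        ds_rows = []
        for i, group in enumerate(config.groups):
            sim, frac = _invitro_absorbed_fraction(
                config, dgim_cfg, group, stage_seeds["invitro"] + i)
            sims[group] = sim
            fracs[group] = frac
            report = fit_dissolution(frac, "weibull2",
                                     n_starts=config.weibull_starts, seed=seed)
            weibulls[group] = report
            write_timeseries(frac, outdir / f"invitro_fraction_{group}.csv")
            if config.apparatus == "dgim":
                bundle = {
                    "duodenal_aq": sim.duodenal_aq,
                    "jejunal_aq": sim.jejunal_aq,
                    "duodenal_org": sim.duodenal_org,
                    "jejunal_org": sim.jejunal_org,
                    "pH_d": sim.pH_d,
                    "pH_j": sim.pH_j,
                }
                write_timeseries_bundle(bundle, outdir / f"dgim_curves_{group}.csv")
                for cup, conc, ph in (("duodenal", sim.duodenal_aq, sim.pH_d),
                                      ("jejunal", sim.jejunal_aq, sim.pH_j)):
                    ds = ds_profile(conc, ph, results["solubility_fits"][group])
                    m = ds_metrics(ds)
                    ds_rows.append((group, cup, m.DS_max, m.DS_auc, m.t_at_DSmax))
        if ds_rows:
            path = outdir / "ds_metrics.csv"
            with open(path, "w") as fh:
                fh.write("group,cup,DS_max,DS_auc_h,t_at_DSmax_min\n")
                for row in ds_rows:
                    fh.write(",".join(str(x) for x in row) + "\n")
        results["invitro"] = sims
        results["weibull_fits"] = weibulls
        record(stage, outdir=outdir)
    except MulticupError as exc:
        write_manifest(outdir / "manifest.json", **manifest)
        raise PipelineStageError(stage, exc) from exc

    # -- stage 4: ground-truth in vivo plasma ------------------------------
    stage = "plasma"
    try:
        truth = IVIVCParams(config.abs_scale_true, config.t_scale_true,
                            config.t_shift_true)
        t_obs = np.asarray(config.invivo_times, dtype=float)
        pk = PKDispositionParams(terms=config.kernel_terms,
                                 dose_oral=config.dose_oral,
                                 dose_iv=config.dose_iv, F_true=1.0)
        oral_obs = {}
        from ..synthetic_data import simulate_plasma
        for i, group in enumerate(config.groups):
            diss_h = weibulls[group].params.with_time_scale(1.0 / 60.0)
            fabs_true = predict_fabs(truth, diss_h,
                                     np.arange(0.0, t_obs[-1] + 1e-9, 0.05))
            plasma = simulate_plasma(fabs_true, pk, "oral", t_eval=t_obs)
            if config.noise_sigma > 0:
                plasma = add_noise(plasma, config.noise_sigma,
                                   seed=stage_seeds["plasma"] + i)
            oral_obs[group] = plasma
            write_timeseries(plasma, outdir / f"plasma_oral_{group}.csv")
        iv_plasma = simulate_plasma(None, pk, "iv", t_eval=t_obs)
        if config.noise_sigma > 0:
            iv_plasma = add_noise(iv_plasma, config.noise_sigma,
                                  seed=stage_seeds["plasma"] + 1000)
        write_timeseries(iv_plasma, outdir / "plasma_iv.csv")
        results["oral_plasma"] = oral_obs
        results["iv_plasma"] = iv_plasma
        record(stage, outdir=outdir)
    except MulticupError as exc:
        write_manifest(outdir / "manifest.json", **manifest)
        raise PipelineStageError(stage, exc) from exc

    # -- stage 5: UIR, deconvolution, correlation --------------------------
    stage = "ivivc"
    try:
        uir, uir_diag = fit_uir(iv_plasma, config.dose_iv, seed=seed)
        fabs_obs = {g: deconvolve(oral_obs[g], uir, config.dose_oral)
                    for g in config.groups}
        for g, f in fabs_obs.items():
            write_timeseries(f, outdir / f"fabs_deconvolved_{g}.csv")
        corr, corr_diag = fit_correlation(
            [fabs_obs[g] for g in config.training_groups],
            [weibulls[g].params.with_time_scale(1.0 / 60.0)
             for g in config.training_groups],
        )
        results["uir"] = uir
        results["correlation"] = corr
        results["correlation_diag"] = corr_diag
        record(stage, outdir=outdir)
    except MulticupError as exc:
        write_manifest(outdir / "manifest.json", **manifest)
        raise PipelineStageError(stage, exc) from exc

    # -- stage 6: prediction and PE report ---------------------------------
    stage = "prediction"
    try:
        observed, predicted = {}, {}
        pred_grid = np.arange(0.0, t_obs[-1] + 1e-9, 0.05)
        for group in config.groups:
            diss_h = weibulls[group].params.with_time_scale(1.0 / 60.0)
            fabs_pred = predict_fabs(corr, diss_h, pred_grid)
            plasma_pred = convolve_predict_plasma(
                fabs_pred, uir, config.dose_oral, F_ref=1.0, t_eval=t_obs)
            write_timeseries(plasma_pred, outdir / f"plasma_predicted_{group}.csv")
            obs = oral_obs[group]
            observed[group] = (cmax_tmax(obs)[0], auc_linear_trapezoid(obs))
            predicted[group] = (cmax_tmax(plasma_pred)[0],
                                auc_linear_trapezoid(plasma_pred))
        report = pe_report(observed, predicted,
                           external_groups=config.external_groups)
        flags = validate_ivivc(report)
        results["pe_report"] = report
        results["validation"] = flags
        path = outdir / "pe_report.csv"
        with open(path, "w") as fh:
            fh.write("metric,group,observed,predicted,pe_percent,external\n")
            for r in report.groups:
                fh.write(f"Cmax,{r.group},{r.observed_cmax:.6g},"
                         f"{r.predicted_cmax:.6g},{r.pe_cmax:.4f},{r.external}\n")
            for r in report.groups:
                fh.write(f"AUC,{r.group},{r.observed_auc:.6g},"
                         f"{r.predicted_auc:.6g},{r.pe_auc:.4f},{r.external}\n")
            fh.write(f"Cmax,mean_abs,,,{report.mean_abs_pe_cmax:.4f},\n")
            fh.write(f"AUC,mean_abs,,,{report.mean_abs_pe_auc:.4f},\n")
        record(stage, report=path)
    except MulticupError as exc:
        write_manifest(outdir / "manifest.json", **manifest)
        raise PipelineStageError(stage, exc) from exc

    write_manifest(outdir / "manifest.json", **manifest)
    return results
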