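"""End-to-end two-stage pipeline orchestration.

prep → cross-validated model selection → final exposure fit → subject
prediction → naive health fit → parameter bootstrap at λ = 0 and λ = 1
(optionally SIMEX) → tables written to the output directory with a
provenance log.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .correction import (BootstrapConfig, BootstrapInputs, parameter_bootstrap,
                         simex_bias)
from .evaluation import cross_validate, cv_table, select_model
from .exposure import ExposureModel, monitor_design, subject_design
from .health import fit_health_ols
from .io import RunConfig, read_covariates, read_monitors, read_subjects, \
    write_table
from .pls import project_scores

logger = logging.getLogger(__name__)


def _stage_seeds(root: int) -> dict:
    ss = np.random.SeedSequence(root)
    names = ("cv", "bootstrap", "simex")
    return {name: int(child.generate_state(1)[0] % (2 ** 31))
            for name, child in zip(names, ss.spawn(len(names)))}


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the full two-stage analysis; returns the artifact directory."""
    cfg.validate()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter(
        "%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root_logger = logging.getLogger("plskrige")
    root_logger.addHandler(handler)
    root_logger.setLevel(logging.INFO)
    seeds = _stage_seeds(cfg.seed)
    try:
        logger.info("plskrige %s; config hash %s", __version__,
                    cfg.config_hash())
        logger.info("config: %s", json.dumps(cfg.to_dict(), sort_keys=True))
        logger.info("stage seeds: %s", seeds)

        stage = "load"
        monitors = read_monitors(cfg.monitors_csv)
        covariates = read_covariates(cfg.covariates_csv)
        subjects = read_subjects(cfg.subjects_csv)
        cov_mon = covariates.loc[monitors.ids].reset_index(drop=True)
        cov_sub = covariates.loc[subjects["id"]].reset_index(drop=True)
        z_cols = [c for c in subjects.columns if str(c).startswith("z_")]
        logger.info("loaded %d monitors, %d subjects, %d covariates",
                    len(monitors), len(subjects), covariates.shape[1])

        stage = "cross_validate"
        t0 = time.time()
        from .preprocess import CovariatePreprocessor
        prep_proto = CovariatePreprocessor(distance_cap=cfg.distance_cap,
                                           log_base=cfg.log_base)
        results = cross_validate(monitors, cov_mon, methods=cfg.cv_methods,
                                 k_grid=cfg.k_grid, n_folds=cfg.n_folds,
                                 seed=seeds["cv"], family=cfg.family,
                                 preprocessor=prep_proto)
        table = cv_table(results)
        table["config_hash"] = cfg.config_hash()
        write_table(table, outdir / "cv_results.csv")
        method, k = select_model(results)
        logger.info("CV done in %.1fs; selected method=%s k=%d",
                    time.time() - t0, method, k)
        held = pd.DataFrame({
            "id": monitors.ids,
            "fold": results[0].fold_assignment,
            **{f"{r.method}_k{r.k}": r.cv_predictions for r in results},
        })
        write_table(held, outdir / "cv_predictions.csv")

        stage = "fit_exposure"
        model = ExposureModel(n_components=max(k, 1), family=cfg.family,
                              method=method, preprocessor=prep_proto,
                              compute_param_cov=True)
        model.fit(monitor_design(monitors, cov_mon), monitors.conc_sqrt)

        stage = "predict_subjects"
        X_sub = subject_design(subjects[["x", "y"]].to_numpy(), cov_sub)
        preds = model.predict_full(X_sub, ids=subjects["id"].to_numpy())
        pred_frame = preds.to_frame()
        pred_frame["config_hash"] = cfg.config_hash()
        write_table(pred_frame, outdir / "exposure_predictions.csv")

        stage = "fit_health"
        Z = subjects[z_cols]
        hf = fit_health_ols(subjects["y_outcome"].to_numpy(),
                            preds.pred_raw, Z)
        coef = hf.coefficient_table("naive")

        stage = "bootstrap"
        if method == "pls_uk":
            covs_std_sub = model.prep_.transform(cov_sub)
            inputs = BootstrapInputs(
                kriging_fit=model.kriging_,
                health_fit=hf,
                coords_monitors=monitors.coords,
                scores_monitors=model.scores_,
                coords_subjects=subjects[["x", "y"]].to_numpy(dtype=float),
                scores_subjects=project_scores(model.pls_, covs_std_sub),
                Z=Z.to_numpy(dtype=float),
            )
            rows = [coef]
            for lam, tag in ((0.0, "pb_lambda0"),
                             (cfg.bootstrap_lambda, "pb_lambda1")):
                bcfg = BootstrapConfig(B=cfg.bootstrap_B, lam=lam,
                                       seed=seeds["bootstrap"])
                res = parameter_bootstrap(bcfg, inputs)
                from .health import normal_ci
                lo, hi = normal_ci(res.beta_corrected, res.se_boot)
                rows.append(pd.DataFrame([{
                    "term": "exposure", "estimate": res.beta_corrected,
                    "se": res.se_boot, "ci_lo": lo, "ci_hi": hi,
                    "method": tag}]))
                logger.info("bootstrap λ=%g: se=%.4g bias=%.4g dropped=%d",
                            lam, res.se_boot, res.bias, res.n_dropped)
            coef = pd.concat(rows, ignore_index=True)
            if cfg.run_simex:
                scfg = BootstrapConfig(B=cfg.bootstrap_B, lam=1.0,
                                       seed=seeds["simex"],
                                       lambda_grid=cfg.lambda_grid)
                sx = simex_bias(scfg, inputs)
                from .health import normal_ci
                coef = pd.concat([coef, pd.DataFrame([{
                    "term": "exposure", "estimate": sx.beta_corrected,
                    "se": np.nan, "ci_lo": np.nan, "ci_hi": np.nan,
                    "method": "simex"}])], ignore_index=True)
        else:
            logger.info("selected method %s has no bootstrap correction", method)

        coef["config_hash"] = cfg.config_hash()
        write_table(coef, outdir / "health_results.csv")
        logger.info("pipeline complete")
    except Exception as exc:
        logger.exception("pipeline aborted in stage %r", stage)
        raise RuntimeError(f"pipeline failed in stage {stage!r}") from exc
    finally:
        root_logger.removeHandler(handler)
        handler.close()
    return outdir
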