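"""One-command end-to-end pipeline: simulate/load -> split -> cohort ->
index baselines -> per-family tuning -> stacking -> evaluation -> diagnostics.

The pipeline is configured by a plain dict (typically parsed from YAML),
validated up front, and writes a run directory containing train/test
CSVs, an index-baseline table, a per-family single-model table, the
stack weight report, the importance and residual profiles, and a
``metrics.json`` that is byte-identical across reruns of the same
config (all randomness is explicitly seeded; timestamps go to the log
only).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import index_bench, interpret, stack_engine, synthetic_leaf
from .learner_zoo import (CVSpec, FAMILIES, PrepConfig, finalize_and_evaluate,
                          select_one_se, tune)
from .spectra_core import (Dataset, cohort_stats, load_dataset, split_dataset,
                           write_dataset)

__all__ = ["default_config", "validate_config", "run_pipeline"]

logger = logging.getLogger("specstack")


def default_config() -> dict:
    """Reference defaults: 10x3 CV, top-20 stacking, lambda=1e-6, SG off."""
    return {
        "data": {"simulate": {"n": 482, "seed": 0, "mode": "linear",
                              "oracle_r2": 0.9}},
        "split": {"frac": 0.8, "seed": 2025},
        "preprocess": {"sg_window": 0, "variance_target": 0.99},
        "families": {f: 60 for f in FAMILIES},
        "cv": {"folds": 10, "repeats": 3, "seed": 0},
        "stack": {"top_m": 20, "lambda": 1e-6},
        "explain": {"band_nm": 10, "repeats": 10, "seed": 3, "span": 0.75},
    }


def validate_config(config: dict) -> dict:
    """Merge over defaults and fail fast on invalid settings."""
    cfg = default_config()
    for section, values in (config or {}).items():
        if section not in cfg:
            raise ValueError(f"unknown config section {section!r}")
        if section == "data":
            cfg["data"] = values
        elif section == "families":
            cfg["families"] = dict(values)
        else:
            cfg[section].update(values)
    if "input_csv" not in cfg["data"] and "simulate" not in cfg["data"]:
        raise ValueError("data section needs 'input_csv' or 'simulate'")
    if not 0 < cfg["split"]["frac"] < 1:
        raise ValueError("split.frac must be in (0, 1)")
    if cfg["cv"]["folds"] < 2:
        raise ValueError("cv.folds must be >= 2")
    if cfg["cv"]["repeats"] < 1:
        raise ValueError("cv.repeats must be >= 1")
    if cfg["preprocess"]["sg_window"] not in (0, 7, 9, 11, 13):
        raise ValueError("preprocess.sg_window must be 0 (off) or one of 7/9/11/13")
    for fam, budget in cfg["families"].items():
        if fam not in FAMILIES:
            raise ValueError(f"unknown family {fam!r}; known: {FAMILIES}")
        if budget < 1:
            raise ValueError(f"family {fam}: budget must be >= 1")
    if cfg["stack"]["top_m"] < 1:
        raise ValueError("stack.top_m must be >= 1")
    if cfg["stack"]["lambda"] < 0:
        raise ValueError("stack.lambda must be >= 0")
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=float).encode()).hexdigest()[:16]


def _load_or_simulate(data_cfg: dict) -> Dataset:
    if "input_csv" in data_cfg:
        return load_dataset(data_cfg["input_csv"])
    sim = dict(data_cfg["simulate"])
    oracle_r2 = sim.pop("oracle_r2", None)
    cfg = synthetic_leaf.SyntheticConfig(**sim)
    if oracle_r2 is not None:
        cfg = synthetic_leaf.SyntheticConfig(
            **{**sim, "trait_noise_sd": synthetic_leaf.noise_for_oracle_r2(oracle_r2, cfg)})
    ds, _ = synthetic_leaf.generate_dataset(cfg)
    return ds


def run_pipeline(config: dict, out_dir) -> dict:
    """Execute the full pipeline; returns the metrics dict it also writes."""
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    chash = _config_hash(cfg)
    metrics: dict = {"config_hash": chash, "config": cfg}
    t0 = time.perf_counter()
    try:
        logger.info("run start (config hash %s)", chash)
        ds = _load_or_simulate(cfg["data"])
        train, test = split_dataset(ds, cfg["split"]["frac"], cfg["split"]["seed"])
        write_dataset(train, out / "train.csv")
        write_dataset(test, out / "test.csv")
        metrics["n_train"], metrics["n_test"] = train.n, test.n
        logger.info("split: %d train / %d test", train.n, test.n)

        s_tr, s_te = cohort_stats(train.traits, test.traits)
        pd.DataFrame([{"subset": "train", **s_tr.to_dict()},
                      {"subset": "test", **s_te.to_dict()}]).to_csv(
            out / "cohort.csv", index=False, float_format="%.6g")
        metrics["cohort"] = {"train": s_tr.to_dict(), "test": s_te.to_dict()}
        logger.info("cohort comparability: location p=%.3f", s_tr.location_p)

        rows = []
        for name in index_bench.INDEX_REGISTRY:
            try:
                res = index_bench.single_index_baseline(train, test, name)
                rows.append({"Index": name, "RMSE": res.rmse, "R2": res.r2})
            except ValueError as e:
                logger.warning("index %s skipped: %s", name, e)
        table5 = pd.DataFrame(rows).sort_values("RMSE", kind="stable").reset_index(drop=True)
        table5.to_csv(out / "table5.csv", index=False, float_format="%.6g")
        enet = index_bench.enet_on_indices(train, test, seed=cfg["cv"]["seed"])
        metrics["index_baselines"] = {
            "best_single": table5.iloc[0].to_dict(),
            "enet": {"rmse": enet.test_rmse, "r2": enet.test_r2,
                     "retained": enet.retained, "equation": enet.equation()},
        }
        logger.info("index baselines: best single R2=%.3f, enet R2=%.3f",
                    table5.iloc[0]["R2"], enet.test_r2)

        prep = PrepConfig(sg_window=cfg["preprocess"]["sg_window"],
                          variance_target=cfg["preprocess"]["variance_target"])
        cv = CVSpec(**cfg["cv"])
        results, table6_rows = {}, []
        for fam, budget in cfg["families"].items():
            t = time.perf_counter()
            cands = tune(fam, train, prep=prep, cv=cv, budget=budget)
            logger.info("tuned %s: %d candidates in %.1fs", fam, len(cands),
                        time.perf_counter() - t)
            if not cands:
                continue
            results[fam] = cands
            best = select_one_se(cands)
            mp = finalize_and_evaluate(best, train, test, prep)
            table6_rows.append({"Model": fam, "RMSE": mp.rmse, "R2": mp.r2,
                                **{f"param_{k}": v for k, v in best.params.items()}})
        table6 = pd.DataFrame(table6_rows).sort_values("RMSE", kind="stable").reset_index(drop=True)
        table6.to_csv(out / "table6.csv", index=False, float_format="%.6g")
        metrics["single_models"] = {
            r["Model"]: {"rmse": r["RMSE"], "r2": r["R2"]} for r in table6_rows}

        library = stack_engine.build_candidate_library(results, cfg["stack"]["top_m"])
        oof = stack_engine.assemble_oof(library, cv, train.spectra.sample_ids)
        w, b = stack_engine.blend(oof, train.y, lam=cfg["stack"]["lambda"])
        stack = stack_engine.finalize_stack(w, b, library, train, prep,
                                            penalty=cfg["stack"]["lambda"])
        report = stack_engine.report_weights(stack)
        report.members.to_csv(out / "weights.csv", index=False, float_format="%.6g")
        report.family_totals.to_csv(out / "family_weights.csv", index=False,
                                    float_format="%.6g")
        mp_tr = stack_engine.rmse_r2(train.y, stack_engine.predict_stack(stack, train.X))
        mp_te = stack_engine.evaluate_stack(stack, test)
        metrics["stack"] = {
            "train": asdict(mp_tr), "test": asdict(mp_te),
            "n_members": len(stack.members),
            "intercept": stack.intercept,
            "weights": {m.candidate_id: float(wc)
                        for m, wc in zip(stack.members, stack.weights)},
        }
        logger.info("stack: %d members, test R2=%.3f RMSE=%.3f",
                    len(stack.members), mp_te.r2, mp_te.rmse)

        ex = cfg["explain"]
        prof = interpret.band_permutation_importance(
            stack, test, band_nm=ex["band_nm"], repeats=ex["repeats"],
            seed=ex["seed"])
        pd.DataFrame({
            "band_start_nm": prof.band_start_nm, "band_end_nm": prof.band_end_nm,
            "delta_rmse_mean": prof.delta_rmse_mean,
            "delta_rmse_sd": prof.delta_rmse_sd,
        }).to_csv(out / "importance.csv", index=False, float_format="%.6g")
        center, dmax = prof.top_band()
        metrics["importance"] = {"top_band_center_nm": center,
                                 "top_band_delta_rmse": dmax,
                                 "baseline_rmse": prof.baseline_rmse}
        resid = interpret.residual_diagnostics(stack, test, span=ex["span"])
        pd.DataFrame({"predicted": resid.predicted,
                      "residual": resid.residuals}).to_csv(
            out / "residuals.csv", index=False, float_format="%.6g")
        pd.DataFrame({"x": resid.smoother_x, "smoothed": resid.smoother_y}).to_csv(
            out / "residual_smoother.csv", index=False, float_format="%.6g")
        logger.info("explain: top band %.0f nm (dRMSE %.4f)", center, dmax)

        metrics_clean = json.loads(json.dumps(metrics, sort_keys=True, default=float))
        (out / "metrics.json").write_text(
            json.dumps(metrics_clean, sort_keys=True, indent=2) + "\n")
        logger.info("run complete in %.1fs", time.perf_counter() - t0)
        return metrics_clean
    except Exception:
        logger.exception("pipeline failed; partial outputs retained in %s", out)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
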