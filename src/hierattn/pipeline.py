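"""End-to-end pipeline: simulate -> tensorize -> train -> evaluate ->
baselines -> explain, each stage writing versioned outputs and a manifest
carrying the config, its hash, and the derived stage seeds."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import baselines as bl
from . import evaluation, io
from .attention_maps import patient_map, render_map
from .config import RunConfig, stage_seed
from .model import HierarchicalAttentionClassifier
from .nn import ModelConfig
from .schema import build_default_schema
from .synthetic import PlantedEffect, SyntheticConfig, generate_cohort, planted_signal_report
from .tensorize import EligibilityConfig, tensorize_cohort
from .training import TrainingConfig, make_splits

logger = logging.getLogger(__name__)


def _risk_spec(cfg: RunConfig):
    if cfg.synthetic.risk_spec is None:
        return None
    return [PlantedEffect(**d) for d in cfg.synthetic.risk_spec]


def synthetic_config(cfg: RunConfig) -> SyntheticConfig:
    kwargs = dict(
        n_patients=cfg.synthetic.n_patients,
        seed=stage_seed(cfg.seed, "simulate"),
        visit_rate_range=cfg.synthetic.visit_rate_range,
        outcome_base_rates=cfg.synthetic.outcome_base_rates,
        prediction_window=cfg.window,
        in_migrant_fraction=cfg.synthetic.in_migrant_fraction,
        exit_hazard=cfg.synthetic.exit_hazard,
        planted_event_rate=cfg.synthetic.planted_event_rate,
    )
    spec = _risk_spec(cfg)
    if spec is not None:
        kwargs["risk_spec"] = spec
    return SyntheticConfig(**kwargs)


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> dict:
    """Run every stage; returns the manifest dict (also written to disk)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_text = json.dumps(cfg.model_dump(mode="json"), sort_keys=True)
    manifest = {
        "config": cfg.model_dump(mode="json"),
        "config_hash": hashlib.sha256(cfg_text.encode()).hexdigest()[:16],
        "stage_seeds": {s: stage_seed(cfg.seed, s) for s in
                        ("simulate", "train", "evaluate", "baselines")},
        "stages": {},
    }
    schema = build_default_schema()

    def run_stage(name, fn):
        t0 = time.time()
        try:
            data, info = fn()
        except Exception as err:
            manifest["stages"][name] = {"status": "failed", "error": str(err)}
            (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
            raise RuntimeError(
                f"stage {name!r} failed ({err}); replay with: "
                f"hierattn {name} --config <config.yaml> --out-dir {out}"
            ) from err
        manifest["stages"][name] = {
            "status": "ok", "seconds": round(time.time() - t0, 2), **(info or {})}
        logger.info("stage %s done in %.1fs", name, time.time() - t0)
        return data

    # ------------------------------------------------------------ simulate
    def do_simulate():
        syn_cfg = synthetic_config(cfg)
        events, statics, truth = generate_cohort(syn_cfg, schema)
        io.write_events(events, out / "events.csv")
        io.write_statics(statics, out / "statics.csv")
        return (events, statics, truth), {"n_events": len(events),
                                          "n_patients": len(statics)}

    events, statics, truth = run_stage("simulate", do_simulate)

    # ----------------------------------------------------------- tensorize
    def do_tensorize():
        elig = EligibilityConfig(prediction_window=cfg.window)
        tensor, labels, report = tensorize_cohort(events, statics, schema, elig)
        tensor.save(out / "tensor")
        labels.to_csv(out / "labels.csv", index=False)
        return (tensor, labels), {"n_final": report["n_final"],
                                  "t_max": tensor.t_max,
                                  "exclusions": report["exclusions"]}

    tensor, labels = run_stage("tensorize", do_tensorize)

    # --------------------------------------------------------------- train
    def do_train():
        y = labels[cfg.outcome].values
        model_cfg = ModelConfig(
            rnn_type=cfg.model.rnn_type, units=cfg.model.units,
            dense_before_output=cfg.model.dense_before_output,
            n_variables=tensor.n_variables, n_static=tensor.S.shape[1],
            t_max=tensor.t_max, embed_dim=cfg.model.embed_dim,
            attn_dim=cfg.model.attn_dim, seed=stage_seed(cfg.seed, "train"))
        clf = HierarchicalAttentionClassifier(tensor, y, outcome=cfg.outcome,
                                              config=model_cfg, schema=schema)
        train_cfg = TrainingConfig(
            learning_rate=cfg.training.learning_rate,
            batch_size=cfg.training.batch_size,
            max_epochs=cfg.training.max_epochs,
            patience=cfg.training.patience,
            grid_max_epochs=cfg.training.grid_max_epochs,
            seed=stage_seed(cfg.seed, "train"))
        plan = make_splits(tensor.patient_ids, stage_seed(cfg.seed, "train"))
        results = clf.fit(split=plan, training=train_cfg, grid=cfg.grid)
        results.net.save(out / "model_params")
        plan.to_json(out / "splits.json")
        if results.grid_result is not None:
            (out / "grid_result.json").write_text(
                json.dumps(results.grid_result.to_dict(), indent=1))
        info = {"epochs": len(results.history),
                "config": {"rnn_type": results.net.config.rnn_type,
                           "units": results.net.config.units,
                           "dense": results.net.config.dense_before_output}}
        return results, info

    results = run_stage("train", do_train)

    # ------------------------------------------------------------ evaluate
    def do_evaluate():
        rep = results.evaluate(threshold=cfg.evaluation.threshold,
                               n_bootstrap=cfg.evaluation.n_bootstrap,
                               seed=stage_seed(cfg.seed, "evaluate"))
        rep.to_json(out / "metrics.json")
        cal = results.calibration()
        cal.to_csv(out / "calibration.csv", index=False)
        evaluation.calibration_plot(cal, out / "calibration.png",
                                    title=f"{cfg.outcome}, {cfg.window}-year")
        (out / "summary.txt").write_text(results.summary())
        return rep, {"roc_auc": rep.metrics["roc_auc"].point}

    run_stage("evaluate", do_evaluate)

    # ------------------------------------------------------------ baselines
    def do_baselines():
        table = bl.build_cross_section(tensor, statics)
        y = pd.Series(labels[cfg.outcome].values,
                      index=labels["patient_id"].values)
        all_reports = bl.fit_all_baselines(
            table, y.loc[table["patient_id"].values].values, results.split,
            schema, seed=stage_seed(cfg.seed, "baselines"),
            threshold=cfg.evaluation.threshold,
            n_bootstrap=cfg.evaluation.n_bootstrap)
        blob = {name: {"report": d["report"].to_dict(), "run_log": d["run_log"]}
                for name, d in all_reports.items()}
        (out / "baseline_metrics.json").write_text(json.dumps(blob, indent=1))
        info = {name: d["report"].metrics["roc_auc"].point
                for name, d in all_reports.items()}
        return all_reports, info

    run_stage("baselines", do_baselines)

    # -------------------------------------------------------------- explain
    def do_explain():
        pop = results.population_attention()
        render_map(pop, out / "population_attention",
                   title=f"Population attention — {cfg.outcome}")
        recovery = planted_signal_report(truth, pop.variable_scores)
        (out / "signal_recovery.json").write_text(json.dumps(recovery, indent=1))
        test_out = results.predict_test()
        rows = results.normalized_tensor.rows_for(results.split.test_ids)
        t = results.normalized_tensor
        pm = patient_map(test_out.alpha[0], test_out.beta[0],
                         t.value_mask[rows[0]], t.period_mask[rows[0]],
                         t.variable_index)
        render_map(pm, out / "patient_attention_example",
                   title="Patient attention (example)")
        return (pop, recovery), {"recovery_fraction": recovery["recovery_fraction"],
                                 "top_variables": pop.top_variables}

    run_stage("explain", do_explain)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
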