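"""End-to-end estimation pipeline.

Phase 1 fits the amortized encoder–decoder to the cohort (dynamics
modeling); phase 2 computes each subject's Pearson functional-connectivity
matrix and uses it to refine the learned directed graphs, which are then
thresholded into binary networks and, when ground truth is available,
scored.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path

import numpy as np
import yaml

from .data import CohortTimeSeries
from .fc import guide_ec, pearson_fc
from .io import (
    RunConfig,
    load_cohort,
    save_adjacency_csv,
    save_checkpoint,
    save_cohort_csv_dir,
    save_edge_list,
)
from .metrics import evaluate_cohort
from .model import ECGraph
from .simulate import GroundTruthGraph, make_stable_graph, simulate_cohort
from .training import adapt_subject, binarize, train_amortized

__all__ = ["PipelineError", "run_pipeline"]

log = logging.getLogger("effconn")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as err:
                raise PipelineError(f"stage '{name}': {err}") from err

        return wrapped

    return deco


@_stage("data")
def _get_cohort(cfg: RunConfig):
    if cfg.data_path is not None:
        log.info("loading cohort from %s", cfg.data_path)
        return load_cohort(cfg.data_path, normalize=cfg.normalize)
    spec = cfg.simulate
    log.info(
        "simulating cohort: %d subjects, %d nodes, %d arcs, t=%d",
        spec.n_subjects,
        spec.n_nodes,
        spec.n_arcs,
        spec.n_timepoints,
    )
    graph = make_stable_graph(
        spec.n_nodes,
        spec.n_arcs,
        spec.n_bidirectional,
        cfg.sim_options.coupling_strength,
        seed=cfg.seed,
    )
    cohort, truths = simulate_cohort(
        graph, spec.n_subjects, spec.n_timepoints, cfg.sim_options, seed=cfg.seed
    )
    if cfg.normalize:
        cohort = cohort.zscore()
    return cohort, truths


@_stage("train")
def _train(cfg: RunConfig, cohort: CohortTimeSeries):
    training = cfg.training
    if training.seed != cfg.seed:
        training = type(training)(**{**training.as_dict(), "seed": cfg.seed})
    return train_amortized(cohort, training, cfg.encoder, cfg.decoder)


@_stage("guidance")
def _guide(cfg: RunConfig, cohort: CohortTimeSeries, graphs: list[ECGraph]):
    if cfg.guidance == "off":
        return [pearson_fc(cohort.subject(s)) for s in range(cohort.n_subjects)], graphs
    fcs = [pearson_fc(cohort.subject(s)) for s in range(cohort.n_subjects)]
    return fcs, [guide_ec(g, w, mode=cfg.guidance) for g, w in zip(graphs, fcs)]


def _config_hash(cfg: RunConfig) -> str:
    canonical = yaml.safe_dump(cfg.to_dict(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> dict:
    """Run both phases and write all artifacts under ``out_dir``.

    Returns the report dictionary (also written as ``report.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    stderr_handler = logging.StreamHandler(sys.stderr)
    log.setLevel(logging.INFO)
    log.addHandler(handler)
    log.addHandler(stderr_handler)
    try:
        log.info("seed=%d config_hash=%s", cfg.seed, _config_hash(cfg))
        cohort, truths = _get_cohort(cfg)
        if truths is not None:
            save_cohort_csv_dir(cohort, out / "cohort", truths=truths)
        state, report = _train(cfg, cohort)
        save_checkpoint(state, out / "checkpoint.npz")
        fcs, guided = _guide(cfg, cohort, report.graphs)
        tau = cfg.training.binarize_threshold
        binaries = [binarize(g, tau) for g in guided]

        labels = cohort.region_labels
        for kind, mats in (
            ("weighted", [g.weights for g in report.graphs]),
            ("guided", [g.weights for g in guided]),
            ("fc", [w.values for w in fcs]),
            ("binary", binaries),
        ):
            sub = out / kind
            sub.mkdir(exist_ok=True)
            for sid, mat in zip(cohort.subject_ids, mats):
                save_adjacency_csv(mat, sub / f"{sid}.csv", labels)
        edges = out / "edges"
        edges.mkdir(exist_ok=True)
        for sid, g in zip(cohort.subject_ids, guided):
            save_edge_list(g.weights, edges / f"{sid}.tsv", labels)

        result = {
            "seed": cfg.seed,
            "config_hash": _config_hash(cfg),
            "config": cfg.to_dict(),
            "n_subjects": cohort.n_subjects,
            "loss_trace": {
                "first": report.loss_trace[0],
                "last": report.loss_trace[-1],
                "min": min(report.loss_trace),
                "epochs": len(report.loss_trace),
            },
        }
        if truths is not None:
            evaluation = evaluate_cohort(binaries, [g.adjacency for g in truths])
            result["metrics"] = {"mean": evaluation.mean, "sd": evaluation.sd}
            rows = ["metric\tmean\tsd"]
            for key in ("precision", "recall", "f1", "shd"):
                rows.append(f"{key}\t{evaluation.mean[key]:.6f}\t{evaluation.sd[key]:.6f}")
            (out / "metrics.tsv").write_text("\n".join(rows) + "\n")
        (out / "report.json").write_text(json.dumps(result, indent=2, sort_keys=True))
        cfg.to_yaml(out / "config_echo.yaml")
        log.info("pipeline complete: %s", out)
        return result
    finally:
        log.removeHandler(handler)
        log.removeHandler(stderr_handler)
        handler.close()
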