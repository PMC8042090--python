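"""End-to-end experiment orchestration, result tables and run manifests.

``run_experiment`` executes generate -> (leaky and nested protocols) ->
feature-count sweep -> overlap analysis from a single config mapping, writes
every result as a tab-delimited table plus a JSON manifest of the config,
seeds and library versions, and is bit-reproducible from that manifest.
"""

from __future__ import annotations

import copy
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .classifiers import ClassifierSpec
from .cv_protocols import (
    ProtocolResult,
    SweepResult,
    make_cv_plan,
    run_feature_count_sweep,
    run_outside_cv_protocol,
    run_within_cv_protocol,
)
from .datatypes import FeatureMatrix
from .overlap import classify_edges, overlap_ratio, selection_frequency
from .selection import VoteParams, VoteTable, select_by_threshold, vote_count
from .synthetic import (
    ConnectivitySpec,
    GaussianGridSpec,
    generate_connectivity_features,
    generate_gaussian_features,
    generate_null_features,
    zscore_standardize,
)

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "data": {
        "kind": "gaussian",  # gaussian | null | connectivity
        "n_features": 6424,
        "n_per_class": 58,
        "per_class_draw": False,
        "grid_mode": "discrete",
    },
    "vote": {"n_reps": 100, "subsample_frac": 0.8, "alpha": 0.05, "t_variant": "pooled"},
    "cv": {"n_folds": 10, "n_repetitions": 10, "stratified": True},
    "classifiers": [
        {"kind": "svm", "svm_cost": 1.0},
        {"kind": "rlda", "rlda_gamma": "auto"},
    ],
    "thresholds": [50, 60, 70, 80, 90],
    "sweep": {"enabled": True, "k_max": 40},
    "overlap": {"enabled": True, "threshold": 90, "cutoff": 50},
    "write_data": False,
}


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Defaults, optionally updated from a YAML/JSON file and an override dict."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)

    def merge(dst: dict, src: dict) -> None:
        for k, v in src.items():
            if isinstance(v, dict) and isinstance(dst.get(k), dict):
                merge(dst[k], v)
            else:
                dst[k] = v

    if path is not None:
        with open(path) as fh:
            merge(cfg, yaml.safe_load(fh) or {})
    if overrides:
        merge(cfg, overrides)
    return cfg


def _stage_seeds(master: int | None) -> dict[str, int]:
    state = np.random.SeedSequence(master).generate_state(3) % (2**31)
    return {"data": int(state[0]), "vote": int(state[1]), "cv_plan": int(state[2])}


def _classifier_specs(entries: Sequence[dict]) -> list[ClassifierSpec]:
    return [ClassifierSpec(**e) for e in entries]


def _generate(cfg: dict, seed: int):
    data_cfg = cfg["data"]
    kind = data_cfg["kind"]
    if kind == "gaussian":
        spec = GaussianGridSpec(
            n_features=data_cfg["n_features"],
            n_per_class=data_cfg["n_per_class"],
            per_class_draw=data_cfg.get("per_class_draw", False),
            grid_mode=data_cfg.get("grid_mode", "discrete"),
            seed=seed,
        )
        return generate_gaussian_features(spec), None
    if kind == "null":
        return (
            generate_null_features(data_cfg["n_features"], data_cfg["n_per_class"], seed=seed),
            None,
        )
    if kind == "connectivity":
        spec = ConnectivitySpec(
            n_per_class=data_cfg["n_per_class"],
            planted_edges=[tuple(e) for e in data_cfg.get("planted_edges", [])]
            or ConnectivitySpec().planted_edges,
            seed=seed,
        )
        return generate_connectivity_features(spec)
    raise ValueError(f"unknown data kind {kind!r}")


@dataclass
class RunManifest:
    """Everything needed to re-execute a run bit-identically."""

    config: dict
    seeds: dict[str, int]
    started_utc: str
    finished_utc: str = ""
    versions: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, default=str)


def _fmt(x: float) -> str:
    return f"{x:.2f}"


def render_summary_table(
    outside: ProtocolResult,
    within: ProtocolResult,
    path: str | Path | None = None,
) -> pd.DataFrame:
    """Two-protocol accuracy table: one row per vote threshold plus a mean (S.D.) row.

    Columns per protocol: n selected (integer for the leaky protocol,
    "min-max" for the nested one) and the mean accuracy (%) of each
    classifier, two-decimal formatted.  Requires identical threshold lists
    and classifiers in both results.
    """
    if list(outside.thresholds) != list(within.thresholds):
        raise ValueError("protocol results cover different thresholds")
    if list(outside.classifier_kinds) != list(within.classifier_kinds):
        raise ValueError("protocol results cover different classifiers")

    kinds = outside.classifier_kinds
    rows = []
    for t in outside.thresholds:
        row: dict = {"vote_threshold": f">={t}"}
        n_out = outside.n_selected[t]
        row["outside_n"] = str(n_out)
        for k in kinds:
            row[f"outside_{k}"] = _fmt(outside.mean_accuracy(t, k))
        n_in = within.n_selected[t]
        row["within_n"] = f"{n_in[0]}-{n_in[1]}" if isinstance(n_in, tuple) else str(n_in)
        for k in kinds:
            row[f"within_{k}"] = _fmt(within.mean_accuracy(t, k))
        rows.append(row)

    mean_row: dict = {"vote_threshold": "Mean (S.D.)", "outside_n": "", "within_n": ""}
    for prefix, result in (("outside", outside), ("within", within)):
        for k in kinds:
            per_t = np.array([result.mean_accuracy(t, k) for t in result.thresholds])
            sd = per_t.std(ddof=1) if len(per_t) > 1 else 0.0
            mean_row[f"{prefix}_{k}"] = f"{per_t.mean():.2f} ({sd:.2f})"
    rows.append(mean_row)

    frame = pd.DataFrame(rows)
    if path is not None:
        frame.to_csv(path, sep="\t", index=False)
    return frame


def export_sweep(
    sweeps: SweepResult | Sequence[SweepResult], path: str | Path
) -> pd.DataFrame:
    """Write sweep curves in long format (k, protocol, classifier, accuracy %)."""
    if isinstance(sweeps, SweepResult):
        sweeps = [sweeps]
    frame = pd.concat([s.to_frame() for s in sweeps], ignore_index=True)
    frame = frame.sort_values(["protocol", "classifier", "k"], kind="stable").reset_index(
        drop=True
    )
    frame.to_csv(path, sep="\t", index=False, float_format="%.6f")
    return frame


def run_experiment(config: dict | str | Path | None = None, out_dir: str | Path = "results") -> RunManifest:
    """Execute the full pipeline from a config and persist all result tables.

    Stages: synthetic data generation, both CV protocols over the configured
    thresholds, the feature-count sweep for both protocols, and the overlap
    analysis at the configured threshold (with edge categorization when the
    data carry a connectivity index).  Any stage failure aborts with the
    stage name and cause.
    """
    if config is None or isinstance(config, (str, Path)):
        cfg = load_config(config)
    else:
        cfg = load_config(overrides=config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(cfg["seed"])
    manifest = RunManifest(
        config=cfg,
        seeds=seeds,
        started_utc=time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime()),
        versions={
            "leakage_lab": __import__("leakage_lab").__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    )

    stage = "generate"
    try:
        data, conn_index = _generate(cfg, seeds["data"])
        if cfg.get("write_data"):
            data.to_tsv(out / "data.tsv")
            manifest.outputs["data"] = str(out / "data.tsv")
            if conn_index is not None:
                conn_index.to_tsv(out / "connectivity_index.tsv")
                manifest.outputs["connectivity_index"] = str(out / "connectivity_index.tsv")

        specs = _classifier_specs(cfg["classifiers"])
        vote = VoteParams(**cfg["vote"], seed=seeds["vote"])
        plan = make_cv_plan(
            data.labels,
            n_folds=cfg["cv"]["n_folds"],
            n_repetitions=cfg["cv"]["n_repetitions"],
            seed=seeds["cv_plan"],
            stratified=cfg["cv"]["stratified"],
        )
        thresholds = list(cfg["thresholds"])

        stage = "outside_cv"
        t0 = time.time()
        outside = run_outside_cv_protocol(data, thresholds, specs, plan, vote)
        logger.info("outside_cv done in %.1fs", time.time() - t0)

        stage = "within_cv"
        t0 = time.time()
        within = run_within_cv_protocol(data, thresholds, specs, plan, vote)
        logger.info("within_cv done in %.1fs", time.time() - t0)

        stage = "summary"
        render_summary_table(outside, within, out / "summary.tsv")
        manifest.outputs["summary"] = str(out / "summary.tsv")

        if cfg["sweep"]["enabled"]:
            stage = "sweep"
            t0 = time.time()
            sweeps = [
                run_feature_count_sweep(data, p, specs, plan, vote, cfg["sweep"]["k_max"])
                for p in ("outside_cv", "within_cv")
            ]
            export_sweep(sweeps, out / "sweep.tsv")
            manifest.outputs["sweep"] = str(out / "sweep.tsv")
            logger.info("sweep done in %.1fs", time.time() - t0)

        if cfg["overlap"]["enabled"]:
            stage = "overlap"
            t = cfg["overlap"]["threshold"]
            std, _ = zscore_standardize(data)
            table: VoteTable = vote_count(std, vote)
            outside_sel = select_by_threshold(table, t)
            loops = within.per_loop_selected[t]
            report = overlap_ratio(outside_sel, loops)
            freq = selection_frequency(loops)
            overlap_frame = pd.DataFrame(
                {
                    "threshold": [t],
                    "mean_overlap_percent": [report.mean_percent],
                    "n_loops": [len(report.per_loop_ratio)],
                }
            )
            overlap_frame.to_csv(out / "overlap.tsv", sep="\t", index=False)
            manifest.outputs["overlap"] = str(out / "overlap.tsv")
            if conn_index is not None:
                edges = classify_edges(outside_sel, freq, conn_index, cfg["overlap"]["cutoff"])
                edges.to_csv(out / "edge_categories.tsv", sep="\t", index=False)
                manifest.outputs["edge_categories"] = str(out / "edge_categories.tsv")
    except Exception as exc:
        raise RuntimeError(f"experiment failed at stage {stage!r}: {exc}") from exc

    manifest.finished_utc = time.strftime("%Y-%m-%dT%H:%M:%SZ", time.gmtime())
    manifest.to_json(out / "manifest.json")
    manifest.outputs["manifest"] = str(out / "manifest.json")
    return manifest
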