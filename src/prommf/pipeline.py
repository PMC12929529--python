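"""End-to-end orchestration: data -> preprocessing -> models -> comparisons.

One YAML config drives the whole run. :func:`run_pipeline` generates (or
loads) a cohort, splits it at the patient level, trains every requested
model under the shared protocol, evaluates each on the held-out test set,
and produces a paired comparison report for every model pair. A failing
model is recorded in the manifest without aborting the others. Fixed seed
in, identical numbers out.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evalstat, syncohort, training
from .fusionnet import FusionConfig

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "load_config", "run_pipeline", "DEFAULT_CONFIG", "FAST_CONFIG"]

# full protocol: 6:2:2 at seed 2024, 100 epochs
DEFAULT_CONFIG: dict = {
    "synthetic": dataclasses.asdict(syncohort.SyntheticSpec()),
    "data_dir": None,
    "split": {"ratio": [0.6, 0.2, 0.2], "seed": 2024, "stratified": False},
    "train": {"learning_rate": 1e-4, "weight_decay": 5e-3, "epochs": 100,
              "dropout": 0.1, "seed": 2024, "max_tiles": None,
              "lfc_threshold": 2.0, "p_threshold": 0.05, "de_method": "welch"},
    "fusion": {"mode": "kron", "progressive": True, "iterations": 2,
               "unimodal_dim": 32, "classifier_hidden": 64,
               "share_backprojection_weights": True, "late_fusion_weight": 0.5},
    "models": ["AMIL", "DMLP", "LateFusion", "MMF_Kron", "MMF_Con",
               "ProMMF_Kron", "ProMMF_Con"],
    "comparison": {"n_boot": 2000, "n_perm": 5000, "n_sim": 2000, "seed": 2024},
}

# small-cohort, short-epoch profile for quick runs
FAST_CONFIG: dict = {
    **DEFAULT_CONFIG,
    "synthetic": dataclasses.asdict(
        syncohort.SyntheticSpec(n_patients=60, n_genes=300, embedding_dim=64,
                                signal_dim=8, bag_size_range=(4, 10))
    ),
    "split": {"ratio": [0.6, 0.2, 0.2], "seed": 2024, "stratified": True},
    "train": {**DEFAULT_CONFIG["train"], "epochs": 20},
    "models": ["DMLP", "ProMMF_Kron"],
    "comparison": {"n_boot": 500, "n_perm": 1000, "n_sim": 500, "seed": 2024},
}


class PipelineConfig(dict):
    """A validated nested config dict (YAML-round-trippable)."""

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        merged = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
        for key, val in d.items():
            if isinstance(val, dict) and isinstance(merged.get(key), dict):
                merged[key].update(val)
            else:
                merged[key] = val
        return cls(merged)

    def train_config(self) -> training.TrainConfig:
        t = self["train"]
        return training.TrainConfig(
            learning_rate=t["learning_rate"], weight_decay=t["weight_decay"],
            epochs=t["epochs"], dropout=t["dropout"], seed=t["seed"],
            max_tiles=t.get("max_tiles"), lfc_threshold=t["lfc_threshold"],
            p_threshold=t["p_threshold"], de_method=t["de_method"],
            fusion=FusionConfig(**self["fusion"]),
        )


def load_config(path: str | Path | None = None, profile: str = "default") -> PipelineConfig:
    if path is not None:
        with open(path) as f:
            return PipelineConfig.from_dict(yaml.safe_load(f) or {})
    base = FAST_CONFIG if profile == "fast" else DEFAULT_CONFIG
    return PipelineConfig.from_dict(base)


def _get_cohort(cfg: PipelineConfig) -> syncohort.Cohort:
    if cfg.get("data_dir"):
        return syncohort.read_cohort(cfg["data_dir"])
    spec = syncohort.spec_from_dict(cfg["synthetic"])
    return syncohort.generate_cohort(spec)


def run_pipeline(config: PipelineConfig | str | Path, out_dir: str | Path) -> dict:
    """Execute the full study described by ``config``; return the manifest."""
    if not isinstance(config, PipelineConfig):
        config = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    cohort = _get_cohort(config)
    scfg = config["split"]
    split = training.patient_level_split(
        cohort.patient_ids, ratio=tuple(scfg["ratio"]), seed=scfg["seed"],
        stratify_labels=cohort.labels if scfg.get("stratified") else None,
    )
    with open(out / "split.json", "w") as f:
        json.dump(split.assignment, f, indent=2)

    tcfg = config.train_config()
    runs: dict[str, training.TrainRun] = {}
    failures: dict[str, str] = {}
    metric_rows = []
    audits = {}
    for name in config["models"]:
        try:
            run = training.train_model(cohort, split, name, tcfg)
        except Exception as exc:  # isolate per-model failures
            logger.exception("model %s failed", name)
            failures[name] = f"{type(exc).__name__}: {exc}"
            continue
        runs[name] = run
        audits[name] = training.no_leakage_audit(run)
        metric_rows.append({"model": name, **run.metrics("test")})
        pd.DataFrame({"epoch": range(len(run.loss_history)),
                      "train_loss": run.loss_history,
                      "val_auc": run.val_auc_history or np.nan}
                     ).to_csv(out / f"history_{name}.csv", index=False)
        run.predictions["test"].to_frame().to_csv(out / f"scores_{name}.csv",
                                                  index=False)
        training.save_checkpoint(run, out / f"checkpoint_{name}.npz")

    metrics = pd.DataFrame(metric_rows)
    metrics.to_csv(out / "metrics.csv", index=False)

    ccfg = config["comparison"]
    reports = {}
    for a, b in itertools.combinations(runs, 2):
        rep = evalstat.compare_models(
            runs[a].predictions["test"], runs[b].predictions["test"],
            n_boot=ccfg["n_boot"], n_perm=ccfg["n_perm"], n_sim=ccfg["n_sim"],
            seed=ccfg["seed"],
        )
        rep.to_json(out / f"compare_{a}_vs_{b}.json")
        reports[f"{a}_vs_{b}"] = json.loads(rep.to_json())

    manifest = {
        "config": dict(config),
        "n_patients": len(cohort.records),
        "split_sizes": {p: len(split.ids(p)) for p in ("train", "val", "test")},
        "metrics": metric_rows,
        "comparisons": reports,
        "leakage_audits": audits,
        "failures": failures,
        "elapsed_seconds": round(time.time() - t0, 2),
        "package_version": __import__("prommf").__version__,
        "library_versions": {m: __import__(m).__version__
                             for m in ("numpy", "scipy", "pandas", "sklearn")},
    }
    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2, default=str)
    return manifest
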