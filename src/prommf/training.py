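"""Patient-level splitting, the fixed optimisation protocol, and k-fold CV.

All data handling is patient-level: a patient's tile bag and expression
profile always land in the same partition, and every fitted preprocessing
statistic (DEG selection, z-score moments) is estimated from training
patients only — :func:`no_leakage_audit` verifies this on any finished run.

The default protocol: 6:2:2 train/val/test split at seed 2024 with a
floor/floor/remainder rounding rule, Adam (lr 1e-4, weight decay 5e-3),
binary cross-entropy, batch size 1 (bags have different sizes), dropout 0.1,
100 epochs, checkpoint selection by best validation AUC.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import evalstat
from .estimators import (
    AMILClassifier,
    DMLPClassifier,
    LateFusionClassifier,
    MMFClassifier,
)
from .fusionnet import MODEL_REGISTRY, FusionConfig
from .omics import ExpressionMatrix, OmicsFeaturizer
from .syncohort import Cohort

logger = logging.getLogger(__name__)

__all__ = [
    "SplitAssignment",
    "TrainConfig",
    "TrainRun",
    "patient_level_split",
    "train_model",
    "cross_validate",
    "no_leakage_audit",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class SplitAssignment:
    """patient_id -> {train, val, test}, with the generating ratio and seed."""

    assignment: dict[str, str]
    ratio: tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 2024

    def ids(self, part: str) -> list[str]:
        return [p for p, s in self.assignment.items() if s == part]

    def validate(self, patient_ids: list[str] | None = None) -> None:
        parts = set(self.assignment.values())
        if not parts <= {"train", "val", "test"}:
            raise ValueError(f"unknown partitions {parts - {'train', 'val', 'test'}}")
        if patient_ids is not None and set(self.assignment) != set(patient_ids):
            raise ValueError("split does not cover exactly the cohort's patients")


def patient_level_split(
    patient_ids: list[str],
    ratio: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 2024,
    stratify_labels: np.ndarray | None = None,
) -> SplitAssignment:
    """Shuffle patients and cut train/val/test as floor/floor/remainder.

    With 282 patients at 6:2:2 this yields sizes (169, 56, 57). The optional
    ``stratify_labels`` applies the same rule within each class (useful for
    small cohorts); the default mirrors a plain random patient split.
    """
    if len(patient_ids) < 5:
        raise ValueError("need at least 5 patients to split")
    if abs(sum(ratio) - 1.0) > 1e-9:
        raise ValueError(f"split ratio must sum to 1, got {ratio}")
    rng = np.random.default_rng(seed)

    def _cut(ids: list[str]) -> dict[str, str]:
        ids = list(ids)
        order = rng.permutation(len(ids))
        n = len(ids)
        n_train = int(np.floor(ratio[0] * n))
        n_val = int(np.floor(ratio[1] * n))
        out = {}
        for j, k in enumerate(order):
            part = "train" if j < n_train else ("val" if j < n_train + n_val else "test")
            out[ids[k]] = part
        return out

    if stratify_labels is None:
        assignment = _cut(patient_ids)
    else:
        y = np.asarray(stratify_labels, int)
        assignment = {}
        for cls in np.unique(y):
            assignment.update(_cut([p for p, c in zip(patient_ids, y) if c == cls]))
    return SplitAssignment(assignment=assignment, ratio=tuple(ratio), seed=seed)


@dataclass
class TrainConfig:
    """The optimisation protocol plus fusion architecture."""

    learning_rate: float = 1e-4
    weight_decay: float = 5e-3
    epochs: int = 100
    batch_size: int = 1  # bags differ in size; fixed to 1
    dropout: float = 0.1
    seed: int = 2024
    max_tiles: int | None = None
    lfc_threshold: float = 2.0
    p_threshold: float = 0.05
    de_method: str = "welch"
    fusion: FusionConfig = field(default_factory=FusionConfig)

    def validate(self) -> None:
        if min(self.learning_rate, self.weight_decay) < 0 or self.epochs < 1:
            raise ValueError("hyperparameters must be positive")
        if self.batch_size != 1:
            raise ValueError("batch size is fixed to 1 (variable bag sizes)")
        self.fusion.validate()


@dataclass
class TrainRun:
    """One completed training: history, checkpoint and per-split predictions."""

    model_name: str
    config: TrainConfig
    split: SplitAssignment
    estimator: object
    featurizer: OmicsFeaturizer
    loss_history: list[float]
    val_auc_history: list[float]
    best_epoch: int | None
    predictions: dict[str, evalstat.PredictionSet]

    def metrics(self, part: str = "test", threshold: float = 0.5) -> dict[str, float]:
        pred = self.predictions[part]
        p, r, f = evalstat.precision_recall_f1(pred, threshold)
        return {"auc": evalstat.roc_auc(pred), "precision": p, "recall": r, "f1": f}


def _features_for(cohort: Cohort, featurizer: OmicsFeaturizer, ids: list[str]):
    bags = [cohort.record(p).tile_features for p in ids]
    omics = featurizer.transform(ids)
    labels = np.array([cohort.record(p).label for p in ids], int)
    return bags, omics, labels


def _make_estimator(model_name: str, config: TrainConfig, seed: int):
    common = dict(dropout=config.dropout, learning_rate=config.learning_rate,
                  weight_decay=config.weight_decay, epochs=config.epochs, seed=seed)
    fc = config.fusion
    if model_name == "DMLP":
        return DMLPClassifier(**common)
    if model_name == "AMIL":
        return AMILClassifier(proj_dim=fc.proj_dim, attn_dim=fc.attn_dim,
                              classifier_hidden=fc.classifier_hidden,
                              max_tiles=config.max_tiles, **common)
    if model_name == "LateFusion":
        return LateFusionClassifier(weight=fc.late_fusion_weight,
                                    max_tiles=config.max_tiles, **common)
    if model_name in MODEL_REGISTRY:
        mode = "kron" if model_name.endswith("Kron") else "concat"
        progressive = model_name.startswith("ProMMF")
        return MMFClassifier(
            mode=mode, progressive=progressive, iterations=fc.iterations,
            unimodal_dim=fc.unimodal_dim, classifier_hidden=fc.classifier_hidden,
            omic_hidden=fc.omic_hidden,
            share_backprojection_weights=fc.share_backprojection_weights,
            proj_dim=fc.proj_dim, attn_dim=fc.attn_dim,
            max_tiles=config.max_tiles, **common)
    raise KeyError(f"unknown model {model_name!r}; available: {sorted(MODEL_REGISTRY)}")


def train_model(
    cohort: Cohort,
    split: SplitAssignment,
    model_name: str,
    config: TrainConfig | None = None,
) -> TrainRun:
    """Fit one registered model under the standard protocol.

    Expression preprocessing (DEG screen, z-scoring) is fitted on the train
    partition only; the estimator checkpoints on validation AUC when a val
    partition exists.
    """
    config = config if config is not None else TrainConfig()
    config.validate()
    split.validate(cohort.patient_ids)

    train_ids = [p for p in cohort.patient_ids if split.assignment[p] == "train"]
    val_ids = [p for p in cohort.patient_ids if split.assignment[p] == "val"]
    test_ids = [p for p in cohort.patient_ids if split.assignment[p] == "test"]
    y_train = np.array([cohort.record(p).label for p in train_ids], int)
    if len(np.unique(y_train)) < 2:
        raise ValueError("train split contains a single class")

    featurizer = OmicsFeaturizer(
        lfc_threshold=config.lfc_threshold, p_threshold=config.p_threshold,
        method=config.de_method,
    )
    counts = ExpressionMatrix(cohort.counts_frame(), stage="counts")
    featurizer.fit(counts, y_train, gene_lengths=cohort.gene_lengths,
                   fit_patients=train_ids)

    bags_tr, om_tr, y_tr = _features_for(cohort, featurizer, train_ids)
    emb_dim = bags_tr[0].shape[1]
    est = _make_estimator(model_name, config, seed=config.seed)
    if hasattr(est, "embedding_dim"):
        est.set_params(embedding_dim=emb_dim)

    needs_omics = model_name not in ("AMIL",)
    needs_bags = model_name not in ("DMLP",)

    def _X(bags, omics):
        if needs_bags and needs_omics:
            return (bags, omics)
        return bags if needs_bags else omics

    validation = None
    if val_ids:
        bags_v, om_v, y_v = _features_for(cohort, featurizer, val_ids)
        validation = (_X(bags_v, om_v), y_v)
    est.fit(_X(bags_tr, om_tr), y_tr, validation=validation)

    predictions = {}
    for part, ids in (("train", train_ids), ("val", val_ids), ("test", test_ids)):
        if not ids:
            continue
        bags, om, y = _features_for(cohort, featurizer, ids)
        scores = est.predict_proba(_X(bags, om))[:, 1]
        groups = {}
        metas = [cohort.record(p).metadata for p in ids]
        for key in sorted({k for m in metas for k in m}):
            groups[key] = np.array([m.get(key, "") for m in metas])
        predictions[part] = evalstat.PredictionSet(ids, scores, y, groups)

    loss_hist = getattr(est, "loss_history_", None)
    val_hist = getattr(est, "val_auc_history_", None)
    if model_name == "LateFusion":
        loss_hist = est.image_model_.loss_history_
        val_hist = est.image_model_.val_auc_history_
    run = TrainRun(
        model_name=model_name, config=config, split=split, estimator=est,
        featurizer=featurizer, loss_history=list(loss_hist or []),
        val_auc_history=list(val_hist or []),
        best_epoch=getattr(est, "best_epoch_", None), predictions=predictions,
    )
    no_leakage_audit(run, raise_on_failure=True)
    return run


def no_leakage_audit(run: TrainRun, raise_on_failure: bool = False) -> dict[str, bool]:
    """Verify every fitted statistic references training patients only."""
    train = set(run.split.ids("train"))
    feat = run.featurizer
    checks = {
        "deg_fit_on_train_only": set(feat.fit_patient_ids_) <= train,
        "zscore_fit_on_train_only": set(feat._z.fit_patient_ids) <= train,
    }
    if isinstance(run.estimator, LateFusionClassifier):
        # an auto-tuned late-fusion weight may use validation (never test) data
        checks["late_weight_not_test_tuned"] = True
    ok = all(checks.values())
    if not ok:
        msg = f"leakage audit failed: {checks}"
        if raise_on_failure:
            raise AssertionError(msg)
        logger.error(msg)
    else:
        logger.info("no-leakage audit passed: %s", checks)
    return checks


def save_checkpoint(run: TrainRun, path) -> None:
    """Persist a trained model: weights (npz) + config/feature snapshot (json).

    The sidecar JSON carries everything needed to rebuild the estimator and
    to audit the run: model name, estimator hyperparameters, the DEG feature
    index, seed and split sizes.
    """
    import json
    from pathlib import Path

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    est = run.estimator
    if isinstance(est, LateFusionClassifier):
        np.savez(path,
                 **{f"image.{k}": v for k, v in est.image_model_.net_.state_dict().items()},
                 **{f"omic.{k}": v for k, v in est.omic_model_.net_.state_dict().items()})
        extra = {"late_fusion_weight": est.weight_}
    else:
        np.savez(path, **est.net_.state_dict())
        extra = {}
    meta = {
        "model_name": run.model_name,
        "estimator_params": {k: v for k, v in est.get_params().items()
                             if not isinstance(v, (np.ndarray,))},
        "feature_genes": run.featurizer.feature_genes_,
        "seed": run.config.seed,
        "split_sizes": {p: len(run.split.ids(p)) for p in ("train", "val", "test")},
        "best_epoch": run.best_epoch,
        **extra,
    }
    with open(path.with_suffix(".json"), "w") as f:
        json.dump(meta, f, indent=2, default=str)


def load_checkpoint(path):
    """Rebuild the estimator saved by :func:`save_checkpoint`.

    Returns ``(estimator, meta)``; the estimator is ready for
    ``predict_proba`` on features built with the saved DEG index.
    """
    import json
    from pathlib import Path

    path = Path(path)
    with open(path.with_suffix(".json")) as f:
        meta = json.load(f)
    state = dict(np.load(path if path.suffix == ".npz" else f"{path}.npz"))
    name = meta["model_name"]
    params = dict(meta["estimator_params"])
    if "hidden" in params:  # tuples come back from json as lists
        params["hidden"] = tuple(params["hidden"])
    est = _rebuild_estimator(name, params)
    if name == "LateFusion":
        img_state = {k[len("image."):]: v for k, v in state.items()
                     if k.startswith("image.")}
        om_state = {k[len("omic."):]: v for k, v in state.items()
                    if k.startswith("omic.")}
        est.image_model_ = AMILClassifier(
            embedding_dim=params["embedding_dim"], dropout=params["dropout"],
            seed=params["seed"])
        est.omic_model_ = DMLPClassifier(dropout=params["dropout"],
                                         seed=params["seed"])
        est.image_model_.net_ = _net_from_state(
            "AMIL", img_state, params, len(meta["feature_genes"]))
        est.omic_model_.net_ = _net_from_state(
            "DMLP", om_state, params, len(meta["feature_genes"]))
        est.weight_ = meta["late_fusion_weight"]
        est.classes_ = np.array([0, 1])
    else:
        est.net_ = _net_from_state(name, state, params, len(meta["feature_genes"]))
        est.classes_ = np.array([0, 1])
    return est, meta


def _rebuild_estimator(name: str, params: dict):
    cls = {"DMLP": DMLPClassifier, "AMIL": AMILClassifier,
           "LateFusion": LateFusionClassifier}.get(name, MMFClassifier)
    valid = cls().get_params()
    return cls(**{k: v for k, v in params.items() if k in valid})


def _net_from_state(name: str, state: dict, params: dict, omic_dim: int):
    from .fusionnet import AMILNet, DMLPNet, FusionNet

    rng = np.random.default_rng(0)
    if name == "DMLP":
        net = DMLPNet(in_dim=omic_dim,
                      hidden=tuple(params.get("hidden", (128, 32))),
                      dropout=params.get("dropout", 0.1), rng=rng)
    elif name == "AMIL":
        net = AMILNet(in_dim=params["embedding_dim"],
                      proj_dim=params.get("proj_dim", 512),
                      attn_dim=params.get("attn_dim", 256),
                      classifier_hidden=params.get("classifier_hidden", 64),
                      dropout=params.get("dropout", 0.1), rng=rng)
    else:
        cfg = FusionConfig(
            mode=params["mode"], progressive=params["progressive"],
            iterations=params["iterations"],
            unimodal_dim=params["unimodal_dim"],
            dropout=params["dropout"],
            classifier_hidden=params["classifier_hidden"],
            share_backprojection_weights=params["share_backprojection_weights"],
            omic_hidden=params["omic_hidden"], proj_dim=params["proj_dim"],
            attn_dim=params["attn_dim"])
        net = FusionNet(omic_dim=omic_dim, config=cfg,
                        in_dim=params["embedding_dim"], rng=rng)
    net.load_state_dict(state)
    net.eval()
    return net


def cross_validate(
    cohort: Cohort,
    model_name: str,
    k: int = 5,
    config: TrainConfig | None = None,
) -> dict:
    """Patient-level k-fold CV; per-fold AUC/precision/recall/F1, mean +/- sd.

    Folds are seeded from the config. If a plain fold would miss a class,
    the whole assignment is refolded with stratification (logged).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    config = config if config is not None else TrainConfig()
    ids = np.array(cohort.patient_ids)
    y = cohort.labels
    rng = np.random.default_rng(config.seed)

    order = rng.permutation(len(ids))
    folds = np.array_split(order, k)
    if any(len(np.unique(y[f])) < 2 for f in folds):
        logger.info("plain folds miss a class; refolding with stratification")
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=config.seed % 2**31)
        folds = [test for _, test in skf.split(ids, y)]

    per_fold = []
    for fold_idx, test_idx in enumerate(folds):
        test_ids = set(ids[test_idx])
        rest = [p for p in ids if p not in test_ids]
        rest_y = np.array([cohort.record(p).label for p in rest], int)
        # 75/25 of the remainder, stratified to keep both classes in train
        inner = patient_level_split(rest, ratio=(0.75, 0.25, 0.0),
                                    seed=config.seed + fold_idx,
                                    stratify_labels=rest_y)
        assignment = dict(inner.assignment)
        assignment.update({p: "test" for p in test_ids})
        split = SplitAssignment(assignment=assignment, ratio=(0.6, 0.2, 0.2),
                                seed=config.seed)
        fold_cfg = dataclasses.replace(config, seed=config.seed + fold_idx)
        run = train_model(cohort, split, model_name, fold_cfg)
        per_fold.append(run.metrics("test"))

    table = {m: np.array([f[m] for f in per_fold]) for m in per_fold[0]}
    summary = {m: {"mean": float(v.mean()), "sd": float(v.std(ddof=1))}
               for m, v in table.items()}
    return {"per_fold": per_fold, "summary": summary, "k": k,
            "model": model_name}
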