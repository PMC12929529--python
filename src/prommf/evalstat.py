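"""Classification metrics and paired model-comparison statistics.

Two fitted classifiers scored on the *same* test patients are compared with:

* paired bootstrap — resample patients with replacement, apply the identical
  index vector to both score vectors, recompute both AUCs per replicate;
  95% confidence intervals by the percentile method (2.5th / 97.5th);
* paired permutation test — the observed statistic is the mean per-patient
  score difference; each permutation independently swaps each pair's two
  scores with probability 0.5; two-sided p with add-one smoothing;
* paired Cohen's d — mean difference over its sample standard deviation;
* parametric Monte-Carlo power — simulate paired differences from a normal
  law with the observed mean and SD, and count replicates whose one-sample
  t statistic exceeds the two-sided critical value at alpha.

An alternative permutation statistic (the recomputed AUC difference) is
available behind ``statistic="auc_difference"``; the default follows the
mean-difference formulation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import precision_recall_fscore_support, roc_auc_score

logger = logging.getLogger(__name__)

__all__ = [
    "PredictionSet",
    "ComparisonReport",
    "roc_auc",
    "precision_recall_f1",
    "group_metrics",
    "paired_bootstrap_auc",
    "paired_permutation_test",
    "cohens_d_paired",
    "power_parametric_mc",
    "compare_models",
]


@dataclass
class PredictionSet:
    """Patient-aligned scores and labels (MSI = positive class)."""

    patient_ids: list[str]
    scores: np.ndarray
    labels: np.ndarray
    groups: dict[str, np.ndarray] = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        n = len(self.patient_ids)
        if self.scores.shape != (n,) or self.labels.shape != (n,):
            raise ValueError("patient_ids, scores and labels must align")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"patient_id": self.patient_ids,
                           "score": self.scores, "label": self.labels})
        for k, v in self.groups.items():
            df[k] = v
        return df

    @classmethod
    def from_csv(cls, path: str | Path) -> "PredictionSet":
        df = pd.read_csv(path)
        extra = [c for c in df.columns if c not in ("patient_id", "score", "label")]
        return cls(
            patient_ids=[str(p) for p in df["patient_id"]],
            scores=df["score"].to_numpy(float),
            labels=df["label"].to_numpy(int),
            groups={c: df[c].to_numpy() for c in extra},
        )


@dataclass
class ComparisonReport:
    """Everything the paired comparison of two models produces."""

    auc_a: float
    auc_b: float
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]
    delta_observed: float
    p_permutation: float
    cohen_d: float | None  # None when the difference SD is zero (undefined)
    cohen_d_sign: int = 0
    power: float = float("nan")
    n_bootstrap: int = 0
    n_permutation: int = 0

    def validate(self) -> None:
        for lo, hi in (self.ci_a, self.ci_b):
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError("CI bounds must be ordered within [0, 1]")
        if not 0.0 < self.p_permutation <= 1.0:
            raise ValueError("p must lie in (0, 1]")
        if not (np.isnan(self.power) or 0.0 <= self.power <= 1.0):
            raise ValueError("power must lie in [0, 1]")

    def to_json(self, path: str | Path | None = None) -> str:
        d = dataclasses.asdict(self)
        d["ci_a"], d["ci_b"] = list(self.ci_a), list(self.ci_b)
        s = json.dumps(d, indent=2)
        if path is not None:
            Path(path).write_text(s)
        return s


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC requires both classes to be present")
    return labels


def roc_auc(pred: PredictionSet) -> float:
    """ROC AUC in the Mann-Whitney formulation (ties count 1/2)."""
    labels = _check_binary(pred.labels)
    return float(roc_auc_score(labels, pred.scores))


def _auc_rows(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Row-wise AUC for (R, n) score matrices against (R, n) binary labels.

    Rank-based Mann-Whitney with midranks, vectorised over replicates.
    """
    ranks = stats.rankdata(scores, axis=1)
    n_pos = labels.sum(axis=1)
    n_neg = labels.shape[1] - n_pos
    r_pos = (ranks * labels).sum(axis=1)
    u = r_pos - n_pos * (n_pos + 1) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        return u / (n_pos * n_neg)


def precision_recall_f1(
    pred: PredictionSet, threshold: float = 0.5
) -> tuple[float, float, float]:
    """Precision/recall/F1 for the positive (MSI) class at a score threshold.

    Zero-denominator cases return 0 (flagged via a log record).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    y_hat = (pred.scores >= threshold).astype(int)
    if y_hat.sum() == 0:
        logger.info("no predicted positives at threshold %.3f; precision set to 0",
                    threshold)
    p, r, f, _ = precision_recall_fscore_support(
        pred.labels, y_hat, average="binary", pos_label=1, zero_division=0
    )
    return float(p), float(r), float(f)


def group_metrics(pred: PredictionSet, group_key: str,
                  threshold: float = 0.5) -> pd.DataFrame:
    """Per-group AUC/precision/recall/F1; AUC omitted when a class is absent."""
    if group_key not in pred.groups:
        raise KeyError(f"no group labels named {group_key!r}")
    g = np.asarray(pred.groups[group_key])
    rows = []
    for level in pd.unique(g):
        m = g == level
        if m.sum() == 0:
            logger.info("group %s=%r is empty; skipped", group_key, level)
            continue
        sub = PredictionSet([p for p, k in zip(pred.patient_ids, m) if k],
                            pred.scores[m], pred.labels[m])
        try:
            auc = roc_auc(sub)
        except ValueError:
            auc = np.nan
            logger.info("group %s=%r lacks a class; AUC omitted", group_key, level)
        p, r, f = precision_recall_f1(sub, threshold)
        rows.append({"group": level, "n": int(m.sum()), "auc": auc,
                     "precision": p, "recall": r, "f1": f})
    return pd.DataFrame(rows)


def paired_bootstrap_auc(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    labels: np.ndarray,
    n_boot: int = 2000,
    seed: int = 0,
) -> tuple[tuple[float, float], tuple[float, float], np.ndarray]:
    """Paired bootstrap of two models' AUCs on the same patients.

    Each replicate resamples patient indices with replacement and applies
    the identical index vector to both score vectors. Returns the two 95%
    percentile CIs and the per-replicate AUC-difference distribution.
    Replicates whose resample lacks a class are redrawn (count logged).
    """
    a = np.asarray(scores_a, float)
    b = np.asarray(scores_b, float)
    y = _check_binary(labels)
    if not (a.shape == b.shape == y.shape):
        raise ValueError("scores_a, scores_b and labels must align")
    n = y.shape[0]
    rng = np.random.default_rng(seed)

    idx = rng.integers(0, n, size=(n_boot, n))
    redraws = 0
    while True:
        ylab = y[idx]
        bad = (ylab.sum(axis=1) == 0) | (ylab.sum(axis=1) == n)
        if not bad.any():
            break
        redraws += int(bad.sum())
        idx[bad] = rng.integers(0, n, size=(int(bad.sum()), n))
    if redraws:
        logger.info("redrew %d single-class bootstrap replicates", redraws)

    auc_a = _auc_rows(a[idx], y[idx])
    auc_b = _auc_rows(b[idx], y[idx])
    ci_a = tuple(np.percentile(auc_a, [2.5, 97.5]))
    ci_b = tuple(np.percentile(auc_b, [2.5, 97.5]))
    return (float(ci_a[0]), float(ci_a[1])), (float(ci_b[0]), float(ci_b[1])), auc_a - auc_b


def paired_permutation_test(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    n_perm: int = 5000,
    seed: int = 0,
    statistic: str = "mean_difference",
    labels: np.ndarray | None = None,
) -> float:
    """Two-sided paired permutation p-value for two aligned score vectors.

    Under the null each pair's two scores are exchangeable, so every
    permutation independently swaps each pair with probability 0.5. The
    default statistic is the mean per-pair difference; ``"auc_difference"``
    recomputes the AUC difference per permutation (requires ``labels``).
    p = (1 + #{|T*| >= |T_obs|}) / (1 + n_perm).
    """
    a = np.asarray(scores_a, float)
    b = np.asarray(scores_b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("scores must be aligned 1-d arrays")
    if a.shape[0] < 2:
        raise ValueError("need at least 2 pairs")
    rng = np.random.default_rng(seed)
    n = a.shape[0]

    if statistic == "mean_difference":
        d = a - b
        t_obs = d.mean()
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
        t_null = (signs * d).mean(axis=1)
    elif statistic == "auc_difference":
        if labels is None:
            raise ValueError("auc_difference statistic requires labels")
        y = _check_binary(labels)
        t_obs = roc_auc_score(y, a) - roc_auc_score(y, b)
        swap = rng.random(size=(n_perm, n)) < 0.5
        pa = np.where(swap, b, a)
        pb = np.where(swap, a, b)
        ymat = np.broadcast_to(y, (n_perm, n))
        t_null = _auc_rows(pa, ymat) - _auc_rows(pb, ymat)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")

    exceed = int(np.sum(np.abs(t_null) >= abs(t_obs) - 1e-15))
    return float((1 + exceed) / (1 + n_perm))


def cohens_d_paired(scores_a: np.ndarray, scores_b: np.ndarray
                    ) -> tuple[float | None, int]:
    """Paired Cohen's d: mean difference / sample SD (ddof=1) of differences.

    Returns ``(d, sign)``; ``d`` is None (undefined) when the SD is zero,
    with the sign of the mean difference still reported.
    """
    d = np.asarray(scores_a, float) - np.asarray(scores_b, float)
    if d.shape[0] < 2:
        raise ValueError("need at least 2 pairs")
    sd = d.std(ddof=1)
    mean = d.mean()
    sign = int(np.sign(mean))
    if sd == 0:
        return None, sign
    return float(mean / sd), sign


def power_parametric_mc(
    mean_diff: float,
    sd_diff: float,
    n: int,
    alpha: float = 0.05,
    n_sim: int = 2000,
    seed: int = 0,
) -> float:
    """Monte-Carlo power of the paired (one-sample) two-sided t-test.

    Simulates ``n`` paired differences ~ Normal(mean_diff, sd_diff^2) per
    replicate and reports the fraction whose t statistic exceeds the
    two-sided critical value at ``alpha``.
    """
    if sd_diff <= 0:
        raise ValueError("sd_diff must be positive")
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    sims = rng.normal(mean_diff, sd_diff, size=(n_sim, n))
    t = sims.mean(axis=1) / (sims.std(axis=1, ddof=1) / np.sqrt(n))
    crit = stats.t.ppf(1 - alpha / 2, df=n - 1)
    return float(np.mean(np.abs(t) > crit))


def compare_models(
    pred_a: PredictionSet,
    pred_b: PredictionSet,
    n_boot: int = 2000,
    n_perm: int = 5000,
    n_sim: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
    statistic: str = "mean_difference",
) -> ComparisonReport:
    """Full paired comparison of two models scored on identical patients."""
    if pred_a.patient_ids != pred_b.patient_ids:
        raise ValueError("prediction sets must cover identical patients in order")
    if not np.array_equal(pred_a.labels, pred_b.labels):
        raise ValueError("prediction sets disagree on labels")

    a, b, y = pred_a.scores, pred_b.scores, pred_a.labels
    ss = np.random.SeedSequence(seed).spawn(3)
    boot_seed, perm_seed, pow_seed = (int(s.generate_state(1)[0] % 2**31) for s in ss)

    ci_a, ci_b, delta = paired_bootstrap_auc(a, b, y, n_boot=n_boot, seed=boot_seed)
    p = paired_permutation_test(a, b, n_perm=n_perm, seed=perm_seed,
                                statistic=statistic, labels=y)
    d_val, d_sign = cohens_d_paired(a, b)

    diffs = a - b
    sd = diffs.std(ddof=1)
    if sd > 0:
        power = power_parametric_mc(diffs.mean(), sd, n=len(diffs), alpha=alpha,
                                    n_sim=n_sim, seed=pow_seed)
    else:
        power = float("nan")

    report = ComparisonReport(
        auc_a=roc_auc(pred_a), auc_b=roc_auc(pred_b),
        ci_a=ci_a, ci_b=ci_b,
        delta_observed=float(diffs.mean()) if statistic == "mean_difference"
        else float(roc_auc(pred_a) - roc_auc(pred_b)),
        p_permutation=p, cohen_d=d_val, cohen_d_sign=d_sign, power=power,
        n_bootstrap=n_boot, n_permutation=n_perm,
    )
    report.validate()
    return report
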