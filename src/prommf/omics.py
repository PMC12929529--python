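"""Gene-expression preprocessing and differential-expression screening.

The molecular feature vector fed to the classifiers is built in three steps,
all fitted on the training split only:

1. counts -> TPM (or CPM when gene lengths are unavailable),
2. log2(x + 1) then per-gene z-scoring with training-split moments,
3. a differential-expression screen keeping genes with |logFC| > 2 (strict)
   and p < 0.05 (nominal, no multiplicity correction — the screen selects
   candidate features for the model, not a biological gene set).

The per-gene test is a pluggable stand-in (Welch t-test on log2
library-size-normalised counts by default, Wilcoxon rank-sum as an
alternative); a DEG list computed externally can be imported instead.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "DEGRecord",
    "counts_to_tpm",
    "counts_to_cpm",
    "log_z_normalize",
    "differential_expression",
    "select_degs",
    "OmicsFeaturizer",
    "read_counts",
    "write_counts",
    "write_deg_table",
    "read_deg_table",
]

_STAGES = ("counts", "tpm", "log_tpm", "zscore")
DE_METHODS = ("welch", "wilcoxon")


@dataclass
class ExpressionMatrix:
    """Gene-by-patient matrix tagged with its processing stage."""

    values: pd.DataFrame  # genes x patients
    stage: str = "counts"

    def __post_init__(self):
        if self.stage not in _STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {_STAGES}")

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.values.index]

    @property
    def patient_ids(self) -> list[str]:
        return [str(p) for p in self.values.columns]

    def _require_stage(self, stage: str) -> None:
        if self.stage != stage:
            raise ValueError(f"expected a {stage!r}-stage matrix, got {self.stage!r}")


@dataclass(frozen=True)
class DEGRecord:
    """One gene's screening result: MSI-vs-MSS log2 fold change and p-value."""

    gene_id: str
    logFC: float
    p_value: float
    direction: str = "ns"


def counts_to_tpm(counts: ExpressionMatrix, gene_lengths: np.ndarray) -> ExpressionMatrix:
    """Transcripts per million: length-normalise, then scale columns to 1e6."""
    counts._require_stage("counts")
    lengths = np.asarray(gene_lengths, dtype=float)
    if lengths.shape[0] != counts.values.shape[0]:
        raise ValueError(
            f"gene_lengths has {lengths.shape[0]} entries for "
            f"{counts.values.shape[0]} genes"
        )
    if np.any(lengths <= 0):
        raise ValueError("gene lengths must be positive")
    col_sums = counts.values.sum(axis=0)
    if (col_sums == 0).any():
        bad = list(col_sums.index[col_sums == 0])
        raise ValueError(f"all-zero count columns (TPM undefined): {bad}")
    rate = counts.values.div(lengths, axis=0)
    tpm = rate.div(rate.sum(axis=0), axis=1) * 1e6
    return ExpressionMatrix(tpm, stage="tpm")


def counts_to_cpm(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Counts per million — the fallback when gene lengths are unavailable."""
    counts._require_stage("counts")
    col_sums = counts.values.sum(axis=0)
    if (col_sums == 0).any():
        raise ValueError("all-zero count columns (CPM undefined)")
    logger.warning("no gene lengths supplied; using CPM in place of TPM")
    cpm = counts.values.div(col_sums, axis=1) * 1e6
    return ExpressionMatrix(cpm, stage="tpm")


def log_z_normalize(tpm: ExpressionMatrix, fit_patients: list[str]) -> ExpressionMatrix:
    """log2(x+1) then per-gene z-score with moments from ``fit_patients`` only.

    Genes with zero variance on the fit set are set to 0 everywhere and
    listed in the returned matrix's ``zero_variance_genes`` attribute.
    """
    tpm._require_stage("tpm")
    fit = [p for p in fit_patients if p in tpm.values.columns]
    if not fit:
        raise ValueError("fit_patients is disjoint from the matrix columns")
    logged = np.log2(tpm.values + 1.0)
    mu = logged[fit].mean(axis=1)
    sd = logged[fit].std(axis=1, ddof=0)
    flat = sd == 0
    sd_safe = sd.mask(flat, 1.0)
    z = logged.sub(mu, axis=0).div(sd_safe, axis=0)
    z[flat] = 0.0
    out = ExpressionMatrix(z, stage="zscore")
    out.zero_variance_genes = [str(g) for g in z.index[flat]]
    out.fit_patient_ids = list(fit)
    out.fit_mean = mu
    out.fit_sd = sd_safe
    return out


def _libsize_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Scale each column to the median library size."""
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("all-zero count columns")
    return counts.div(lib, axis=1) * float(lib.median())


def differential_expression(
    counts: ExpressionMatrix,
    groups: np.ndarray,
    method: str = "welch",
    pseudocount: float = 1.0,
) -> list[DEGRecord]:
    """Per-gene MSI-vs-MSS screen on library-size-normalised counts.

    logFC = log2((mean_pos + pc) / (mean_neg + pc)); the p-value comes from
    the chosen two-sample statistic on log2(normalised + pc) values. Genes
    with zero counts everywhere get logFC 0 and p 1 by convention.
    """
    counts._require_stage("counts")
    if method not in DE_METHODS:
        raise ValueError(f"unknown method {method!r}; available: {DE_METHODS}")
    y = np.asarray(groups, dtype=int)
    if y.shape[0] != counts.values.shape[1]:
        raise ValueError("groups length must match the number of patients")
    if y.sum() == 0 or y.sum() == y.shape[0]:
        raise ValueError("both groups must be non-empty")

    norm = _libsize_normalize(counts.values)
    pos = norm.loc[:, y == 1].to_numpy()
    neg = norm.loc[:, y == 0].to_numpy()
    logfc = np.log2((pos.mean(axis=1) + pseudocount) / (neg.mean(axis=1) + pseudocount))

    lpos = np.log2(pos + pseudocount)
    lneg = np.log2(neg + pseudocount)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant genes produce nan p-values
        if method == "welch":
            _, pvals = stats.ttest_ind(lpos, lneg, axis=1, equal_var=False)
        else:
            res = stats.mannwhitneyu(lpos, lneg, axis=1, alternative="two-sided")
            pvals = res.pvalue
    pvals = np.where(np.isfinite(pvals), pvals, 1.0)

    all_zero = (pos.sum(axis=1) + neg.sum(axis=1)) == 0
    logfc = np.where(all_zero, 0.0, logfc)
    pvals = np.where(all_zero, 1.0, pvals)

    return [
        DEGRecord(gene_id=str(g), logFC=float(fc), p_value=float(p))
        for g, fc, p in zip(counts.values.index, logfc, pvals)
    ]


def _with_direction(r: DEGRecord, lfc: float, p: float) -> DEGRecord:
    if r.logFC > lfc and r.p_value < p:
        d = "up"
    elif r.logFC < -lfc and r.p_value < p:
        d = "down"
    else:
        d = "ns"
    return DEGRecord(r.gene_id, r.logFC, r.p_value, d)


def select_degs(
    records: list[DEGRecord],
    lfc_threshold: float = 2.0,
    p_threshold: float = 0.05,
) -> tuple[list[DEGRecord], list[DEGRecord]]:
    """Strict-threshold screen: |logFC| > lfc and p < p_threshold.

    Returns (up, down), each sorted by p ascending then |logFC| descending.
    """
    if lfc_threshold <= 0 or p_threshold <= 0:
        raise ValueError("thresholds must be positive")
    tagged = [_with_direction(r, lfc_threshold, p_threshold) for r in records]
    key = lambda r: (r.p_value, -abs(r.logFC))  # noqa: E731
    up = sorted([r for r in tagged if r.direction == "up"], key=key)
    down = sorted([r for r in tagged if r.direction == "down"], key=key)
    if records and not up and not down:
        warnings.warn(
            "DEG screen selected no genes at the configured thresholds; "
            "consider the top-k fallback", stacklevel=2
        )
    return up, down


class OmicsFeaturizer(BaseEstimator, TransformerMixin):
    """Counts -> DEG-indexed z-score features, fitted on training patients only.

    sklearn-style transformer. ``fit`` receives the full gene-by-patient
    count matrix plus the labels and ids of the *training* patients; all
    normalisation moments and the DEG selection are estimated from those
    patients alone, and ``transform`` applies the frozen state to any
    patient subset (anti-leakage by construction).

    Parameters
    ----------
    lfc_threshold, p_threshold : the DEG screen thresholds (strict |logFC| >
        lfc and p < p_threshold).
    method : per-gene two-sample statistic, "welch" or "wilcoxon".
    fallback_top_k : if the screen selects nothing, keep this many genes by
        smallest p-value instead (0 disables the fallback).
    """

    def __init__(
        self,
        lfc_threshold: float = 2.0,
        p_threshold: float = 0.05,
        method: str = "welch",
        pseudocount: float = 1.0,
        fallback_top_k: int = 32,
        deg_genes: list[str] | None = None,
    ):
        self.lfc_threshold = lfc_threshold
        self.p_threshold = p_threshold
        self.method = method
        self.pseudocount = pseudocount
        self.fallback_top_k = fallback_top_k
        self.deg_genes = deg_genes

    def fit(self, counts: ExpressionMatrix, y: np.ndarray,
            gene_lengths: np.ndarray | None = None,
            fit_patients: list[str] | None = None) -> "OmicsFeaturizer":
        counts._require_stage("counts")
        fit_ids = list(fit_patients) if fit_patients is not None else counts.patient_ids
        y = np.asarray(y, dtype=int)
        if y.shape[0] != len(fit_ids):
            raise ValueError("y must align with fit_patients")

        train_counts = ExpressionMatrix(counts.values[fit_ids], stage="counts")
        if self.deg_genes is not None:
            selected = [g for g in self.deg_genes if g in counts.gene_ids]
            self.deg_records_ = None
            self.up_, self.down_ = [], []
        else:
            recs = differential_expression(
                train_counts, y, method=self.method, pseudocount=self.pseudocount
            )
            up, down = select_degs(recs, self.lfc_threshold, self.p_threshold)
            if not up and not down and self.fallback_top_k > 0:
                recs_sorted = sorted(recs, key=lambda r: r.p_value)
                selected = [r.gene_id for r in recs_sorted[: self.fallback_top_k]]
                logger.warning(
                    "empty DEG selection; falling back to top %d genes by p-value",
                    self.fallback_top_k,
                )
            else:
                selected = [r.gene_id for r in up + down]
            self.deg_records_ = recs
            self.up_, self.down_ = up, down

        if gene_lengths is not None:
            tpm = counts_to_tpm(counts, gene_lengths)
        else:
            tpm = counts_to_cpm(counts)
        z = log_z_normalize(tpm, fit_ids)

        self.feature_genes_ = selected
        self.fit_patient_ids_ = fit_ids
        self._z = z  # frozen full-matrix z-scores (moments from fit split only)
        self.n_features_out_ = len(selected)
        return self

    def transform(self, patient_ids: list[str]) -> np.ndarray:
        """Patient-by-feature matrix of DEG-indexed z-scores."""
        if not hasattr(self, "feature_genes_"):
            raise RuntimeError("OmicsFeaturizer is not fitted")
        z = self._z.values.loc[self.feature_genes_, list(patient_ids)]
        return z.to_numpy().T.astype(np.float64)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_counts(path: str | Path, sep: str | None = None) -> ExpressionMatrix:
    """Read a gene-by-patient count matrix (TSV/CSV; first column gene_id)."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    return ExpressionMatrix(df, stage="counts")


def write_counts(em: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    out = em.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep=sep)


def write_deg_table(records: list[DEGRecord], path: str | Path) -> None:
    pd.DataFrame(
        [{"gene_id": r.gene_id, "logFC": r.logFC, "p_value": r.p_value,
          "direction": r.direction} for r in records]
    ).to_csv(path, sep="\t", index=False)


def read_deg_table(path: str | Path) -> list[DEGRecord]:
    """Import a DEG table computed externally (e.g. by DESeq2)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "logFC", "p_value"}
    if not required.issubset(df.columns):
        raise ValueError(f"DEG table must have columns {sorted(required)}")
    return [
        DEGRecord(str(r.gene_id), float(r.logFC), float(r.p_value),
                  str(getattr(r, "direction", "ns")))
        for r in df.itertuples(index=False)
    ]
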