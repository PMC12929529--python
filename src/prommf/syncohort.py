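"""Synthetic multimodal cohorts: paired histology tile-embedding bags and
RNA-seq style counts with a planted MSI/MSS signal.

The generator emulates the statistical structure the classifiers and the
AUC-comparison statistics assume, so the whole pipeline is testable without
access to patient data:

* binary labels drawn at a configurable prevalence (default 0.22, the
  approximate MSI fraction in stomach adenocarcinoma);
* a gene-by-patient count matrix with negative-binomial noise
  (variance = mu + mu^2 * dispersion) and a block of planted up/down
  differentially expressed genes at a configurable log2 fold change;
* per-patient bags of tile embeddings of variable size, in which only a
  minority of tiles in positive patients carry class signal (the standard
  multiple-instance assumption) while every other tile is isotropic Gaussian
  background;
* a ``modality_balance`` knob that moves the planted class signal between
  the image and the expression modality (1.0 = image only, 0.0 = genes only,
  0.5 = the stated effect sizes apply to both).

Everything is driven by a single integer seed; identical spec + seed gives a
bit-identical cohort.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtri

__all__ = [
    "SyntheticSpec",
    "PatientRecord",
    "Cohort",
    "generate_cohort",
    "generate_score_pairs",
    "write_cohort",
    "read_cohort",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Study-design parameters of a synthetic multimodal cohort."""

    n_patients: int = 300
    prevalence: float = 0.22
    n_genes: int = 2000
    n_de_up: int = 30
    n_de_down: int = 30
    de_logfc: float = 2.5
    nb_dispersion: float = 0.4
    gene_length_range: tuple[int, int] = (500, 5000)
    bag_size_range: tuple[int, int] = (10, 40)
    informative_fraction: float = 0.3
    image_effect: float = 2.5
    signal_dim: int = 16
    modality_balance: float = 0.5
    embedding_dim: int = 2048
    with_metadata: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.n_de_up + self.n_de_down > self.n_genes:
            raise ValueError("n_de_up + n_de_down must not exceed n_genes")
        for name in ("prevalence", "informative_fraction", "modality_balance"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.bag_size_range[0] < 1 or self.bag_size_range[0] > self.bag_size_range[1]:
            raise ValueError(f"invalid bag_size_range {self.bag_size_range}")
        if not 1 <= self.signal_dim <= self.embedding_dim:
            raise ValueError("signal_dim must lie in [1, embedding_dim]")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.gene_length_range[0] <= 0:
            raise ValueError("gene lengths must be positive")


@dataclass
class PatientRecord:
    """One patient: a bag of tile embeddings, a count vector and a label."""

    patient_id: str
    label: int  # 1 = MSI (positive), 0 = MSS
    tile_features: np.ndarray  # (M_i, embedding_dim)
    gene_counts: np.ndarray  # (n_genes,) non-negative integers
    metadata: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        if self.tile_features.ndim != 2 or self.tile_features.shape[0] < 1:
            raise ValueError(f"{self.patient_id}: tile bag must be a non-empty matrix")
        if not np.all(np.isfinite(self.tile_features)):
            raise ValueError(f"{self.patient_id}: non-finite tile features")
        if np.any(self.gene_counts < 0) or not np.issubdtype(self.gene_counts.dtype, np.integer):
            raise ValueError(f"{self.patient_id}: counts must be non-negative integers")

    @property
    def n_tiles(self) -> int:
        return self.tile_features.shape[0]


@dataclass
class Cohort:
    """A list of patients sharing one gene index."""

    records: list[PatientRecord]
    gene_ids: list[str]
    gene_lengths: np.ndarray | None = None
    generating_spec: SyntheticSpec | None = None

    def validate(self) -> None:
        ids = [r.patient_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate patient_ids")
        for r in self.records:
            r.validate()
            if r.gene_counts.shape[0] != len(self.gene_ids):
                raise ValueError(f"{r.patient_id}: count vector length mismatch")

    @property
    def patient_ids(self) -> list[str]:
        return [r.patient_id for r in self.records]

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=int)

    @property
    def total_instances(self) -> int:
        return sum(r.n_tiles for r in self.records)

    def counts_frame(self) -> pd.DataFrame:
        """Gene-by-patient raw count matrix."""
        mat = np.column_stack([r.gene_counts for r in self.records])
        return pd.DataFrame(mat, index=self.gene_ids, columns=self.patient_ids)

    def record(self, patient_id: str) -> PatientRecord:
        for r in self.records:
            if r.patient_id == patient_id:
                return r
        raise KeyError(patient_id)


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial draws in the mean/dispersion parameterisation.

    variance = mu + mu^2 * dispersion; dispersion 0 degenerates to Poisson.
    Sampled as a gamma-Poisson mixture.
    """
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def generate_cohort(spec: SyntheticSpec) -> Cohort:
    """Draw one cohort from ``spec``; identical spec+seed is bit-identical."""
    spec.validate()
    if spec.n_patients < 10:
        raise ValueError("n_patients must be >= 10 for a usable cohort")
    expected_pos = spec.n_patients * spec.prevalence
    if expected_pos < 2 or spec.n_patients - expected_pos < 2:
        raise ValueError(
            "spec leaves one class expected (near-)empty; "
            "increase n_patients or move prevalence away from 0/1"
        )

    rng = np.random.default_rng(spec.seed)

    # --- shared structure -------------------------------------------------
    labels = (rng.random(spec.n_patients) < spec.prevalence).astype(int)
    gene_ids = [f"G{g:05d}" for g in range(spec.n_genes)]
    gene_lengths = rng.integers(
        spec.gene_length_range[0], spec.gene_length_range[1] + 1, size=spec.n_genes
    )
    # per-gene baseline means span orders of magnitude, as in RNA-seq
    base_mean = np.exp(rng.normal(3.0, 1.5, size=spec.n_genes))
    de_up = np.arange(spec.n_de_up)
    de_down = np.arange(spec.n_de_up, spec.n_de_up + spec.n_de_down)
    # planted DE genes sit on moderately expressed baselines: a fold-change
    # screen can only ever detect adequately expressed genes
    n_de = spec.n_de_up + spec.n_de_down
    if n_de:
        base_mean[:n_de] = np.exp(rng.normal(4.0, 0.5, size=n_de))

    # modality_balance splits the planted signal: 0.5 leaves the stated
    # magnitudes untouched on both sides; 1.0 silences the genes, 0.0 the images
    gene_scale = 2.0 * (1.0 - spec.modality_balance)
    image_scale = 2.0 * spec.modality_balance
    lfc = spec.de_logfc * gene_scale
    shift = spec.image_effect * image_scale

    # fixed orthonormal signal directions in embedding space; informative
    # tiles are all shifted by the same composite vector of total magnitude
    # image_effect spread evenly across the signal_dim directions
    basis = rng.normal(size=(spec.embedding_dim, spec.signal_dim))
    q, _ = np.linalg.qr(basis)
    directions = q.T  # (signal_dim, embedding_dim), orthonormal rows
    signal_vector = directions.sum(axis=0) / np.sqrt(spec.signal_dim)  # unit norm

    records: list[PatientRecord] = []
    for i in range(spec.n_patients):
        pid = f"P{i:04d}"
        y = int(labels[i])

        # ---- expression -------------------------------------------------
        mu = base_mean.copy()
        if y == 1:
            mu[de_up] *= 2.0 ** lfc
            mu[de_down] *= 2.0 ** (-lfc)
        size_factor = np.exp(rng.normal(0.0, 0.25))  # library-size variation
        counts = _nb_counts(rng, mu * size_factor, spec.nb_dispersion)

        # ---- histology bag ----------------------------------------------
        m_i = int(rng.integers(spec.bag_size_range[0], spec.bag_size_range[1] + 1))
        tiles = rng.normal(size=(m_i, spec.embedding_dim))
        if y == 1:
            n_informative = rng.binomial(m_i, spec.informative_fraction)
            if n_informative > 0:
                which = rng.choice(m_i, size=n_informative, replace=False)
                tiles[which] += shift * signal_vector

        meta: dict[str, str] = {}
        if spec.with_metadata:
            meta["stage_group"] = "early" if rng.random() < 0.5 else "late"
            meta["prior_treatment"] = "treated" if rng.random() < 0.5 else "naive"

        records.append(
            PatientRecord(
                patient_id=pid,
                label=y,
                tile_features=tiles,
                gene_counts=counts.astype(np.int64),
                metadata=meta,
            )
        )

    cohort = Cohort(
        records=records,
        gene_ids=gene_ids,
        gene_lengths=gene_lengths.astype(np.int64),
        generating_spec=spec,
    )
    cohort.validate()
    return cohort


def recovery_spec(effects: str = "moderate", seed: int = 0) -> SyntheticSpec:
    """Named study conditions for the scaled-down multimodal recovery study.

    Both profiles use a 300-patient cohort at 22% prevalence with the class
    signal split evenly across modalities (modality_balance = 0.5) and a
    reduced embedding width / bag size so a full training run stays cheap on
    one CPU. ``moderate`` plants a sparse, noisy expression signal (4 up / 4
    down genes at logFC 2.3 under heavy NB dispersion) and a mid-sized image
    shift, so each unimodal classifier is clearly sub-ceiling and fusion has
    headroom; ``strong`` plants an abundant, clean signal in both modalities.
    """
    common = dict(n_patients=300, prevalence=0.22, n_genes=2000,
                  modality_balance=0.5, signal_dim=8, embedding_dim=128,
                  bag_size_range=(6, 16), seed=seed)
    if effects == "moderate":
        return SyntheticSpec(n_de_up=4, n_de_down=4, de_logfc=2.3,
                             nb_dispersion=3.0, informative_fraction=0.3,
                             image_effect=4.0, **common)
    if effects == "strong":
        return SyntheticSpec(n_de_up=30, n_de_down=30, de_logfc=3.0,
                             nb_dispersion=0.5, informative_fraction=0.4,
                             image_effect=6.0, **common)
    raise ValueError(f"unknown effects profile {effects!r}")


def generate_score_pairs(
    n: int,
    auc_a: float,
    auc_b: float,
    pairing_corr: float = 0.5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Paired model scores from a binormal model with known population AUCs.

    Both score vectors are ``mu * y + noise`` with unit-variance Gaussian
    noise shared across the pair at correlation ``pairing_corr``; the
    binormal identity AUC = Phi(mu / sqrt(2)) fixes ``mu`` from the target.
    With ``auc_a == auc_b`` the construction is exchangeable between models,
    so the paired permutation null holds exactly.
    """
    if n < 10:
        raise ValueError("n must be >= 10")
    for auc in (auc_a, auc_b):
        if not 0.5 <= auc <= 1.0:
            raise ValueError("target AUCs must lie in [0.5, 1.0]")
    if not 0.0 <= pairing_corr <= 1.0:
        raise ValueError("pairing_corr must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    n_pos = n // 2
    if n_pos == 0 or n - n_pos == 0:
        raise ValueError("degenerate n: one class would be empty")
    labels = np.zeros(n, dtype=int)
    labels[rng.choice(n, size=n_pos, replace=False)] = 1

    def _mu(auc: float) -> float:
        if auc >= 1.0:
            return np.inf
        return float(np.sqrt(2.0) * ndtri(auc))

    shared = rng.normal(size=n)
    eps_a = rng.normal(size=n)
    eps_b = rng.normal(size=n)
    rho = pairing_corr
    noise_a = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * eps_a
    noise_b = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * eps_b

    def _scores(mu: float, noise: np.ndarray) -> np.ndarray:
        if np.isinf(mu):
            # zero-overlap limit: classes separated far beyond the noise scale
            return labels * 1e6 + noise
        return mu * labels + noise

    return _scores(_mu(auc_a), noise_a), _scores(_mu(auc_b), noise_b), labels


# ---------------------------------------------------------------------------
# on-disk format: manifest CSV + counts TSV + tile features (HDF5 or CSV dir)
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, out_dir: str | Path, features: str = "hdf5") -> Path:
    """Write manifest.csv, counts.tsv, gene_lengths.tsv and the tile bags."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    meta_keys = sorted({k for r in cohort.records for k in r.metadata})
    rows = []
    for r in cohort.records:
        row = {"patient_id": r.patient_id, "label": r.label, "n_tiles": r.n_tiles}
        row.update({k: r.metadata.get(k, "") for k in meta_keys})
        rows.append(row)
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)

    counts = cohort.counts_frame()
    counts.index.name = "gene_id"
    counts.to_csv(out / "counts.tsv", sep="\t")

    if cohort.gene_lengths is not None:
        pd.DataFrame(
            {"gene_id": cohort.gene_ids, "length": cohort.gene_lengths}
        ).to_csv(out / "gene_lengths.tsv", sep="\t", index=False)

    if features == "hdf5":
        import h5py

        with h5py.File(out / "features.h5", "w") as f:
            for r in cohort.records:
                f.create_dataset(r.patient_id, data=r.tile_features)
    elif features == "csv":
        fdir = out / "features"
        fdir.mkdir(exist_ok=True)
        for r in cohort.records:
            np.savetxt(fdir / f"{r.patient_id}.csv", r.tile_features, delimiter=",")
    else:
        raise ValueError(f"unknown feature container {features!r} (hdf5 or csv)")
    return out


def read_cohort(in_dir: str | Path) -> Cohort:
    """Read a cohort written by :func:`write_cohort`."""
    src = Path(in_dir)
    manifest = pd.read_csv(src / "manifest.csv", dtype={"patient_id": str})
    counts = pd.read_csv(src / "counts.tsv", sep="\t", index_col="gene_id")
    gene_ids = [str(g) for g in counts.index]

    gene_lengths = None
    if (src / "gene_lengths.tsv").exists():
        gl = pd.read_csv(src / "gene_lengths.tsv", sep="\t")
        gl = gl.set_index("gene_id").reindex(gene_ids)
        gene_lengths = gl["length"].to_numpy(dtype=np.int64)

    h5_path = src / "features.h5"
    csv_dir = src / "features"

    def _load_tiles(pid: str) -> np.ndarray:
        if h5_path.exists():
            import h5py

            with h5py.File(h5_path, "r") as f:
                return np.asarray(f[pid])
        if csv_dir.exists():
            return np.atleast_2d(np.loadtxt(csv_dir / f"{pid}.csv", delimiter=","))
        raise FileNotFoundError(f"no tile-feature container found under {src}")

    meta_cols = [c for c in manifest.columns if c not in ("patient_id", "label", "n_tiles")]
    records = []
    for _, row in manifest.iterrows():
        pid = str(row["patient_id"])
        records.append(
            PatientRecord(
                patient_id=pid,
                label=int(row["label"]),
                tile_features=_load_tiles(pid),
                gene_counts=counts[pid].to_numpy(dtype=np.int64),
                metadata={c: str(row[c]) for c in meta_cols if pd.notna(row[c])},
            )
        )
    cohort = Cohort(records=records, gene_ids=gene_ids, gene_lengths=gene_lengths)
    cohort.validate()
    return cohort


def spec_to_dict(spec: SyntheticSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["gene_length_range"] = list(d["gene_length_range"])
    d["bag_size_range"] = list(d["bag_size_range"])
    return d


def spec_from_dict(d: dict) -> SyntheticSpec:
    d = dict(d)
    for key in ("gene_length_range", "bag_size_range"):
        if key in d:
            d[key] = tuple(d[key])
    known = {f.name for f in dataclasses.fields(SyntheticSpec)}
    unknown = set(d) - known
    if unknown:
        warnings.warn(f"ignoring unknown synthetic-spec fields: {sorted(unknown)}")
    return SyntheticSpec(**{k: v for k, v in d.items() if k in known})
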