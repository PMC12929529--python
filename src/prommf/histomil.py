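"""Gated attention-based multiple-instance pooling of tile embeddings.

A patient is a bag of tile embeddings (one 2048-d vector per tile, as
produced by the global-average-pool layer of a 50-layer residual backbone).
Each instance is projected to 512 dimensions, scored by a gated attention
head — ``w^T (tanh(V h) * sigm(U h))`` — normalised over the bag with a
softmax, and the bag is pooled to a single patient vector as the attention-
weighted sum of instance projections. Only the pooling is learned here; the
image backbone is an optional plugin, never required.

Two parallel surfaces are provided: plain-NumPy functions over a frozen
:class:`GatedAttentionParams` (used for inspection and contract tests) and
the differentiable :class:`GatedAttentionPooling` module used in training.
Both compute the same map; the test suite checks them against each other.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from ._tensor import Tensor
from .nn import Module

__all__ = [
    "GatedAttentionParams",
    "BagEmbedding",
    "embed_tiles",
    "project_instances",
    "gated_attention_scores",
    "attention_pool",
    "GatedAttentionPooling",
    "register_backbone",
    "read_tile_features",
    "export_attention_weights",
]

_BACKBONE: Callable[[np.ndarray], np.ndarray] | None = None


def register_backbone(fn: Callable[[np.ndarray], np.ndarray] | None) -> None:
    """Register (or clear, with None) an image-embedding plugin.

    The plugin maps a batch of raw tiles to an (M, 2048) embedding matrix;
    nothing in this package requires one to be present.
    """
    global _BACKBONE
    _BACKBONE = fn


@dataclass
class GatedAttentionParams:
    """Frozen weights of the projection + gated attention head.

    V_a, U_a : (L, proj_dim) gate branches; w_a : (L,) scoring vector;
    proj_W : (proj_dim, in_dim) and proj_b : (proj_dim,) instance projection.
    """

    V_a: np.ndarray
    U_a: np.ndarray
    w_a: np.ndarray
    proj_W: np.ndarray
    proj_b: np.ndarray

    def validate(self) -> None:
        L, p = self.V_a.shape
        if self.U_a.shape != (L, p) or self.w_a.shape != (L,):
            raise ValueError("inconsistent attention shapes")
        if self.proj_W.shape[0] != p or self.proj_b.shape != (p,):
            raise ValueError("inconsistent projection shapes")
        for a in (self.V_a, self.U_a, self.w_a, self.proj_W, self.proj_b):
            if not np.all(np.isfinite(a)):
                raise ValueError("non-finite attention parameters")


@dataclass
class BagEmbedding:
    """Projected instances H, attention weights A, pooled patient vector."""

    H: np.ndarray  # (M_i, proj_dim)
    A: np.ndarray  # (M_i,), non-negative, sums to 1
    h_patient: np.ndarray  # (proj_dim,)

    def validate(self, atol: float = 1e-6) -> None:
        if np.any(self.A < 0) or abs(self.A.sum() - 1.0) > atol:
            raise ValueError("attention weights must be a point on the simplex")
        if not np.allclose(self.h_patient, self.A @ self.H, atol=1e-8):
            raise ValueError("h_patient must equal A^T H")


def embed_tiles(tiles: np.ndarray, expected_dim: int = 2048) -> np.ndarray:
    """Validate precomputed embeddings, or run the registered backbone.

    2-d input of width ``expected_dim`` is treated as precomputed embeddings
    and passed through after shape/finiteness checks; anything else requires
    a registered backbone plugin.
    """
    tiles = np.asarray(tiles)
    if tiles.ndim == 2 and tiles.shape[1] == expected_dim:
        if not np.all(np.isfinite(tiles)):
            raise ValueError("tile embeddings contain non-finite values")
        return tiles
    if tiles.ndim == 2:
        raise ValueError(
            f"expected precomputed embeddings of width {expected_dim}, "
            f"got width {tiles.shape[1]}"
        )
    if _BACKBONE is None:
        raise RuntimeError(
            "raw tiles supplied but no backbone is registered; "
            "register one with prommf.histomil.register_backbone"
        )
    out = np.asarray(_BACKBONE(tiles))
    return embed_tiles(out, expected_dim=expected_dim)


def project_instances(features: np.ndarray, params: GatedAttentionParams) -> np.ndarray:
    """Affine per-instance map to the projection space: H = X W^T + b."""
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[1] != params.proj_W.shape[1]:
        raise ValueError(
            f"features must be (M, {params.proj_W.shape[1]}), got {features.shape}"
        )
    return features @ params.proj_W.T + params.proj_b


def gated_attention_scores(H: np.ndarray, params: GatedAttentionParams) -> np.ndarray:
    """Softmax-normalised gated attention over one bag.

    logit_m = w^T (tanh(V h_m) * sigm(U h_m)); the softmax subtracts the
    max logit for overflow safety.
    """
    H = np.asarray(H, dtype=float)
    if H.ndim != 2 or H.shape[0] < 1:
        raise ValueError("H must be a non-empty instance matrix")
    gate = np.tanh(H @ params.V_a.T) * _sigm(H @ params.U_a.T)
    logits = gate @ params.w_a
    z = logits - logits.max()
    e = np.exp(z)
    return e / e.sum()


def _sigm(x: np.ndarray) -> np.ndarray:
    e = np.exp(-np.abs(x))
    return np.where(x >= 0, 1.0 / (1.0 + e), e / (1.0 + e))


def attention_pool(A: np.ndarray, H: np.ndarray) -> np.ndarray:
    """h_patient = sum_m a_m h_m; A must already be on the simplex."""
    A = np.asarray(A, dtype=float)
    H = np.asarray(H, dtype=float)
    if np.any(A < 0) or abs(A.sum() - 1.0) > 1e-6:
        raise ValueError("attention weights must be non-negative and sum to 1")
    return A @ H


def pool_bag(features: np.ndarray, params: GatedAttentionParams) -> BagEmbedding:
    """Full bag pipeline: project, score, pool."""
    H = project_instances(features, params)
    A = gated_attention_scores(H, params)
    return BagEmbedding(H=H, A=A, h_patient=attention_pool(A, H))


class GatedAttentionPooling(Module):
    """Differentiable projection + gated attention pooling (training path)."""

    def __init__(
        self,
        in_dim: int = 2048,
        proj_dim: int = 512,
        attn_dim: int = 256,
        dropout: float = 0.1,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.in_dim, self.proj_dim, self.attn_dim = in_dim, proj_dim, attn_dim
        self.dropout = dropout
        self.proj = self.add_linear("proj", in_dim, proj_dim, rng)
        # gate branches carry no bias, matching the usual gated-attention form
        from .nn import kaiming_uniform

        self.params["attn.V"] = Tensor(kaiming_uniform(rng, proj_dim, (attn_dim, proj_dim)),
                                       requires_grad=True)
        self.params["attn.U"] = Tensor(kaiming_uniform(rng, proj_dim, (attn_dim, proj_dim)),
                                       requires_grad=True)
        self.params["attn.w"] = Tensor(kaiming_uniform(rng, attn_dim, (attn_dim,)),
                                       requires_grad=True)

    def forward(self, features: np.ndarray, rng: np.random.Generator) -> tuple[Tensor, Tensor, Tensor]:
        """Return (H, A, h_patient) as graph tensors for one bag."""
        x = Tensor(embed_tiles(features, expected_dim=self.in_dim))
        H = self.proj(x)
        Hd = H.dropout(self.dropout, rng, self.training)
        V, U, w = self.params["attn.V"], self.params["attn.U"], self.params["attn.w"]
        gate = (Hd @ _t(V)).tanh() * (Hd @ _t(U)).sigmoid()
        logits = gate @ w
        A = logits.softmax()
        h_patient = A @ Hd
        return H, A, h_patient

    def export_params(self) -> GatedAttentionParams:
        """Snapshot the trained weights into the frozen NumPy container."""
        p = GatedAttentionParams(
            V_a=self.params["attn.V"].data.copy(),
            U_a=self.params["attn.U"].data.copy(),
            w_a=self.params["attn.w"].data.copy(),
            proj_W=self.params["proj.weight"].data.copy(),
            proj_b=self.params["proj.bias"].data.copy(),
        )
        p.validate()
        return p


def _t(t: Tensor) -> Tensor:
    from .nn import _transpose

    return _transpose(t)


def read_tile_features(container: str | Path, patient_id: str) -> np.ndarray:
    """Read one patient's bag from the HDF5 (or CSV-directory) container."""
    container = Path(container)
    if container.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(container, "r") as f:
            if patient_id not in f:
                raise KeyError(f"{patient_id} not in {container}")
            return np.asarray(f[patient_id])
    csv = container / f"{patient_id}.csv"
    if csv.exists():
        return np.atleast_2d(np.loadtxt(csv, delimiter=","))
    raise FileNotFoundError(f"no features for {patient_id} under {container}")


def export_attention_weights(A: np.ndarray, path: str | Path) -> None:
    """Write per-tile attention weights as CSV (tile_index, attention)."""
    pd.DataFrame({"tile_index": np.arange(len(A)), "attention": A}).to_csv(
        path, index=False
    )
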