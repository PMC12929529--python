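"""Classifier heads: unimodal AMIL and DMLP, late fusion, intermediate
multimodal fusion (MMF) and its progressive back-projection variant (ProMMF).

The fusion core works on two 32-d unimodal features — the attention-pooled
histology vector after a linear + ReLU head, and the DEG-indexed expression
vector after an MLP. Two fusion operators are supported:

* ``kron``  — each unimodal vector is augmented with a trailing 1 and the
  fused vector is the row-major flattening of their outer product, a
  33 x 33 rank-1 matrix whose last column carries the (augmented) histology
  vector and last row the (augmented) expression vector, so unimodal
  information survives fusion intact;
* ``concat`` — plain concatenation, histology block first.

Progressive fusion re-projects the fused vector back into each unimodal
space through two learned affine maps, adds these context vectors to the
original unimodal features, and fuses again; the refinement is unrolled for
T iterations (1–5, default 2) with back-projection weights shared across
iterations by default. With all back-projection parameters at zero the
progressive model reduces exactly to single-pass MMF.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._tensor import Tensor, concat
from .histomil import GatedAttentionPooling
from .nn import Module

__all__ = [
    "FusionConfig",
    "FusionState",
    "kron_fuse",
    "concat_fuse",
    "late_fusion",
    "unimodal_heads",
    "back_project",
    "progressive_fuse",
    "classify",
    "dmlp_forward",
    "DMLPNet",
    "AMILNet",
    "FusionNet",
    "MODEL_REGISTRY",
    "build_model",
]


@dataclass(frozen=True)
class FusionConfig:
    """Architecture of the fusion stage and classifier head."""

    mode: str = "kron"  # "kron" or "concat"
    progressive: bool = True
    iterations: int = 2
    unimodal_dim: int = 32
    dropout: float = 0.1
    classifier_hidden: int = 64
    share_backprojection_weights: bool = True
    late_fusion_weight: float = 0.5
    omic_hidden: int = 128
    proj_dim: int = 512
    attn_dim: int = 256

    def validate(self) -> None:
        if self.mode not in ("kron", "concat"):
            raise ValueError(f"mode must be 'kron' or 'concat', got {self.mode!r}")
        if self.progressive and not 1 <= self.iterations <= 5:
            raise ValueError("iterations must lie in 1..5")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if not 0.0 <= self.late_fusion_weight <= 1.0:
            raise ValueError("late_fusion_weight must lie in [0, 1]")

    @property
    def fusion_dim(self) -> int:
        d = self.unimodal_dim
        return (d + 1) ** 2 if self.mode == "kron" else 2 * d


@dataclass
class FusionState:
    """Snapshot of one fusion pass (for inspection and tests)."""

    h_histology: np.ndarray
    h_omic: np.ndarray
    h_fusion: np.ndarray
    hhat_histology: np.ndarray | None = None
    hhat_omic: np.ndarray | None = None
    iteration: int = 0


# ---------------------------------------------------------------------------
# functional fusion operators (NumPy reference surface)
# ---------------------------------------------------------------------------

def kron_fuse(h_histology: np.ndarray, h_omic: np.ndarray) -> np.ndarray:
    """Unit-augmented Kronecker fusion.

    Returns the row-major flattening of [h_histology; 1] [h_omic; 1]^T, a
    (d1+1)(d2+1) vector. Row i < d1 carries h_histology[i] * [h_omic; 1];
    the last row is [h_omic, 1] and the last column is [h_histology, 1].
    """
    h = np.append(np.asarray(h_histology, dtype=float), 1.0)
    g = np.append(np.asarray(h_omic, dtype=float), 1.0)
    if not (np.all(np.isfinite(h)) and np.all(np.isfinite(g))):
        raise ValueError("non-finite fusion inputs")
    return np.outer(h, g).reshape(-1)


def concat_fuse(h_histology: np.ndarray, h_omic: np.ndarray) -> np.ndarray:
    """Plain concatenation, histology block first."""
    return np.concatenate([np.asarray(h_histology, float), np.asarray(h_omic, float)])


def late_fusion(p_image: float, p_omic: float, w: float = 0.5) -> float:
    """Decision-level fusion: w * p_image + (1 - w) * p_omic."""
    if not 0.0 <= w <= 1.0:
        raise ValueError("late-fusion weight must lie in [0, 1]")
    for p in (p_image, p_omic):
        if not 0.0 <= p <= 1.0:
            raise ValueError("late fusion expects probabilities in [0, 1]")
    return w * p_image + (1.0 - w) * p_omic


# ---------------------------------------------------------------------------
# network modules
# ---------------------------------------------------------------------------

class ClassifierHead(Module):
    """hidden (ReLU, dropout) -> sigmoid scalar."""

    def __init__(self, in_dim: int, hidden: int, dropout: float, rng: np.random.Generator):
        super().__init__()
        self.dropout = dropout
        self.fc1 = self.add_linear("fc1", in_dim, hidden, rng)
        self.fc2 = self.add_linear("fc2", hidden, 1, rng)

    def logit(self, x: Tensor, rng: np.random.Generator) -> Tensor:
        h = self.fc1(x).relu().dropout(self.dropout, rng, self.training)
        return self.fc2(h).reshape(())


class DMLPNet(Module):
    """Expression-only classifier: MLP over the DEG-indexed z-score vector."""

    def __init__(self, in_dim: int, hidden: tuple[int, int] = (128, 32),
                 dropout: float = 0.1, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.in_dim = in_dim
        self.dropout = dropout
        self.fc1 = self.add_linear("fc1", in_dim, hidden[0], rng)
        self.fc2 = self.add_linear("fc2", hidden[0], hidden[1], rng)
        self.fc3 = self.add_linear("fc3", hidden[1], 1, rng)

    def logit(self, omic: np.ndarray | Tensor, rng: np.random.Generator) -> Tensor:
        x = omic if isinstance(omic, Tensor) else Tensor(np.asarray(omic, float))
        h = self.fc1(x).relu().dropout(self.dropout, rng, self.training)
        h = self.fc2(h).relu().dropout(self.dropout, rng, self.training)
        return self.fc3(h).reshape(())


class AMILNet(Module):
    """Image-only classifier: gated attention pooling + classifier head."""

    def __init__(self, in_dim: int = 2048, proj_dim: int = 512, attn_dim: int = 256,
                 classifier_hidden: int = 64, dropout: float = 0.1,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.mil = self.add_module(
            "mil", GatedAttentionPooling(in_dim, proj_dim, attn_dim, dropout, rng)
        )
        self.head = self.add_module(
            "head", ClassifierHead(proj_dim, classifier_hidden, dropout, rng)
        )

    def logit(self, bag: np.ndarray, rng: np.random.Generator) -> Tensor:
        _, _, h_patient = self.mil.forward(bag, rng)
        return self.head.logit(h_patient, rng)

    def attention(self, bag: np.ndarray) -> np.ndarray:
        was = self.training
        self.eval()
        _, A, _ = self.mil.forward(bag, np.random.default_rng(0))
        if was:
            self.train()
        return A.data


def _fuse_tensors(h: Tensor, g: Tensor, mode: str) -> Tensor:
    if mode == "kron":
        one = Tensor(np.ones(1))
        return concat([h, one]).outer(concat([g, one])).reshape(-1)
    return concat([h, g])


class FusionNet(Module):
    """Intermediate multimodal fusion (MMF / ProMMF, Kronecker or concat)."""

    def __init__(self, omic_dim: int, config: FusionConfig | None = None,
                 in_dim: int = 2048, rng: np.random.Generator | None = None):
        super().__init__()
        config = config if config is not None else FusionConfig()
        config.validate()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.config = config
        self.omic_dim = omic_dim
        d = config.unimodal_dim

        self.mil = self.add_module(
            "mil", GatedAttentionPooling(in_dim, config.proj_dim, config.attn_dim,
                                         config.dropout, rng)
        )
        self.img_head = self.add_linear("img_head", config.proj_dim, d, rng)
        self.omic_fc1 = self.add_linear("omic_fc1", omic_dim, config.omic_hidden, rng)
        self.omic_fc2 = self.add_linear("omic_fc2", config.omic_hidden, d, rng)

        if config.progressive:
            n_sets = 1 if config.share_backprojection_weights else config.iterations
            self.backproj = []
            for t in range(n_sets):
                bp_img = self.add_linear(f"backproj_img{t}", config.fusion_dim, d, rng)
                bp_om = self.add_linear(f"backproj_omic{t}", config.fusion_dim, d, rng)
                # start at zero: the first forward pass is exactly single-pass
                # MMF and the refinement is learned from there
                for layer in (bp_img, bp_om):
                    layer.weight.data[:] = 0.0
                    layer.bias.data[:] = 0.0
                self.backproj.append((bp_img, bp_om))
        else:
            self.backproj = []

        self.head = self.add_module(
            "head", ClassifierHead(config.fusion_dim, config.classifier_hidden,
                                   config.dropout, rng)
        )

    # -- forward -------------------------------------------------------------

    def _unimodal(self, bag: np.ndarray, omic: np.ndarray,
                  rng: np.random.Generator) -> tuple[Tensor, Tensor]:
        omic = np.asarray(omic, dtype=float)
        if omic.shape != (self.omic_dim,):
            raise ValueError(
                f"omic feature vector must have length {self.omic_dim} "
                f"(the selected DEG union), got {omic.shape}"
            )
        _, _, h_patient = self.mil.forward(bag, rng)
        h_hist = self.img_head(h_patient).relu()
        x = Tensor(omic)
        h = self.omic_fc1(x).relu().dropout(self.config.dropout, rng, self.training)
        h_om = self.omic_fc2(h).relu()
        return h_hist, h_om

    def _progressive(self, h_hist: Tensor, h_om: Tensor,
                     states: list[FusionState] | None = None) -> Tensor:
        cfg = self.config
        f = _fuse_tensors(h_hist, h_om, cfg.mode)
        if states is not None:
            states.append(FusionState(h_hist.data.copy(), h_om.data.copy(),
                                      f.data.copy(), iteration=0))
        if not cfg.progressive:
            return f
        for t in range(1, cfg.iterations + 1):
            bp_img, bp_om = self.backproj[0 if cfg.share_backprojection_weights
                                          else t - 1]
            hhat = bp_img(f)
            ghat = bp_om(f)
            h_t = h_hist + hhat
            g_t = h_om + ghat
            f = _fuse_tensors(h_t, g_t, cfg.mode)
            if states is not None:
                states.append(FusionState(h_t.data.copy(), g_t.data.copy(),
                                          f.data.copy(), hhat.data.copy(),
                                          ghat.data.copy(), iteration=t))
        return f

    def logit(self, bag: np.ndarray, omic: np.ndarray,
              rng: np.random.Generator) -> Tensor:
        h_hist, h_om = self._unimodal(bag, omic, rng)
        f = self._progressive(h_hist, h_om)
        return self.head.logit(f, rng)

    def forward_states(self, bag: np.ndarray, omic: np.ndarray) -> list[FusionState]:
        """Eval-mode trace of every fusion iteration (no dropout)."""
        was = self.training
        self.eval()
        rng = np.random.default_rng(0)
        h_hist, h_om = self._unimodal(bag, omic, rng)
        states: list[FusionState] = []
        self._progressive(h_hist, h_om, states)
        if was:
            self.train()
        return states


# ---------------------------------------------------------------------------
# functional wrappers over trained modules (eval mode, no dropout)
# ---------------------------------------------------------------------------

def _eval_call(module: Module, fn):
    was = module.training
    module.eval()
    try:
        return fn()
    finally:
        if was:
            module.train()


def unimodal_heads(h_patient: np.ndarray, omic_features: np.ndarray,
                   net: FusionNet) -> tuple[np.ndarray, np.ndarray]:
    """The two 32-d post-ReLU unimodal features, from a pooled patient vector."""
    omic_features = np.asarray(omic_features, float)
    if omic_features.shape != (net.omic_dim,):
        raise ValueError(f"omic vector must have length {net.omic_dim}")

    def run():
        rng = np.random.default_rng(0)
        h_hist = net.img_head(Tensor(np.asarray(h_patient, float))).relu()
        h = net.omic_fc1(Tensor(omic_features)).relu()
        h_om = net.omic_fc2(h).relu()
        return h_hist.data.copy(), h_om.data.copy()

    return _eval_call(net, run)


def back_project(h_fusion: np.ndarray, net: FusionNet,
                 iteration: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Affine maps from fusion space back to the two 32-d unimodal spaces."""
    if not net.config.progressive:
        raise ValueError("back-projection requires a progressive fusion config")
    bp_img, bp_om = net.backproj[0 if net.config.share_backprojection_weights
                                 else iteration - 1]
    f = Tensor(np.asarray(h_fusion, float))
    return bp_img(f).data.copy(), bp_om(f).data.copy()


def progressive_fuse(h_histology: np.ndarray, h_omic: np.ndarray,
                     net: FusionNet) -> np.ndarray:
    """Run the configured fusion (with back-projection refinement) to f^T."""

    def run():
        f = net._progressive(Tensor(np.asarray(h_histology, float)),
                             Tensor(np.asarray(h_omic, float)))
        return f.data.copy()

    return _eval_call(net, run)


def classify(h_fusion: np.ndarray, net: FusionNet) -> float:
    """Classifier head probability for a fused vector (eval mode)."""

    def run():
        rng = np.random.default_rng(0)
        z = net.head.logit(Tensor(np.asarray(h_fusion, float)), rng)
        return float(z.sigmoid().data)

    return _eval_call(net, run)


def dmlp_forward(omic_features: np.ndarray, net: DMLPNet) -> float:
    """DMLP probability for one expression feature vector (eval mode)."""

    def run():
        rng = np.random.default_rng(0)
        return float(net.logit(np.asarray(omic_features, float), rng).sigmoid().data)

    return _eval_call(net, run)


# ---------------------------------------------------------------------------
# model registry
# ---------------------------------------------------------------------------

def _fusion_builder(mode: str, progressive: bool):
    def build(omic_dim: int, in_dim: int, config: FusionConfig,
              rng: np.random.Generator) -> FusionNet:
        cfg = replace(config, mode=mode, progressive=progressive)
        return FusionNet(omic_dim=omic_dim, config=cfg, in_dim=in_dim, rng=rng)

    return build


def _amil_builder(omic_dim: int, in_dim: int, config: FusionConfig,
                  rng: np.random.Generator) -> AMILNet:
    return AMILNet(in_dim=in_dim, proj_dim=config.proj_dim, attn_dim=config.attn_dim,
                   classifier_hidden=config.classifier_hidden,
                   dropout=config.dropout, rng=rng)


def _dmlp_builder(omic_dim: int, in_dim: int, config: FusionConfig,
                  rng: np.random.Generator) -> DMLPNet:
    return DMLPNet(in_dim=omic_dim, dropout=config.dropout, rng=rng)


MODEL_REGISTRY = {
    "AMIL": _amil_builder,
    "DMLP": _dmlp_builder,
    "LateFusion": "late",  # composed from the two unimodal models in training
    "MMF_Kron": _fusion_builder("kron", progressive=False),
    "MMF_Con": _fusion_builder("concat", progressive=False),
    "ProMMF_Kron": _fusion_builder("kron", progressive=True),
    "ProMMF_Con": _fusion_builder("concat", progressive=True),
}


def build_model(name: str, omic_dim: int, in_dim: int = 2048,
                config: FusionConfig | None = None,
                rng: np.random.Generator | None = None):
    """Instantiate a registered model by its registry name."""
    if name not in MODEL_REGISTRY:
        raise KeyError(f"unknown model {name!r}; available: {sorted(MODEL_REGISTRY)}")
    if name == "LateFusion":
        raise ValueError("LateFusion is composed from AMIL and DMLP at training time")
    config = config if config is not None else FusionConfig()
    rng = rng if rng is not None else np.random.default_rng(0)
    return MODEL_REGISTRY[name](omic_dim, in_dim, config, rng)
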