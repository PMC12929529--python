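"""sklearn-style classifiers over the MIL / fusion networks.

All estimators follow scikit-learn conventions — constructor parameters are
stored verbatim, ``get_params``/``set_params`` work, fitted state carries a
trailing underscore — but the image-bearing models accept *ragged* input
(a list of per-patient tile-embedding matrices), so they compose with
sklearn model selection only at the patient level.

Training follows one protocol throughout: Adam (lr 1e-4, weight decay 5e-3),
binary cross-entropy on the logit, batch size 1 with a fresh random patient
order per epoch, optional per-step tile subsampling, dropout 0.1, and (when
a validation set is supplied) checkpointing on the best validation AUC.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score

from .fusionnet import AMILNet, DMLPNet, FusionConfig, FusionNet, late_fusion
from .nn import Adam, bce_with_logits

__all__ = [
    "DMLPClassifier",
    "AMILClassifier",
    "MMFClassifier",
    "LateFusionClassifier",
]


def _as_bags(X) -> list[np.ndarray]:
    bags = [np.asarray(b, dtype=float) for b in X]
    for i, b in enumerate(bags):
        if b.ndim != 2 or b.shape[0] < 1:
            raise ValueError(f"bag {i} must be a non-empty 2-d matrix")
        if not np.all(np.isfinite(b)):
            raise ValueError(f"bag {i} contains non-finite values")
    return bags


def _check_y(y, n: int) -> np.ndarray:
    y = np.asarray(y, dtype=int)
    if y.shape != (n,):
        raise ValueError(f"y must have shape ({n},)")
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1 (1 = MSI)")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    return y


class _NetClassifierBase(BaseEstimator, ClassifierMixin):
    """Shared Adam/BCE training loop; subclasses define data access + net."""

    def _build_net(self, X, rng):  # pragma: no cover - abstract
        raise NotImplementedError

    def _example(self, X, i):  # returns the i-th training example
        raise NotImplementedError

    def _logit(self, net, example, rng):
        raise NotImplementedError

    def _n(self, X) -> int:
        raise NotImplementedError

    def _subsample(self, bag: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        cap = getattr(self, "max_tiles", None)
        if cap is not None and bag.shape[0] > cap:
            idx = rng.choice(bag.shape[0], size=cap, replace=False)
            return bag[idx]
        return bag

    def fit(self, X, y, validation=None):
        """Train; ``validation=(X_val, y_val)`` enables best-AUC checkpointing."""
        n = self._n(X)
        y = _check_y(y, n)
        self.classes_ = np.array([0, 1])

        ss = np.random.SeedSequence(self.seed)
        init_seed, train_seed = ss.spawn(2)
        rng_init = np.random.default_rng(init_seed)
        rng = np.random.default_rng(train_seed)

        net = self._build_net(X, rng_init)
        opt = Adam(net.params, lr=self.learning_rate,
                   weight_decay=self.weight_decay)

        loss_history, val_history = [], []
        best_auc, best_state, best_epoch = -np.inf, None, None
        for epoch in range(self.epochs):
            net.train()
            order = rng.permutation(n)
            losses = np.empty(n)
            for j, i in enumerate(order):
                net.zero_grad()
                z = self._logit(net, self._example(X, int(i)), rng)
                loss = bce_with_logits(z, float(y[i]))
                loss.backward()
                opt.step()
                losses[j] = loss.item()
            epoch_loss = float(losses.mean())
            if not np.isfinite(epoch_loss):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            loss_history.append(epoch_loss)
            if validation is not None:
                Xv, yv = validation
                p = self._predict_with(net, Xv)
                auc = roc_auc_score(np.asarray(yv, int), p)
                val_history.append(float(auc))
                if auc > best_auc:
                    best_auc, best_epoch = float(auc), epoch
                    best_state = net.state_dict()

        if best_state is not None:
            net.load_state_dict(best_state)
        net.eval()
        self.net_ = net
        self.loss_history_ = loss_history
        self.val_auc_history_ = val_history
        self.best_epoch_ = best_epoch
        self.best_val_auc_ = best_auc if validation is not None else None
        return self

    def _predict_with(self, net, X) -> np.ndarray:
        was = net.training
        net.eval()
        rng = np.random.default_rng(0)  # dropout is off in eval mode
        n = self._n(X)
        out = np.empty(n)
        for i in range(n):
            z = self._logit(net, self._example(X, i), rng)
            out[i] = float(z.sigmoid().data)
        if was:
            net.train()
        return out

    def predict_proba(self, X) -> np.ndarray:
        if not hasattr(self, "net_"):
            raise RuntimeError("estimator is not fitted")
        p = self._predict_with(self.net_, X)
        return np.column_stack([1.0 - p, p])

    def decision_function(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1]

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


class DMLPClassifier(_NetClassifierBase):
    """Expression-only MLP classifier on DEG-indexed z-score features."""

    def __init__(self, hidden=(128, 32), dropout=0.1, learning_rate=1e-4,
                 weight_decay=5e-3, epochs=100, seed=0):
        self.hidden = hidden
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.epochs = epochs
        self.seed = seed

    def _n(self, X):
        return np.asarray(X).shape[0]

    def _build_net(self, X, rng):
        X = np.asarray(X, dtype=float)
        self.n_features_in_ = X.shape[1]
        return DMLPNet(in_dim=X.shape[1], hidden=tuple(self.hidden),
                       dropout=self.dropout, rng=rng)

    def _example(self, X, i):
        return np.asarray(X, dtype=float)[i]

    def _logit(self, net, example, rng):
        return net.logit(example, rng)


class AMILClassifier(_NetClassifierBase):
    """Image-only classifier: gated attention MIL over tile-embedding bags.

    ``X`` is a list of (M_i, embedding_dim) matrices, one bag per patient.
    """

    def __init__(self, embedding_dim=2048, proj_dim=512, attn_dim=256,
                 classifier_hidden=64, dropout=0.1, learning_rate=1e-4,
                 weight_decay=5e-3, epochs=100, max_tiles=None, seed=0):
        self.embedding_dim = embedding_dim
        self.proj_dim = proj_dim
        self.attn_dim = attn_dim
        self.classifier_hidden = classifier_hidden
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.epochs = epochs
        self.max_tiles = max_tiles
        self.seed = seed

    def _n(self, X):
        return len(X)

    def _build_net(self, X, rng):
        bags = _as_bags(X)
        if bags[0].shape[1] != self.embedding_dim:
            raise ValueError(
                f"bags have width {bags[0].shape[1]}, expected {self.embedding_dim}"
            )
        return AMILNet(in_dim=self.embedding_dim, proj_dim=self.proj_dim,
                       attn_dim=self.attn_dim,
                       classifier_hidden=self.classifier_hidden,
                       dropout=self.dropout, rng=rng)

    def _example(self, X, i):
        return np.asarray(X[i], dtype=float)

    def _logit(self, net, example, rng):
        return net.logit(self._subsample(example, rng), rng)

    def attention_weights(self, bag: np.ndarray) -> np.ndarray:
        """Per-tile attention of the fitted model on one bag."""
        if not hasattr(self, "net_"):
            raise RuntimeError("estimator is not fitted")
        return self.net_.attention(np.asarray(bag, dtype=float))


class MMFClassifier(_NetClassifierBase):
    """Intermediate multimodal fusion classifier (MMF / ProMMF).

    ``X`` is a pair ``(bags, omics)``: a list of tile-embedding matrices and
    an aligned (n_patients, n_deg_features) expression feature matrix.
    ``mode`` selects Kronecker or concatenation fusion; ``progressive``
    enables back-projection refinement with ``iterations`` cycles.
    """

    def __init__(self, mode="kron", progressive=True, iterations=2,
                 unimodal_dim=32, classifier_hidden=64, omic_hidden=128,
                 share_backprojection_weights=True, embedding_dim=2048,
                 proj_dim=512, attn_dim=256, dropout=0.1, learning_rate=1e-4,
                 weight_decay=5e-3, epochs=100, max_tiles=None, seed=0):
        self.mode = mode
        self.progressive = progressive
        self.iterations = iterations
        self.unimodal_dim = unimodal_dim
        self.classifier_hidden = classifier_hidden
        self.omic_hidden = omic_hidden
        self.share_backprojection_weights = share_backprojection_weights
        self.embedding_dim = embedding_dim
        self.proj_dim = proj_dim
        self.attn_dim = attn_dim
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.epochs = epochs
        self.max_tiles = max_tiles
        self.seed = seed

    def _fusion_config(self) -> FusionConfig:
        return FusionConfig(
            mode=self.mode, progressive=self.progressive,
            iterations=self.iterations, unimodal_dim=self.unimodal_dim,
            dropout=self.dropout, classifier_hidden=self.classifier_hidden,
            share_backprojection_weights=self.share_backprojection_weights,
            omic_hidden=self.omic_hidden, proj_dim=self.proj_dim,
            attn_dim=self.attn_dim,
        )

    @staticmethod
    def _unpack(X):
        bags, omics = X
        bags = _as_bags(bags)
        omics = np.asarray(omics, dtype=float)
        if omics.ndim != 2 or omics.shape[0] != len(bags):
            raise ValueError("omics matrix must align with the bag list")
        return bags, omics

    def _n(self, X):
        bags, _ = X
        return len(bags)

    def _build_net(self, X, rng):
        bags, omics = self._unpack(X)
        if bags[0].shape[1] != self.embedding_dim:
            raise ValueError(
                f"bags have width {bags[0].shape[1]}, expected {self.embedding_dim}"
            )
        self.n_omic_features_in_ = omics.shape[1]
        cfg = self._fusion_config()
        cfg.validate()
        return FusionNet(omic_dim=omics.shape[1], config=cfg,
                         in_dim=self.embedding_dim, rng=rng)

    def _example(self, X, i):
        bags, omics = X
        return np.asarray(bags[i], dtype=float), np.asarray(omics, dtype=float)[i]

    def _logit(self, net, example, rng):
        bag, omic = example
        return net.logit(self._subsample(bag, rng), omic, rng)

    def fusion_states(self, bag, omic):
        """Eval-mode trace of the fusion iterations for one patient."""
        if not hasattr(self, "net_"):
            raise RuntimeError("estimator is not fitted")
        return self.net_.forward_states(np.asarray(bag, float),
                                        np.asarray(omic, float))


class LateFusionClassifier(BaseEstimator, ClassifierMixin):
    """Decision-level fusion of the two unimodal classifiers.

    Trains an AMIL model on the bags and a DMLP on the expression features,
    then combines their probabilities as ``w * p_image + (1 - w) * p_omic``.
    With ``weight='auto'`` the weight is tuned on the validation split by an
    AUC grid search; otherwise the fixed weight is used.
    """

    def __init__(self, weight=0.5, embedding_dim=2048, dropout=0.1,
                 learning_rate=1e-4, weight_decay=5e-3, epochs=100,
                 max_tiles=None, seed=0):
        self.weight = weight
        self.embedding_dim = embedding_dim
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.epochs = epochs
        self.max_tiles = max_tiles
        self.seed = seed

    def fit(self, X, y, validation=None):
        bags, omics = X
        y = _check_y(y, len(bags))
        self.classes_ = np.array([0, 1])
        common = dict(dropout=self.dropout, learning_rate=self.learning_rate,
                      weight_decay=self.weight_decay, epochs=self.epochs,
                      seed=self.seed)
        self.image_model_ = AMILClassifier(
            embedding_dim=self.embedding_dim, max_tiles=self.max_tiles, **common
        )
        self.omic_model_ = DMLPClassifier(**common)

        val_img = val_om = None
        if validation is not None:
            (vb, vo), yv = validation
            val_img, val_om = (vb, np.asarray(yv, int)), (vo, np.asarray(yv, int))
        self.image_model_.fit(bags, y, validation=val_img)
        self.omic_model_.fit(omics, y, validation=val_om)

        if self.weight == "auto":
            if validation is None:
                raise ValueError("weight='auto' requires a validation set")
            (vb, vo), yv = validation
            p_img = self.image_model_.predict_proba(vb)[:, 1]
            p_om = self.omic_model_.predict_proba(vo)[:, 1]
            grid = np.linspace(0.0, 1.0, 21)
            aucs = [roc_auc_score(yv, w * p_img + (1 - w) * p_om) for w in grid]
            self.weight_ = float(grid[int(np.argmax(aucs))])
        else:
            if not 0.0 <= float(self.weight) <= 1.0:
                raise ValueError("late-fusion weight must lie in [0, 1]")
            self.weight_ = float(self.weight)
        return self

    def predict_proba(self, X):
        bags, omics = X
        p_img = self.image_model_.predict_proba(bags)[:, 1]
        p_om = self.omic_model_.predict_proba(omics)[:, 1]
        p = np.array([late_fusion(a, b, self.weight_) for a, b in zip(p_img, p_om)])
        return np.column_stack([1.0 - p, p])

    def decision_function(self, X):
        return self.predict_proba(X)[:, 1]

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)
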