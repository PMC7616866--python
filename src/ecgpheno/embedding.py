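"""Diagnosis classifier and embedding extractor over preprocessed ECGs.

The model is a residual 1-D CNN trained with independent per-label binary
cross-entropy on the six rhythm/conduction diagnoses.  Removing the final
classification layer exposes the flattened penultimate activations; under
the default architecture that is a 5120-dimensional embedding (16 temporal
steps x 320 filters), which downstream modules cluster into phenogroups.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.metrics import roc_auc_score

from ._nn import (ArchConfig, ECGResNet, TrainConfig, resolve_arch)
from .synthetic import DIAGNOSES

__all__ = ["ECGEmbedder", "build_model", "extract_embeddings"]


def build_model(arch: ArchConfig | str = "default", seed: int = 0) -> ECGResNet:
    """Instantiate the network; ``net.embedding_dim`` reports the
    penultimate feature count (5120 under the default configuration)."""
    return ECGResNet(resolve_arch(arch), seed=seed)


def extract_embeddings(net: ECGResNet, signals: np.ndarray,
                       batch_size: int = 64) -> np.ndarray:
    """Penultimate feature vectors for a batch of (n, 12, 4096) tensors.

    Inference-mode (running batch-norm statistics), hence deterministic for
    fixed weights.
    """
    signals = np.asarray(signals, dtype=np.float32)
    if signals.ndim == 2:
        signals = signals[None]
    out = [net.embed(signals[i:i + batch_size])
           for i in range(0, signals.shape[0], batch_size)]
    return np.concatenate(out, axis=0)


class ECGEmbedder(TransformerMixin, BaseEstimator):
    """sklearn-style wrapper: ``fit`` trains the diagnosis head,
    ``transform`` returns embeddings, ``predict_proba`` the six sigmoids.

    Parameters
    ----------
    arch : ArchConfig or preset name ("default", "desk", "hires", "tiny")
    epochs, batch_size, learning_rate, val_fraction : training settings
    random_state : seeds weight initialization, shuffling and the split
    """

    def __init__(self, arch="desk", epochs: int = 10, batch_size: int = 32,
                 learning_rate: float = 1e-3, val_fraction: float = 0.2,
                 random_state: int = 0):
        self.arch = arch
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.val_fraction = val_fraction
        self.random_state = random_state

    # ------------------------------------------------------------------

    def fit(self, X, y=None):
        """Train on (n, 12, 4096) signals and (n, 6) binary labels.

        With ``y=None`` or ``epochs=0`` the network keeps its seeded initial
        weights (useful for shape introspection and untrained baselines).
        Label columns with a single class in the training split are excluded
        from the loss and get a NaN validation AUROC.
        """
        X = np.asarray(X, dtype=np.float32)
        arch = resolve_arch(self.arch)
        self.arch_ = arch
        self.net_ = ECGResNet(arch, seed=self.random_state)
        self.n_features_out_ = arch.embedding_dim
        self.auroc_ = {}
        if y is None or self.epochs == 0:
            return self

        y = np.asarray(y, dtype=np.float32)
        if y.ndim != 2 or y.shape[1] != arch.n_outputs:
            raise ValueError(
                f"y must be (n, {arch.n_outputs}) binary labels")
        rng = np.random.default_rng(self.random_state)
        n = X.shape[0]
        order = rng.permutation(n)
        n_val = max(1, int(round(self.val_fraction * n)))
        val_idx, train_idx = order[:n_val], order[n_val:]

        label_mask = np.array(
            [len(np.unique(y[train_idx, j])) > 1 for j in range(y.shape[1])],
            dtype=np.float32)
        cfg = TrainConfig(epochs=self.epochs, batch_size=self.batch_size,
                          learning_rate=self.learning_rate,
                          val_fraction=self.val_fraction,
                          seed=self.random_state)
        self.loss_history_ = self.net_.fit(X[train_idx], y[train_idx], cfg,
                                           label_mask=label_mask)
        probs = self._predict_proba_batched(X[val_idx])
        names = (DIAGNOSES if y.shape[1] == len(DIAGNOSES)
                 else [f"label_{j}" for j in range(y.shape[1])])
        for j, name in enumerate(names):
            col = y[val_idx, j]
            if label_mask[j] and len(np.unique(col)) > 1:
                self.auroc_[name] = float(roc_auc_score(col, probs[:, j]))
            else:
                self.auroc_[name] = float("nan")
        return self

    def _predict_proba_batched(self, X, batch_size: int = 64) -> np.ndarray:
        out = [self.net_.predict_proba(X[i:i + batch_size])
               for i in range(0, X.shape[0], batch_size)]
        return np.concatenate(out, axis=0)

    def transform(self, X) -> np.ndarray:
        """Embeddings, shape (n, embedding_dim)."""
        self._check_fitted()
        return extract_embeddings(self.net_, np.asarray(X, dtype=np.float32))

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        return self._predict_proba_batched(np.asarray(X, dtype=np.float32))

    def _check_fitted(self) -> None:
        if not hasattr(self, "net_"):
            raise RuntimeError("ECGEmbedder is not fitted; call fit() first")

    # ------------------------------------------------------------------

    def save(self, path: str) -> None:
        self._check_fitted()
        self.net_.save(path)

    @classmethod
    def load(cls, path: str) -> "ECGEmbedder":
        net = ECGResNet.load(path)
        est = cls(arch=net.arch, epochs=0)
        est.net_ = net
        est.arch_ = net.arch
        est.n_features_out_ = net.embedding_dim
        est.auroc_ = {}
        return est
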