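"""Attention-based multiple-instance learning for the WSI-level call.

Each slide is one bag of ROI embeddings with a single binary label per
lesion line. The bag is pooled with gated attention

    a_i = softmax_i( w^T ( tanh(V h_i) * sigmoid(U h_i) ) )
    z   = sum_i a_i h_i

and a linear head with sigmoid yields the slide probability. Attention
weights are nonnegative, sum to one, and rank the ROIs for the overlay.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from ._nn import (Adam, CosineAnnealing, Dense, Module, Tensor,
                  bce_with_logits, softmax)
from .metrics import roc_auc


class _GatedAttentionNet(Module):
    def __init__(self, rng, in_dim: int, hidden_dim: int):
        self.V = Dense(rng, in_dim, hidden_dim)
        self.U = Dense(rng, in_dim, hidden_dim)
        self.w = Dense(rng, hidden_dim, 1)
        self.head = Dense(rng, in_dim, 1)

    def pool(self, h: Tensor) -> tuple[Tensor, Tensor]:
        """h: (n, d) -> (bag vector (1, d), attention (n,))."""
        gate = self.V(h).tanh() * self.U(h).sigmoid()
        scores = self.w(gate).reshape(-1)          # (n,)
        a = softmax(scores, axis=0)
        z = (a.reshape(-1, 1) * h).sum(axis=0, keepdims=True)
        return z, a

    def forward(self, h: Tensor) -> tuple[Tensor, Tensor]:
        z, a = self.pool(h)
        return self.head(z).reshape(-1), a


class AttentionMILClassifier(BaseEstimator, ClassifierMixin):
    """Gated-attention MIL slide classifier for one lesion line."""

    def __init__(self, hidden_dim: int = 64, epochs: int = 30,
                 lr: float = 5e-3, wsi_threshold: float = 0.5,
                 lesion_line: str = "mel", n_restarts: int = 3,
                 random_state: int = 0):
        self.hidden_dim = hidden_dim
        self.epochs = epochs
        self.lr = lr
        self.wsi_threshold = wsi_threshold
        self.lesion_line = lesion_line
        self.n_restarts = n_restarts
        self.random_state = random_state

    _init_state: dict | None = None

    def fit(self, bags: list[np.ndarray], labels: np.ndarray,
            splits: list[str] | None = None):
        """Fit with random restarts, keeping the best validation metric.

        The small gated-attention net is bistable on some draws; a few
        restarts from different initializations select a run that
        generalizes. A warm start (``_init_state``) uses one run.
        """
        restarts = 1 if self._init_state is not None else max(1, self.n_restarts)
        cands = []
        for r in range(restarts):
            clone = AttentionMILClassifier(
                hidden_dim=self.hidden_dim, epochs=self.epochs, lr=self.lr,
                wsi_threshold=self.wsi_threshold, lesion_line=self.lesion_line,
                n_restarts=1, random_state=self.random_state + 1000 * r)
            clone._init_state = self._init_state
            clone._fit_once(bags, labels, splits)
            cands.append(clone)
        best = max(cands, key=lambda c: c._score_)
        self.net_ = best.net_
        self.history_ = best.history_
        self.best_epoch_ = best.best_epoch_
        self.val_auc_ = best.val_auc_
        self._score_ = best._score_
        return self

    def _fit_once(self, bags: list[np.ndarray], labels: np.ndarray,
                  splits: list[str] | None = None):
        labels = np.asarray(labels, dtype=float)
        if splits is None:
            splits = ["train"] * len(bags)
        splits = np.asarray(splits)
        tr = np.flatnonzero(splits == "train")
        va = np.flatnonzero(splits == "val")
        if len(np.unique(labels[tr])) < 2:
            raise ValueError("training bags must contain both classes")
        d = bags[0].shape[1]
        rng = np.random.default_rng(self.random_state)
        self.net_ = _GatedAttentionNet(rng, d, self.hidden_dim)
        if self._init_state is not None:
            self.net_.load_state_dict(self._init_state)
        opt = Adam(self.net_.parameters(), lr=self.lr)
        sched = CosineAnnealing(opt, self.epochs)
        self.history_ = []

        def val_metrics():
            if not len(va):
                return np.nan, np.nan
            probs = np.array([self._prob(bags[i]) for i in va])
            _, auc = roc_auc(probs, labels[va].astype(int))
            eps = 1e-12
            bce = float(-np.mean(
                labels[va] * np.log(probs + eps)
                + (1 - labels[va]) * np.log(1 - probs + eps)))
            return auc, bce

        def score_of(val_auc, val_bce, train_loss):
            if len(va) and np.isfinite(val_auc):
                return (1, val_auc, -val_bce)
            if len(va) and np.isfinite(val_bce):
                return (0, -val_bce, 0.0)
            return (0, -train_loss, 0.0)

        best = (None, None, -1, np.nan)
        if self._init_state is not None:
            auc0, bce0 = val_metrics()
            best = (score_of(auc0, bce0, np.inf),
                    self.net_.state_dict(), -1, auc0)
        for epoch in range(self.epochs):
            rng.shuffle(tr)
            losses = []
            for i in tr:                      # one bag per step (1 bag/WSI)
                logit, _ = self.net_.forward(Tensor(bags[i]))
                loss = bce_with_logits(logit, np.array([labels[i]]))
                self.net_.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            sched.step()
            val_auc, val_bce = val_metrics()
            self.history_.append({"epoch": epoch,
                                  "loss": float(np.mean(losses)),
                                  "val_auc": float(val_auc),
                                  "val_loss": float(val_bce)})
            score = score_of(val_auc, val_bce, float(np.mean(losses)))
            if best[0] is None or score > best[0]:
                best = (score, self.net_.state_dict(), epoch, val_auc)
        self.net_.load_state_dict(best[1])
        self.best_epoch_ = best[2]
        self._score_ = best[0]
        self.val_auc_ = float(best[3])
        return self

    def _prob(self, bag: np.ndarray) -> float:
        logit, _ = self.net_.forward(Tensor(np.asarray(bag, dtype=float)))
        return float(1.0 / (1.0 + np.exp(-logit.data[0])))

    def attention_pool(self, bag: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(bag vector, attention weights) for one bag of embeddings."""
        bag = np.asarray(bag, dtype=float)
        if bag.ndim != 2 or bag.shape[0] < 1:
            raise ValueError("bag must be a nonempty (n, d) matrix")
        z, a = self.net_.pool(Tensor(bag))
        return z.data[0], a.data

    def predict_wsi(self, bag: np.ndarray,
                    threshold: float | None = None
                    ) -> tuple[float, bool, np.ndarray]:
        """(probability, binary call, attention weights) for one slide.

        The call uses probability >= threshold (default 0.5).
        """
        if not hasattr(self, "net_"):
            raise RuntimeError("MIL classifier is not fitted")
        bag = np.asarray(bag, dtype=float)
        if bag.ndim != 2 or bag.shape[0] < 1:
            raise ValueError("bag must be a nonempty (n, d) matrix")
        thr = self.wsi_threshold if threshold is None else threshold
        logit, a = self.net_.forward(Tensor(bag))
        prob = float(1.0 / (1.0 + np.exp(-logit.data[0])))
        return prob, prob >= thr, a.data

    def predict_proba(self, bags: list[np.ndarray]) -> np.ndarray:
        return np.array([self._prob(b) for b in bags])

    def predict(self, bags: list[np.ndarray]) -> np.ndarray:
        return (self.predict_proba(bags) >= self.wsi_threshold).astype(int)


def train_wsi_classifier(bags, labels, splits=None,
                         **kwargs) -> AttentionMILClassifier:
    """Train one line's MIL slide classifier (thin estimator wrapper)."""
    clf = AttentionMILClassifier(**kwargs)
    return clf.fit(bags, labels, splits)
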