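"""Two-branch classifier over community and subcellular-localization features.

Essential proteins are rare, so each training epoch sees a *balanced* subset:
all M positives plus M negatives drawn uniformly without replacement from the
N training negatives. The minimum number of epochs guaranteeing (with
probability >= 1 - P per negative) that every negative is sampled at least
once is the smallest k with

    (1 - M/N)^k <= P          (default P = 0.001).

The network has one fully connected branch per feature block (batch
normalization and ReLU after every branch layer), each ending in a length-16
representation; the concatenated representations feed a small fully
connected head with a sigmoid output. Training minimizes binary cross
entropy with full-batch Adam steps, one balanced draw per epoch, and is
reproducible given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import IO

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import train_test_split

from ._nn import Adam, TwoBranchNet, bce_with_logits

__all__ = [
    "ModelSpec",
    "TrainConfig",
    "SplitSpec",
    "Prediction",
    "TwoBranchClassifier",
    "min_epochs_for_coverage",
    "sample_balanced_subset",
    "split_dataset",
    "train_model",
    "predict_scores",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class ModelSpec:
    """Layer widths of the two branches and the head (branch outputs = 16)."""

    community_hidden: tuple[int, ...] = (32, 16)
    subcellular_hidden: tuple[int, ...] = (256, 64, 16)
    head_hidden: tuple[int, ...] = (16,)


@dataclass(frozen=True)
class TrainConfig:
    """Training knobs; ``epochs=None`` selects max(coverage minimum, 200)."""

    epochs: int | None = None
    learning_rate: float = 0.01
    seed: int = 0
    coverage_P: float = 0.001
    min_epochs: int = 200


@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = 0.8
    stratified: bool = True
    seed: int = 0


@dataclass(frozen=True)
class Prediction:
    proteins: tuple[str, ...]
    scores: np.ndarray  # in [0, 1]
    labels: np.ndarray  # at the 0.5 threshold


def min_epochs_for_coverage(M: int, N: int, P: float = 0.001) -> int:
    """Smallest integer k with (1 - M/N)^k <= P.

    M is the positive count, N the negative count (M <= N), P the bound on
    the probability that a given negative is never drawn in k balanced epochs.
    """
    if M <= 0:
        raise ValueError("M must be positive")
    if M > N:
        raise ValueError("M must not exceed N")
    if not 0 < P < 1:
        raise ValueError("P must be in (0, 1)")
    q = 1.0 - M / N
    if q == 0.0:
        return 1
    k = max(1, int(np.ceil(np.log(P) / np.log(q))))
    # guard the closed form against floating-point edge cases
    while k > 1 and q ** (k - 1) <= P:
        k -= 1
    while q**k > P:
        k += 1
    return k


def sample_balanced_subset(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """All positives plus an equal number of negatives drawn without replacement."""
    labels = np.asarray(labels).ravel()
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    if pos.size > neg.size:
        raise ValueError("more positives than negatives; balanced downsampling undefined")
    chosen = rng.choice(neg, size=pos.size, replace=False)
    return np.concatenate([pos, chosen])


def split_dataset(labels: np.ndarray, spec: SplitSpec | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/test index split (stratified by default)."""
    spec = spec or SplitSpec()
    labels = np.asarray(labels).ravel()
    if not 0 < spec.train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    if spec.stratified:
        counts = np.bincount(labels, minlength=2)
        if (counts < 5).any():
            raise ValueError("stratified split needs at least 5 samples per class")
    idx = np.arange(labels.size)
    train, test = train_test_split(
        idx,
        train_size=spec.train_fraction,
        stratify=labels if spec.stratified else None,
        random_state=spec.seed,
        shuffle=True,
    )
    return np.sort(train), np.sort(test)


class TwoBranchClassifier(BaseEstimator, ClassifierMixin):
    """sklearn-style estimator wrapping the two-branch numpy network.

    ``X`` passed to :meth:`fit` is the horizontal concatenation
    ``[community features | subcellular features]``; ``n_community_features``
    says where the split lies (0 = subcellular-only, ``X.shape[1]`` =
    community-only). Branch hidden widths are fixed by the model spec; input
    widths are read from the data.

    Attributes (after fit): ``net_`` the trained network, ``loss_trace_`` the
    per-epoch balanced-subset loss, ``epochs_`` the epoch count used,
    ``n_features_in_``.
    """

    def __init__(
        self,
        n_community_features: int = 0,
        community_hidden: tuple[int, ...] = (32, 16),
        subcellular_hidden: tuple[int, ...] = (256, 64, 16),
        head_hidden: tuple[int, ...] = (16,),
        learning_rate: float = 0.01,
        epochs: int | None = None,
        min_epochs: int = 200,
        coverage_P: float = 0.001,
        random_state: int = 0,
    ):
        self.n_community_features = n_community_features
        self.community_hidden = community_hidden
        self.subcellular_hidden = subcellular_hidden
        self.head_hidden = head_hidden
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.min_epochs = min_epochs
        self.coverage_P = coverage_P
        self.random_state = random_state

    def fit(self, X: np.ndarray, y: np.ndarray) -> "TwoBranchClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).ravel().astype(int)
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ValueError("X/y shape mismatch")
        if not 0 <= self.n_community_features <= X.shape[1]:
            raise ValueError("n_community_features out of range")
        if self.epochs is not None and self.epochs <= 0:
            raise ValueError("epochs must be positive")
        M = int((y == 1).sum())
        N = int((y == 0).sum())
        if M == 0 or N == 0:
            raise ValueError("both classes must be present")
        epochs = self.epochs
        if epochs is None:
            epochs = max(min_epochs_for_coverage(M, N, self.coverage_P), self.min_epochs)
        rng = np.random.default_rng(self.random_state)
        net = TwoBranchNet(
            n_community=self.n_community_features,
            n_subcellular=X.shape[1] - self.n_community_features,
            community_hidden=tuple(self.community_hidden),
            subcellular_hidden=tuple(self.subcellular_hidden),
            head_hidden=tuple(self.head_hidden),
            rng=rng,
        )
        opt = Adam(net.params, lr=self.learning_rate)
        losses: list[float] = []
        for epoch in range(epochs):
            idx = sample_balanced_subset(y, rng)
            logits = net.forward(X[idx], training=True)
            loss, dlogits = bce_with_logits(logits, y[idx].astype(float))
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite training loss at epoch {epoch + 1}")
            net.backward(dlogits)
            opt.step(net.grads)
            losses.append(loss)
        self.net_ = net
        self.loss_trace_ = tuple(losses)
        self.epochs_ = epochs
        self.n_features_in_ = X.shape[1]
        self.classes_ = np.array([0, 1])
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1] if X.ndim == 2 else 'non-2D'}"
            )
        return self.net_.forward(X, training=False)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        p = 1.0 / (1.0 + np.exp(-self.decision_function(X)))
        return np.column_stack([1.0 - p, p])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def train_model(
    X_community: np.ndarray,
    X_subcellular: np.ndarray,
    y: np.ndarray,
    spec: ModelSpec | None = None,
    cfg: TrainConfig | None = None,
) -> TwoBranchClassifier:
    """Train the two-branch classifier on pre-split feature blocks."""
    spec = spec or ModelSpec()
    cfg = cfg or TrainConfig()
    Xc = np.asarray(X_community, dtype=float)
    Xs = np.asarray(X_subcellular, dtype=float)
    X = np.hstack([Xc, Xs]) if Xc.size and Xs.size else (Xc if Xs.size == 0 else Xs)
    clf = TwoBranchClassifier(
        n_community_features=Xc.shape[1] if Xc.size else 0,
        community_hidden=spec.community_hidden,
        subcellular_hidden=spec.subcellular_hidden,
        head_hidden=spec.head_hidden,
        learning_rate=cfg.learning_rate,
        epochs=cfg.epochs,
        min_epochs=cfg.min_epochs,
        coverage_P=cfg.coverage_P,
        random_state=cfg.seed,
    )
    return clf.fit(X, y)


def predict_scores(
    model: TwoBranchClassifier, X: np.ndarray, proteins: list[str] | None = None
) -> Prediction:
    """Sigmoid scores and 0.5-threshold labels (inference-mode normalization)."""
    scores = model.predict_proba(X)[:, 1]
    labels = (scores >= 0.5).astype(int)
    names = tuple(proteins) if proteins is not None else tuple(str(i) for i in range(len(scores)))
    return Prediction(proteins=names, scores=scores, labels=labels)


def save_model(model: TwoBranchClassifier, sink: IO[str]) -> None:
    """Self-describing JSON checkpoint: hyperparameters plus layer weights."""
    payload = {
        "params": {k: (list(v) if isinstance(v, tuple) else v) for k, v in model.get_params().items()},
        "n_features_in": int(model.n_features_in_),
        "epochs": int(model.epochs_),
        "net": model.net_.state(),
    }
    json.dump(payload, sink)


def load_model(source: IO[str]) -> TwoBranchClassifier:
    payload = json.load(source)
    params = payload["params"]
    for k in ("community_hidden", "subcellular_hidden", "head_hidden"):
        params[k] = tuple(params[k])
    model = TwoBranchClassifier(**params)
    model.net_ = TwoBranchNet.from_state(payload["net"])
    model.n_features_in_ = payload["n_features_in"]
    model.epochs_ = payload["epochs"]
    model.loss_trace_ = ()
    model.classes_ = np.array([0, 1])
    return model
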