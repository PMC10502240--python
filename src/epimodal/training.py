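"""Training loop and evaluation metrics for the multimodal models.

The loss is mean binary cross entropy over all (sample, event) entries plus
L1 and L2 penalties on the trainable weights (biases exempt).  Training
runs up to ``max_epochs`` with early stopping on validation BCE (patience
in epochs) and returns the best-validation checkpoint, never the last.
A warm start initialises the sequence encoder from a pretrained
sequence-only checkpoint while the rest of the model starts cold.

Evaluation reports per-event AUROC (pair counting with half credit for
ties) and AUPRC (step-wise precision-recall integral, average-precision
convention), macro-averaged over events that have both classes present.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .encoders import MultimodalModel, load_sequence_encoder_weights
from .nn import Adam, Tensor
from .nn import autograd as ag

PRED_CLIP = 1e-7


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    l1_coef: float = 0.0
    l2_coef: float = 0.0
    max_epochs: int = 40
    patience: int = 4
    batch_size: int = 64
    seed: int = 0
    warm_start: str | None = None  # checkpoint dir for the sequence encoder
    n_trials: int = 5

    def __post_init__(self):
        if self.patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")
        if self.l1_coef < 0 or self.l2_coef < 0:
            raise ValueError("regularization coefficients must be >= 0")


@dataclass
class WindowDataset:
    """Aligned one-hot windows, global bin indices and event labels."""

    onehot: np.ndarray  # (N, 4, L)
    bins: np.ndarray  # (N,)
    labels: np.ndarray  # (N, E)

    def __post_init__(self):
        n = self.onehot.shape[0]
        if not (self.bins.shape[0] == n and self.labels.shape[0] == n):
            raise ValueError("onehot, bins and labels must be aligned")

    def __len__(self) -> int:
        return self.onehot.shape[0]

    @property
    def n_events(self) -> int:
        return self.labels.shape[1]

    def subset(self, idx) -> "WindowDataset":
        return WindowDataset(self.onehot[idx], self.bins[idx], self.labels[idx])


def _penalized_params(model) -> dict:
    return {k: t for k, t in model.parameters().items() if not k.endswith("bias")}


def loss(pred: Tensor, label: np.ndarray, params: dict | None = None,
         l1_coef: float = 0.0, l2_coef: float = 0.0) -> Tensor:
    """Mean BCE over all entries plus L1/L2 penalties on ``params``.

    Predictions are clipped to [1e-7, 1 - 1e-7] before the logarithm.
    """
    label = np.asarray(label, dtype=float)
    p = ag.clip(pred, PRED_CLIP, 1.0 - PRED_CLIP)
    bce = -(Tensor(label) * ag.log(p) + Tensor(1.0 - label) * ag.log(1.0 - p))
    total = ag.mean(bce)
    if params:
        if l1_coef > 0:
            l1 = [ag.sum_(ag.abs_(t)) for t in params.values()]
            total = total + Tensor(l1_coef) * _sum_scalars(l1)
        if l2_coef > 0:
            l2 = [ag.sum_(ag.square(t)) for t in params.values()]
            total = total + Tensor(l2_coef) * _sum_scalars(l2)
    return total


def _sum_scalars(terms):
    acc = terms[0]
    for t in terms[1:]:
        acc = acc + t
    return acc


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    valid_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_valid_loss: float = float("inf")


def _valid_bce(model: MultimodalModel, data: WindowDataset, batch_size: int) -> float:
    probs = model.predict(data.onehot, data.bins, batch_size=batch_size)
    p = np.clip(probs, PRED_CLIP, 1 - PRED_CLIP)
    y = data.labels
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def train(model: MultimodalModel, train_data: WindowDataset,
          valid_data: WindowDataset, config: TrainConfig) -> tuple[MultimodalModel, TrainHistory]:
    """Train with early stopping; returns the best-validation checkpoint."""
    if train_data.n_events != model.n_events:
        raise ValueError(
            f"label matrix has {train_data.n_events} events, model expects {model.n_events}"
        )
    if len(valid_data) == 0:
        raise ValueError("validation set must be non-empty")
    if config.warm_start is not None:
        load_sequence_encoder_weights(model, config.warm_start)
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    penalized = _penalized_params(model)
    history = TrainHistory()
    best_state = model.state_dict()
    epochs_since_best = 0
    n = len(train_data)
    for epoch in range(config.max_epochs):
        model.train()
        order = rng.permutation(n)
        epoch_losses = []
        for lo in range(0, n, config.batch_size):
            idx = order[lo : lo + config.batch_size]
            model.zero_grad()
            pred = model(train_data.onehot[idx], train_data.bins[idx])
            batch_loss = loss(pred, train_data.labels[idx], penalized,
                              config.l1_coef, config.l2_coef)
            if not np.isfinite(batch_loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch + 1} "
                    f"(learning rate {config.learning_rate} may be too high)"
                )
            batch_loss.backward()
            opt.step()
            epoch_losses.append(float(batch_loss.data))
        vloss = _valid_bce(model, valid_data, config.batch_size)
        history.train_loss.append(float(np.mean(epoch_losses)))
        history.valid_loss.append(vloss)
        if vloss < history.best_valid_loss:
            history.best_valid_loss = vloss
            history.best_epoch = epoch
            best_state = model.state_dict()
            epochs_since_best = 0
        else:
            epochs_since_best += 1
            if epochs_since_best >= config.patience:
                break
    model.load_state_dict(best_state)
    model.eval()
    return model, history


# --- metrics ----------------------------------------------------------------

def positive_rate(labels) -> float:
    """Fraction of positive labels in a binary vector/matrix."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label set")
    return float(labels.mean())


def auroc(scores, labels) -> float:
    """P(score_pos > score_neg) + 0.5 P(tie), by the rank formula."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    npos = int(labels.sum())
    nneg = labels.size - npos
    if npos == 0 or nneg == 0:
        raise ValueError("auroc requires both classes")
    from scipy.stats import rankdata

    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - npos * (npos + 1) / 2) / (npos * nneg))


def auprc(scores, labels) -> float:
    """Average precision: sum of precision-weighted recall increments over
    descending score thresholds (ties grouped)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(float)
    npos = labels.sum()
    if npos == 0 or npos == labels.size:
        raise ValueError("auprc requires both classes")
    order = np.argsort(-scores, kind="mergesort")
    s, y = scores[order], labels[order]
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    # keep only the last index of each tied score block (threshold points)
    last = np.r_[s[1:] != s[:-1], True]
    tp, fp = tp[last], fp[last]
    precision = tp / (tp + fp)
    recall = tp / npos
    recall_prev = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - recall_prev) * precision))


@dataclass
class MetricsReport:
    """Per-event metrics with macro averages over non-degenerate events."""

    auroc_per_event: np.ndarray
    auprc_per_event: np.ndarray
    excluded_events: list[int]

    @property
    def macro_auroc(self) -> float:
        return float(np.nanmean(self.auroc_per_event))

    @property
    def macro_auprc(self) -> float:
        return float(np.nanmean(self.auprc_per_event))


def evaluate(model: MultimodalModel, data: WindowDataset,
             batch_size: int = 64) -> MetricsReport:
    probs = model.predict(data.onehot, data.bins, batch_size=batch_size)
    return metrics_report(probs, data.labels)


def metrics_report(scores: np.ndarray, labels: np.ndarray) -> MetricsReport:
    E = labels.shape[1]
    roc = np.full(E, np.nan)
    prc = np.full(E, np.nan)
    excluded = []
    for e in range(E):
        y = labels[:, e]
        if y.sum() in (0, y.size):
            excluded.append(e)
            continue
        roc[e] = auroc(scores[:, e], y)
        prc[e] = auprc(scores[:, e], y)
    if len(excluded) == E:
        raise ValueError("every event is degenerate in the evaluation set")
    return MetricsReport(roc, prc, excluded)
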