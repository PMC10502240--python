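"""Noncoding variant effect prediction from epigenetic-profile changes.

A trained epigenetic predictor scores the reference and alternate windows
of a variant; the per-event probability differences and log-odds
differences are the variant's effect features.  Three uses are supported:

* zero-shot scoring — an aggregation of absolute probability differences
  used directly as an effect indicator, with no labelled variants;
* eQTL classification — L2-regularised logistic regression on the
  log-odds-difference features, cross-validated over chromosome-grouped
  folds (no chromosome appears in two folds; X and Y share a fold), with
  the encoder held fixed;
* few-shot pathogenicity — a Siamese classifier: two weight-tied copies of
  the multimodal encoder, the squared differences of their E event
  probabilities fed to an E-to-1 affine + sigmoid head, trained end to end
  on tens-to-hundreds of labelled variants with the encoder warm-started
  and the head fresh.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
from sklearn.linear_model import LogisticRegression

from .encoders import MultimodalModel
from .nn import Adam, Tensor
from .nn import autograd as ag
from .training import PRED_CLIP, auprc, auroc

LOGIT_CLIP = 1e-6


@dataclass
class EffectFeatures:
    """Per-event probability and log-odds differences (alt minus ref)."""

    variant_id: str | None
    delta_prob: np.ndarray
    delta_logit: np.ndarray


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, LOGIT_CLIP, 1.0 - LOGIT_CLIP)
    return np.log(p / (1.0 - p))


def effect_features(model: MultimodalModel, ref_onehot: np.ndarray,
                    alt_onehot: np.ndarray, bin_index: int,
                    event_mask: np.ndarray | None = None,
                    variant_id: str | None = None) -> EffectFeatures:
    """Score both windows at the same Hi-C bin and return the differences.

    ``event_mask`` restricts to a subset of events (e.g. the cell-line-
    matched ones).
    """
    if ref_onehot.shape != alt_onehot.shape:
        raise ValueError("reference and alternate windows must share a shape")
    probs = model.predict(np.stack([ref_onehot, alt_onehot]),
                          np.array([bin_index, bin_index]))
    p_ref, p_alt = probs[0], probs[1]
    if event_mask is not None:
        p_ref, p_alt = p_ref[event_mask], p_alt[event_mask]
    return EffectFeatures(
        variant_id=variant_id,
        delta_prob=p_alt - p_ref,
        delta_logit=_logit(p_alt) - _logit(p_ref),
    )


def zero_shot_score(features: EffectFeatures, mode: str = "mean_abs") -> float:
    """Aggregate |delta probability| into a scalar effect score."""
    d = np.abs(features.delta_prob)
    if mode == "mean_abs":
        return float(d.mean())
    if mode == "max_abs":
        return float(d.max())
    if mode == "l2":
        return float(np.sqrt((d**2).sum()))
    raise ValueError(f"unknown zero-shot mode {mode!r}")


# --- chromosome-grouped cross-validation ------------------------------------

@dataclass
class GroupedFolds:
    """Fold assignment per variant, grouped by chromosome."""

    fold_of_chrom: dict[str, int]
    n_folds: int

    def fold_of(self, chrom: str) -> int:
        return self.fold_of_chrom[_merge_sex(chrom)]


def _merge_sex(chrom: str) -> str:
    base = chrom.removeprefix("chr")
    return "XY" if base in ("X", "Y") else chrom


def grouped_folds(chromosomes, n_folds: int = 5, seed: int = 0) -> GroupedFolds:
    """Assign chromosome groups to folds, greedily balancing variant counts.

    Sex chromosomes X and Y count as one group and always share a fold.
    Deterministic given the seed (which breaks ordering ties).
    """
    chromosomes = list(chromosomes)
    groups: dict[str, int] = {}
    for c in chromosomes:
        groups[_merge_sex(c)] = groups.get(_merge_sex(c), 0) + 1
    if len(groups) < n_folds:
        raise ValueError(
            f"{len(groups)} chromosome groups cannot fill {n_folds} folds"
        )
    rng = np.random.default_rng(seed)
    names = list(groups)
    order = sorted(rng.permutation(len(names)), key=lambda i: -groups[names[i]])
    fold_sizes = np.zeros(n_folds, dtype=int)
    fold_of: dict[str, int] = {}
    for i in order:
        f = int(np.argmin(fold_sizes))
        fold_of[names[i]] = f
        fold_sizes[f] += groups[names[i]]
    return GroupedFolds(fold_of_chrom=fold_of, n_folds=n_folds)


@dataclass
class CrossvalResult:
    fold_auroc: list[float]
    fold_auprc: list[float]
    best_c: float
    n_used: int

    @property
    def mean_auroc(self) -> float:
        return _nanmean_or_nan(self.fold_auroc)

    @property
    def mean_auprc(self) -> float:
        return _nanmean_or_nan(self.fold_auprc)


def _nanmean_or_nan(values) -> float:
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    return float(arr.mean()) if arr.size else float("nan")


def eqtl_crossval(features: np.ndarray, labels: np.ndarray, chroms,
                  folds: GroupedFolds, c_grid=(0.01, 0.1, 1.0, 10.0),
                  tuning_chroms=("chr8", "chr9"), log2_fold_change=None,
                  fold_change_cutoff: float | None = None,
                  seed: int = 0) -> CrossvalResult:
    """Chromosome-grouped cross-validation of an L2 logistic eQTL classifier.

    ``features`` are the log-odds-difference vectors (the encoder stays
    fixed by construction: only precomputed features enter).  The inverse
    regularisation strength is chosen on the held-out tuning chromosomes,
    then per-fold models are fit on the remaining folds.  When a fold
    change cutoff is given, evaluation keeps variants with
    ``|log2 fold change| >= cutoff``.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels).astype(int)
    chroms = np.asarray(list(chroms))
    tuning_set = {_merge_sex(c) for c in tuning_chroms}
    is_tuning = np.array([_merge_sex(c) in tuning_set for c in chroms])
    eval_filter = np.ones(len(labels), dtype=bool)
    if fold_change_cutoff is not None:
        if log2_fold_change is None:
            raise ValueError("fold_change_cutoff requires log2_fold_change values")
        eval_filter = np.abs(np.asarray(log2_fold_change)) >= fold_change_cutoff
        if not eval_filter.any():
            raise ValueError(
                f"no variant passes |log2FC| >= {fold_change_cutoff}; relax the filter"
            )
    # hyperparameter choice on the tuning chromosomes
    best_c, best_score = c_grid[0], -np.inf
    rest = ~is_tuning
    if is_tuning.sum() >= 4 and len(set(labels[is_tuning])) == 2:
        for c in c_grid:
            clf = LogisticRegression(C=c, max_iter=1000, random_state=seed)
            clf.fit(features[rest], labels[rest])
            score = auroc(clf.predict_proba(features[is_tuning])[:, 1], labels[is_tuning])
            if score > best_score:
                best_c, best_score = c, score
    fold_ids = np.array([folds.fold_of(c) for c in chroms])
    roc, prc = [], []
    n_used = 0
    for f in range(folds.n_folds):
        test = rest & (fold_ids == f) & eval_filter
        train = rest & (fold_ids != f)
        if len(set(labels[test])) < 2 or len(set(labels[train])) < 2:
            roc.append(float("nan"))
            prc.append(float("nan"))
            continue
        clf = LogisticRegression(C=best_c, max_iter=1000, random_state=seed)
        clf.fit(features[train], labels[train])
        scores = clf.predict_proba(features[test])[:, 1]
        roc.append(auroc(scores, labels[test]))
        prc.append(auprc(scores, labels[test]))
        n_used += int(test.sum())
    return CrossvalResult(fold_auroc=roc, fold_auprc=prc, best_c=best_c, n_used=n_used)


# --- the Siamese few-shot pathogenicity classifier --------------------------

class SiameseClassifier:
    """Two weight-tied multimodal encoders with a squared-difference head.

    The squared differences of the E event probabilities of the reference
    and alternate windows feed an E-to-1 affine + sigmoid.  The output is
    exactly invariant to swapping the two inputs.
    """

    def __init__(self, encoder: MultimodalModel, seed: int = 0):
        self.encoder = encoder
        rng = np.random.default_rng(seed)
        from .nn import Linear

        self.head = Linear(encoder.n_events, 1, rng)
        # uniform positive init: before any labelled update the classifier
        # ranks variants by the aggregate squared probability difference,
        # the natural zero-labelled-data limit of the protocol
        self.head.w.data = np.full((encoder.n_events, 1), 1.0)
        self.head.b.data = np.array([-1.0])

    def parameters(self) -> dict[str, Tensor]:
        out = {f"encoder.{k}": v for k, v in self.encoder.parameters().items()}
        out.update({f"head.{k}": v for k, v in self.head.parameters().items()})
        return out

    def forward(self, ref_onehot: np.ndarray, alt_onehot: np.ndarray,
                bins: np.ndarray) -> Tensor:
        bins = np.asarray(bins, dtype=np.intp)
        p_ref = self.encoder(np.asarray(ref_onehot), bins)
        p_alt = self.encoder(np.asarray(alt_onehot), bins)
        sq = ag.square(p_ref - p_alt)
        return ag.sigmoid(self.head(sq))

    def predict(self, ref_onehot, alt_onehot, bins, batch_size: int = 32) -> np.ndarray:
        self.encoder.eval()
        self.head.eval()
        out = []
        ref_onehot = np.asarray(ref_onehot)
        alt_onehot = np.asarray(alt_onehot)
        bins = np.asarray(bins, dtype=np.intp)
        for lo in range(0, ref_onehot.shape[0], batch_size):
            sl = slice(lo, lo + batch_size)
            out.append(self.forward(ref_onehot[sl], alt_onehot[sl], bins[sl]).data[:, 0])
        return np.concatenate(out)


@dataclass
class VariantBatch:
    """Aligned ref/alt one-hot windows, bin indices and binary labels."""

    ref_onehot: np.ndarray
    alt_onehot: np.ndarray
    bins: np.ndarray
    labels: np.ndarray

    def __len__(self) -> int:
        return self.ref_onehot.shape[0]

    def subset(self, idx) -> "VariantBatch":
        return VariantBatch(self.ref_onehot[idx], self.alt_onehot[idx],
                            self.bins[idx], self.labels[idx])


def zero_shot_scores(model: MultimodalModel, batch: VariantBatch,
                     mode: str = "mean_abs") -> np.ndarray:
    """Zero-shot scores for a batch of variants."""
    out = []
    for i in range(len(batch)):
        feats = effect_features(model, batch.ref_onehot[i], batch.alt_onehot[i],
                                int(batch.bins[i]))
        out.append(zero_shot_score(feats, mode=mode))
    return np.asarray(out)


def fit_siamese(encoder: MultimodalModel, train_batch: VariantBatch,
                valid_batch: VariantBatch, l2_weight: float = 1e-11,
                learning_rate: float = 1e-3, max_epochs: int = 40,
                patience: int = 4, batch_size: int = 32, seed: int = 0):
    """Train the few-shot Siamese pathogenicity classifier end to end.

    The encoder is warm-started from the given pretrained model (copied,
    not mutated) and the head starts fresh.  With an empty training set the
    protocol falls back to the zero-shot scorer: the returned object scores
    with mean absolute probability difference.
    """
    if len(train_batch) == 0:
        class _ZeroShot:
            trained = False

            def predict(self, ref, alt, bins, batch_size: int = 32):
                return zero_shot_scores(encoder, VariantBatch(
                    np.asarray(ref), np.asarray(alt),
                    np.asarray(bins, dtype=np.intp),
                    np.zeros(len(ref))))

        return _ZeroShot()
    model = SiameseClassifier(copy.deepcopy(encoder), seed=seed)
    rng = np.random.default_rng(seed)
    opt = Adam(model.parameters(), lr=learning_rate)
    penalized = {k: t for k, t in model.parameters().items() if not k.endswith("bias")}
    def _vloss() -> float:
        vscores = model.predict(valid_batch.ref_onehot, valid_batch.alt_onehot,
                                valid_batch.bins)
        p = np.clip(vscores, PRED_CLIP, 1 - PRED_CLIP)
        y = valid_batch.labels.astype(float)
        return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))

    best_state = {k: t.data.copy() for k, t in model.parameters().items()}
    best_vloss = _vloss()  # the untrained classifier is a valid candidate
    since_best = 0
    n = len(train_batch)
    for epoch in range(max_epochs):
        model.encoder.train()
        order = rng.permutation(n)
        for lo in range(0, n, batch_size):
            idx = order[lo : lo + batch_size]
            for t in model.parameters().values():
                t.grad = None
            pred = model.forward(train_batch.ref_onehot[idx],
                                 train_batch.alt_onehot[idx],
                                 train_batch.bins[idx])
            y = train_batch.labels[idx].astype(float)[:, None]
            p = ag.clip(pred, PRED_CLIP, 1 - PRED_CLIP)
            bce = ag.mean(-(Tensor(y) * ag.log(p) + Tensor(1 - y) * ag.log(1 - p)))
            reg = [ag.sum_(ag.square(t)) for t in penalized.values()]
            total = bce
            if l2_weight > 0:
                acc = reg[0]
                for r in reg[1:]:
                    acc = acc + r
                total = total + Tensor(l2_weight) * acc
            total.backward()
            opt.step()
        vloss = _vloss()
        if vloss < best_vloss:
            best_vloss = vloss
            best_state = {k: t.data.copy() for k, t in model.parameters().items()}
            since_best = 0
        else:
            since_best += 1
            if since_best >= patience:
                break
    for k, t in model.parameters().items():
        t.data = best_state[k]
    model.encoder.eval()
    model.trained = True
    return model
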