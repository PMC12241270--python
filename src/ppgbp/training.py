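"""Training loop and k-fold evaluation protocol.

Optimization follows the reference protocol: Adam, mean-squared error summed
over the SBP and DBP targets, a validation split held out before training
for early stopping, learning-rate halving when the validation loss
plateaus, and restoration of the best-validation weights.  ``kfold_evaluate``
wraps it in k-fold cross-validation and pools the out-of-fold predictions,
which is what every downstream metric is computed on.

Windows from one record overlap by construction, so window-level splitting
leaks samples between train and test folds; ``split_by='subject'`` groups
folds by subject id to avoid this and is what the synthetic recovery study
uses.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.model_selection import GroupKFold, KFold

from ppgbp.config import ConfigurationError, TrainConfig, derive_seed
from ppgbp.imaging import MODALITIES, ModalityImageTriplet, render_triplet
from ppgbp.nn.model import CrossAttentionRegressor
from ppgbp.nn.ops import AdamOptimizer
from ppgbp.preprocess import InputError, SegmentWindow

logger = logging.getLogger(__name__)


@dataclass
class TrainHistory:
    train_loss: List[float] = field(default_factory=list)
    val_loss: List[float] = field(default_factory=list)
    learning_rate: List[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_early: bool = False
    # validation loss of the returned (restored or tail-averaged) weights
    final_val_loss: float = float("nan")

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)


def _render_all(
    windows: Sequence[SegmentWindow], model: CrossAttentionRegressor
) -> List[ModalityImageTriplet]:
    return [render_triplet(w, model.render_spec) for w in windows]


def _stack_images(triplets: Sequence[ModalityImageTriplet]) -> Dict[str, np.ndarray]:
    return {
        mod: np.stack([t.images[j] for t in triplets])
        for j, mod in enumerate(MODALITIES)
    }


def _batch_loss_and_grads(model, triplets, targets_std, need_grad=True):
    images = _stack_images(triplets)
    preds, _, cache = model.forward_batch(images, need_grad=need_grad)
    err = preds - targets_std
    loss = float(np.mean(err**2))
    if not need_grad:
        return loss, None
    dpreds = (2.0 * err / err.size).astype(preds.dtype)
    grads = model.backward_batch(dpreds, cache)
    return loss, grads


def _crop_render(
    window: SegmentWindow,
    crop_frac: float,
    rng: np.random.Generator,
    model: CrossAttentionRegressor,
) -> ModalityImageTriplet:
    n = len(window.ppg)
    length = int(round(rng.uniform(1.0 - crop_frac, 1.0) * n))
    length = max(length, 2)
    start = int(rng.integers(0, n - length + 1))
    cropped = dataclasses.replace(
        window,
        ppg=window.ppg[start : start + length],
        vppg=window.vppg[start : start + length],
        appg=window.appg[start : start + length],
    )
    return render_triplet(cropped, model.render_spec)


def _predict_windows(
    model: CrossAttentionRegressor,
    windows: Sequence[SegmentWindow],
    config: TrainConfig,
) -> np.ndarray:
    """Predictions in mmHg, optionally averaged over time-crop renderings."""
    views = [model.predict_triplets(_render_all(windows, model), batch_size=config.batch_size)]
    if config.tta_crops > 0 and config.augment_time_crop > 0:
        rng = np.random.default_rng(derive_seed(config.seed, 91))
        for _ in range(config.tta_crops):
            trips = [_crop_render(w, config.augment_time_crop, rng, model) for w in windows]
            views.append(model.predict_triplets(trips, batch_size=config.batch_size))
    return np.mean(views, axis=0)


def _eval_loss(model, triplets, targets_std, batch_size):
    losses, weights = [], []
    for i in range(0, len(triplets), batch_size):
        chunk = triplets[i : i + batch_size]
        loss, _ = _batch_loss_and_grads(
            model, chunk, targets_std[i : i + batch_size], need_grad=False
        )
        losses.append(loss)
        weights.append(len(chunk))
    return float(np.average(losses, weights=weights))


def train(
    model: CrossAttentionRegressor,
    windows: Sequence[SegmentWindow],
    config: TrainConfig,
    trainable: Optional[Sequence[str]] = None,
) -> Tuple[CrossAttentionRegressor, TrainHistory]:
    """Fit the model in place; returns it with the best-validation weights.

    ``trainable`` restricts the updated parameters (by name); by default all
    parameters reported by ``model.trainable_names()`` are updated.
    """
    config.validate()
    if len(windows) < 2 * config.batch_size:
        raise InputError(
            f"need at least {2 * config.batch_size} windows, got {len(windows)}"
        )
    labels = np.array([[w.sbp_label, w.dbp_label] for w in windows], dtype=float)
    if not np.all(np.isfinite(labels)):
        raise InputError("non-finite BP labels")

    rng = np.random.default_rng(derive_seed(config.seed, 21))
    order = rng.permutation(len(windows))
    n_val = max(1, int(round(config.val_split * len(windows))))
    val_idx, train_idx = order[:n_val], order[n_val:]

    triplets = _render_all(windows, model)
    # standardize targets on the training portion (identity if degenerate)
    model.y_mean = labels[train_idx].mean(axis=0)
    model.y_scale = np.maximum(labels[train_idx].std(axis=0), 1e-8)
    targets_std = (labels - model.y_mean) / model.y_scale

    train_trip = [triplets[i] for i in train_idx]
    train_y = targets_std[train_idx]
    val_trip = [triplets[i] for i in val_idx]
    val_y = targets_std[val_idx]

    allowed = set(trainable if trainable is not None else model.trainable_names())
    optimizer = AdamOptimizer(lr=config.learning_rate)
    history = TrainHistory()
    best_val = np.inf
    best_params = model.copy_params()
    epochs_since_best = 0
    lr_wait = 0
    lr = config.learning_rate
    tail_params: List[Dict[str, np.ndarray]] = []

    for epoch in range(config.max_epochs):
        if config.augment_time_crop > 0:
            # re-render each training window from a random sub-span: a time
            # rescaling that keeps within-beat morphology but decorrelates
            # beat density (heart rate) from the labels
            epoch_trip = [
                _crop_render(windows[i], config.augment_time_crop, rng, model)
                for i in train_idx
            ]
        else:
            epoch_trip = train_trip
        perm = rng.permutation(len(epoch_trip))
        epoch_losses, epoch_sizes = [], []
        for i in range(0, len(perm), config.batch_size):
            idx = perm[i : i + config.batch_size]
            loss, grads = _batch_loss_and_grads(
                model, [epoch_trip[j] for j in idx], train_y[idx]
            )
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}: lr={lr}, "
                    f"batch indices {idx[:4]}..."
                )
            grads = {k: g for k, g in grads.items() if k in allowed}
            optimizer.lr = lr
            optimizer.step(model.params, grads)
            epoch_losses.append(loss)
            epoch_sizes.append(len(idx))
        train_loss = float(np.average(epoch_losses, weights=epoch_sizes))
        val_loss = _eval_loss(model, val_trip, val_y, config.batch_size)
        history.train_loss.append(train_loss)
        history.val_loss.append(val_loss)
        history.learning_rate.append(lr)
        logger.info(
            "epoch %3d  train %.5f  val %.5f  lr %.2e", epoch, train_loss, val_loss, lr
        )

        if config.tail_average > 0 and epoch >= config.max_epochs - config.tail_average:
            tail_params.append(model.copy_params())

        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_params = model.copy_params()
            history.best_epoch = epoch
            epochs_since_best = 0
            lr_wait = 0
        else:
            epochs_since_best += 1
            lr_wait += 1
            if lr_wait >= config.lr_patience:
                lr *= config.lr_factor
                lr_wait = 0
            if epochs_since_best >= config.early_stop_patience:
                history.stopped_early = True
                break

    if tail_params:
        model.load_params(
            {k: np.mean([p[k] for p in tail_params], axis=0) for k in tail_params[0]}
        )
    else:
        model.load_params(best_params)
    history.final_val_loss = _eval_loss(model, val_trip, val_y, config.batch_size)
    return model, history


@dataclass
class FoldResult:
    fold: int
    window_ids: List[str]
    references: np.ndarray  # (n, 2) mmHg
    estimates: np.ndarray  # (n, 2) mmHg
    history: TrainHistory


def kfold_evaluate(
    windows: Sequence[SegmentWindow],
    config: TrainConfig,
    model_factory,
) -> Tuple[Dict[str, np.ndarray], List[FoldResult]]:
    """k-fold cross-validation with pooled out-of-fold predictions.

    ``model_factory(fold_index) -> CrossAttentionRegressor`` supplies a fresh
    model per fold.  Returns pooled arrays (window_ids, references,
    estimates covering every window exactly once) and per-fold results.
    """
    config.validate()
    if len(windows) < config.k_folds * config.batch_size:
        raise InputError(
            f"need at least k_folds*batch_size = "
            f"{config.k_folds * config.batch_size} windows, got {len(windows)}"
        )
    indices = np.arange(len(windows))
    if config.split_by == "subject":
        groups = np.array([w.subject_id for w in windows])
        if len(np.unique(groups)) < config.k_folds:
            raise ConfigurationError(
                f"{len(np.unique(groups))} subjects < k_folds={config.k_folds}"
            )
        splitter = GroupKFold(n_splits=config.k_folds)
        splits = splitter.split(indices, groups=groups)
    else:
        splitter = KFold(
            n_splits=config.k_folds, shuffle=True, random_state=derive_seed(config.seed, 31) % (2**32)
        )
        splits = splitter.split(indices)

    fold_results: List[FoldResult] = []
    for fold, (tr, te) in enumerate(splits):
        test_windows = [windows[i] for i in te]
        members = []  # (final val loss, estimates, history)
        for member in range(config.ensemble):
            model = model_factory(fold * config.ensemble + member)
            member_config = dataclasses.replace(
                config, seed=derive_seed(config.seed, fold, member)
            )
            model, history = train(model, [windows[i] for i in tr], member_config)
            estimates = _predict_windows(model, test_windows, member_config)
            members.append((history.final_val_loss, estimates, history))
            logger.info(
                "fold %d member %d: final val loss %.4f", fold, member, history.final_val_loss
            )
        # model selection across restarts by validation loss: an undertrained
        # member is clearly separated from converged ones on this scale, so
        # drop members far above the best and average the converged rest
        best_val = min(m[0] for m in members)
        kept = [m for m in members if m[0] <= 1.25 * best_val + 1e-12]
        estimates = np.mean([m[1] for m in kept], axis=0)
        history = min(kept, key=lambda m: m[0])[2]
        refs = np.array([[w.sbp_label, w.dbp_label] for w in test_windows])
        fold_results.append(
            FoldResult(
                fold=fold,
                window_ids=[w.window_id for w in test_windows],
                references=refs,
                estimates=estimates,
                history=history,
            )
        )
        logger.info(
            "fold %d: %d test windows, best epoch %d",
            fold,
            len(te),
            history.best_epoch,
        )

    pooled = {
        "window_ids": np.concatenate([np.array(f.window_ids) for f in fold_results]),
        "references": np.concatenate([f.references for f in fold_results]),
        "estimates": np.concatenate([f.estimates for f in fold_results]),
    }
    return pooled, fold_results


__all__ = ["TrainHistory", "FoldResult", "train", "kfold_evaluate"]
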