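"""Scikit-learn style segmentation estimator.

``UNetSegmenter`` wraps network construction, augmentation, the combined
boundary + cross-entropy objective and Adam optimisation behind the usual
``fit`` / ``predict`` / ``score`` surface, so it composes with sklearn
pipelines and model selection. ``X`` is an (n, H, W) stack of grayscale
images in [0,1]; ``y`` the matching (n, H, W) stack of binary masks.

Randomness is split into independent child streams of the run seed
(initialisation, per-epoch shuffling, augmentation, dropout), so e.g. the
shuffle order does not change when augmentation is disabled.
"""

from __future__ import annotations

import logging
import sys

import numpy as np
from sklearn.base import BaseEstimator

from . import autodiff as ad
from .exceptions import NonFiniteGradient
from .losses import LossWeights, bce_loss, hdl_surrogate, sdhl_surrogate
from .metrics import overlap_scores
from .models import ModelSpec, SegmentationNet, build_model, predict_mask
from .training import LOSS_VARIANTS, Adam, augment_pair

__all__ = ["UNetSegmenter"]

logger = logging.getLogger(__name__)


class UNetSegmenter(BaseEstimator):
    """Binary segmentation with a UNet-family network and a boundary-aware loss.

    Parameters mirror the study configuration: Adam at ``learning_rate``
    1e-3, ``batch_size`` 32, dropout 0.1, combined loss weights
    ``lambda1`` = 0.6 (cross-entropy) and ``lambda2`` = 0.4 (boundary
    surrogate). ``loss`` selects the objective: one of
    {'hdl', 'bce', 'hdl+bce', 'sdhl', 'sdhl+bce'}.

    Fitted attributes: ``model_`` (the network, holding the parameters of
    the best validation-Dice epoch when validation data is supplied),
    ``history_`` (per-epoch loss components and validation metrics),
    ``best_epoch_`` and ``best_val_dice_``.
    """

    def __init__(self, architecture: str = "attention_unet", depth: int = 3,
                 base_channels: int = 8, dropout_rate: float = 0.1,
                 loss: str = "sdhl+bce", lambda1: float = 0.6, lambda2: float = 0.4,
                 learning_rate: float = 1e-3, batch_size: int = 32, epochs: int = 30,
                 patience: int | None = 10, seed: int = 0, augment: bool = True,
                 image_size: tuple[int, int] | None = None,
                 normalize_sdhl: bool = True, verbose: bool = False):
        self.architecture = architecture
        self.depth = depth
        self.base_channels = base_channels
        self.dropout_rate = dropout_rate
        self.loss = loss
        self.lambda1 = lambda1
        self.lambda2 = lambda2
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.epochs = epochs
        self.patience = patience
        self.seed = seed
        self.augment = augment
        self.image_size = image_size
        self.normalize_sdhl = normalize_sdhl
        self.verbose = verbose

    # -- loss dispatch -------------------------------------------------------

    def _batch_loss(self, logits: ad.Tensor, masks: np.ndarray):
        """Per-sample losses averaged over the batch; returns (total, parts)."""
        if self.loss not in LOSS_VARIANTS:
            raise ValueError(f"loss must be one of {LOSS_VARIANTS}")
        w = LossWeights(self.lambda1, self.lambda2)
        n = masks.shape[0]
        parts: dict[str, float] = {}
        terms = []
        if "bce" in self.loss:
            gt = masks.astype(np.float32)[:, None]
            bce = (ad.softplus(logits) - logits * gt).mean()
            weight = w.lambda1 if "+" in self.loss else 1.0
            terms.append(weight * bce)
            parts["bce"] = float(bce)
        if "hdl" in self.loss or "sdhl" in self.loss:
            surrogate = sdhl_surrogate if "sdhl" in self.loss else hdl_surrogate
            per_sample = [surrogate(logits[i, 0], masks[i], normalize=self.normalize_sdhl)
                          for i in range(n)]
            acc = per_sample[0]
            for t in per_sample[1:]:
                acc = acc + t
            boundary = acc * (1.0 / n)
            weight = w.lambda2 if "+" in self.loss else 1.0
            terms.append(weight * boundary)
            parts["sdhl" if "sdhl" in self.loss else "hdl"] = float(boundary)
        total = terms[0]
        for t in terms[1:]:
            total = total + t
        parts["total"] = float(total)
        return total, parts

    # -- sklearn surface -------------------------------------------------------

    def fit(self, X, y, validation=None):
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y)
        if X.shape != y.shape or X.ndim != 3:
            raise ValueError("X and y must be matching (n, H, W) stacks")
        if len(X) == 0:
            raise ValueError("cannot fit on an empty dataset")
        size = tuple(self.image_size) if self.image_size else X.shape[1:]

        ss = np.random.SeedSequence(self.seed)
        init_ss, shuffle_ss, aug_ss, drop_ss = ss.spawn(4)
        init_seed = int(init_ss.generate_state(1)[0] % (2**31))
        shuffle_rng = np.random.default_rng(shuffle_ss)
        aug_rng = np.random.default_rng(aug_ss)
        drop_rng = np.random.default_rng(drop_ss)

        spec = ModelSpec(architecture=self.architecture, depth=self.depth,
                         base_channels=self.base_channels, dropout_rate=self.dropout_rate)
        model = build_model(spec, seed=init_seed)
        opt = Adam(model.parameters(), eta=self.learning_rate)

        history: list[dict] = []
        best_dice = -np.inf
        best_state = None
        best_epoch = -1
        epochs_since_best = 0
        n = len(X)

        for epoch in range(self.epochs):
            perm = shuffle_rng.permutation(n)
            epoch_parts: dict[str, list[float]] = {}
            model.train_mode(drop_rng)
            for b_start in range(0, n, self.batch_size):
                idx = perm[b_start:b_start + self.batch_size]
                imgs, msks = [], []
                for i in idx:
                    if self.augment:
                        im, mk = augment_pair(X[i], y[i], aug_rng, size=size)
                    else:
                        im, mk = X[i], y[i]
                    imgs.append(im)
                    msks.append(mk)
                batch_x = np.stack(imgs)[:, None]
                batch_y = np.stack(msks)
                logits = model(ad.Tensor(batch_x))
                total, parts = self._batch_loss(logits, batch_y)
                if not np.isfinite(float(total)):
                    raise NonFiniteGradient(
                        f"non-finite loss at epoch {epoch}, batch {b_start // self.batch_size}")
                opt.zero_grad()
                total.backward()
                opt.step()
                for k, v in parts.items():
                    epoch_parts.setdefault(k, []).append(v)
            model.eval_mode()

            record = {"epoch": epoch}
            record.update({k: float(np.mean(v)) for k, v in epoch_parts.items()})
            if validation is not None:
                x_val, y_val = validation
                val_dice, val_iou = self._dice_iou(model, np.asarray(x_val, np.float32),
                                                   np.asarray(y_val))
                record["val_dice"] = val_dice
                record["val_iou"] = val_iou
                if val_dice > best_dice:
                    best_dice, best_epoch = val_dice, epoch
                    best_state = model.state_dict()
                    epochs_since_best = 0
                else:
                    epochs_since_best += 1
            history.append(record)
            if self.verbose:
                print(f"[epoch {epoch}] " + " ".join(f"{k}={v:.4f}" for k, v in record.items()
                                                     if k != "epoch"), file=sys.stderr)
            if (validation is not None and self.patience is not None
                    and epochs_since_best >= self.patience):
                logger.info("early stop at epoch %d (best %d)", epoch, best_epoch)
                break

        if best_state is not None:
            model.load_state_dict(best_state)
        self.model_: SegmentationNet = model
        self.history_ = history
        self.best_epoch_ = best_epoch if best_epoch >= 0 else len(history) - 1
        self.best_val_dice_ = float(best_dice) if np.isfinite(best_dice) else None
        return self

    @staticmethod
    def _dice_iou(model, images, masks) -> tuple[float, float]:
        """Mean per-image overlap scores (both-empty counts as perfect)."""
        preds = predict_mask(model, images)
        scores = [overlap_scores(preds[i], masks[i]) for i in range(len(masks))]
        return (float(np.mean([s[0] for s in scores])),
                float(np.mean([s[1] for s in scores])))

    def predict(self, X) -> np.ndarray:
        self._check_fitted()
        return predict_mask(self.model_, np.asarray(X, dtype=np.float32))

    def predict_proba(self, X) -> np.ndarray:
        """Foreground probability maps sigma(logits)."""
        self._check_fitted()
        arr = np.asarray(X, dtype=np.float32)
        batched = arr if arr.ndim == 3 else arr[None]
        self.model_.eval_mode()
        out = []
        for start in range(0, len(batched), 32):
            logits = self.model_(batched[start:start + 32]).data.astype(np.float64)
            out.append(1.0 / (1.0 + np.exp(-logits)))
        probs = np.concatenate(out, axis=0)[:, 0]
        return probs[0] if arr.ndim == 2 else probs

    def score(self, X, y) -> float:
        """Mean per-image Dice on (X, y)."""
        self._check_fitted()
        dice, _ = self._dice_iou(self.model_, np.asarray(X, np.float32), np.asarray(y))
        return dice

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted; call fit first")
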