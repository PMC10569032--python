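"""Scikit-learn style estimator wrapping the SW-UNet segmentation network.

:class:`SWUNetSegmenter` exposes the whole train/predict pipeline through the
familiar ``fit`` / ``predict`` / ``predict_proba`` / ``score`` surface so it
composes with sklearn model selection utilities.  ``X`` is an array of
single-channel images ``(n, side, side)`` with intensities in [0, 1]; ``y``
holds integer per-pixel class labels of the same shape.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .losses_metrics import LossConfig, confusion, dice_coefficient
from .network import ModelConfig, SWUNet, count_parameters
from .train import TrainConfig, evaluate_loss, fit_model


class SWUNetSegmenter(BaseEstimator):
    """Hybrid CNN + sliding-window-transformer semantic segmentation.

    Parameters mirror :class:`swunet.network.ModelConfig` (architecture) and
    :class:`swunet.train.TrainConfig` (optimization).  Defaults are the
    reference operating point: 128x128 single-channel input, 16 base
    convolution kernels, two downsampling stages, token dimension 256 with
    query/key widening rate 2, 4 heads, 4x4 windows shifted by 2, Adam with
    learning rate 1e-5, batch 48, Dice/Focal loss weighted 0.8/0.2.
    """

    def __init__(self, *, n_classes=2, input_side=128, base_width=16, encoder_depth=2,
                 token_dim=256, widening_rate=2, n_heads=4, window_side=4, shift=2,
                 use_sliding_window=True, learning_rate=1e-5, batch_size=48,
                 max_epochs=100, patience=15, alpha=0.8, beta=0.2, gamma=2.0,
                 focal_reduction="sum", lr_schedule="constant", grad_clip=None,
                 target_train_dice=None, seed=0, verbose=0):
        self.n_classes = n_classes
        self.input_side = input_side
        self.base_width = base_width
        self.encoder_depth = encoder_depth
        self.token_dim = token_dim
        self.widening_rate = widening_rate
        self.n_heads = n_heads
        self.window_side = window_side
        self.shift = shift
        self.use_sliding_window = use_sliding_window
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.alpha = alpha
        self.beta = beta
        self.gamma = gamma
        self.focal_reduction = focal_reduction
        self.lr_schedule = lr_schedule
        self.grad_clip = grad_clip
        self.target_train_dice = target_train_dice
        self.seed = seed
        self.verbose = verbose

    # ------------------------------------------------------------------
    def model_config(self) -> ModelConfig:
        return ModelConfig(
            in_channels=1, input_side=self.input_side, base_width=self.base_width,
            encoder_depth=self.encoder_depth, token_dim=self.token_dim,
            widening_rate=self.widening_rate, n_heads=self.n_heads,
            window_side=self.window_side, shift=self.shift, n_classes=self.n_classes,
            use_sliding_window=self.use_sliding_window,
        )

    def loss_config(self) -> LossConfig:
        return LossConfig(alpha=self.alpha, beta=self.beta, gamma=self.gamma,
                          reduction=self.focal_reduction)

    def train_config(self) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.learning_rate, batch_size=self.batch_size,
            max_epochs=self.max_epochs, patience=self.patience, loss=self.loss_config(),
            seed=self.seed, lr_schedule=self.lr_schedule, grad_clip=self.grad_clip,
            target_train_dice=self.target_train_dice, verbose=self.verbose,
        )

    def _validate_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 4 and X.shape[1] == 1:
            X = X[:, 0]
        if X.ndim != 3:
            raise ValueError(f"X must be (n, side, side), got shape {X.shape}")
        if X.shape[1] != self.input_side or X.shape[2] != self.input_side:
            raise ValueError(
                f"images are {X.shape[1]}x{X.shape[2]}, expected {self.input_side}"
            )
        if X.min() < 0 or X.max() > 1:
            raise ValueError("image intensities must lie in [0, 1]; normalize first")
        return X

    def _validate_y(self, y, n: int) -> np.ndarray:
        y = np.asarray(y)
        if y.shape != (n, self.input_side, self.input_side):
            raise ValueError(f"y shape {y.shape} does not match X")
        if y.min() < 0 or y.max() >= self.n_classes:
            raise ValueError(f"labels must lie in [0, {self.n_classes - 1}]")
        return y.astype(np.int64)

    # ------------------------------------------------------------------
    def fit(self, X, y, X_val=None, y_val=None):
        """Train from scratch; keeps the best-monitored-loss weights."""
        X = self._validate_X(X)
        y = self._validate_y(y, len(X))
        if X_val is not None:
            X_val = self._validate_X(X_val)
            y_val = self._validate_y(y_val, len(X_val))
        model = SWUNet(self.model_config(), seed=self.seed)
        log_fn = print if self.verbose else None
        history, best_state = fit_model(
            model, X, y, self.train_config(), X_val, y_val, log_fn=log_fn
        )
        model.load_state_dict(best_state)
        self.model_ = model
        self.history_ = history
        self.n_iter_ = len(history)
        self.classes_ = np.arange(self.n_classes)
        return self

    def predict_proba(self, X, chunk: int = 4) -> np.ndarray:
        """Per-pixel class probabilities ``(n, n_classes, side, side)``."""
        check_is_fitted(self, "model_")
        X = self._validate_X(X)
        out = []
        for i in range(0, len(X), chunk):
            logits = self.model_.predict_logits(X[i : i + chunk])
            shifted = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(shifted)
            out.append(e / e.sum(axis=1, keepdims=True))
        return np.concatenate(out, axis=0)

    def predict(self, X) -> np.ndarray:
        """Argmax label masks ``(n, side, side)``."""
        check_is_fitted(self, "model_")
        X = self._validate_X(X)
        out = []
        for i in range(0, len(X), 4):
            out.append(self.model_.predict_logits(X[i : i + 4]).argmax(axis=1))
        return np.concatenate(out, axis=0)

    def score(self, X, y) -> float:
        """Mean per-case Dice over foreground classes."""
        pred = self.predict(X)
        y = self._validate_y(y, len(pred))
        per_case = []
        for p, t in zip(pred, y):
            vals = [
                dice_coefficient(confusion(p, t, c)) for c in range(1, self.n_classes)
            ]
            per_case.append(np.mean(vals))
        return float(np.mean(per_case))

    def evaluate_loss(self, X, y) -> tuple:
        """(compound loss, hard Dice) on a dataset with the fitted weights."""
        check_is_fitted(self, "model_")
        X = self._validate_X(X)
        y = self._validate_y(y, len(X))
        return evaluate_loss(self.model_, X, y, self.loss_config())

    def n_parameters(self) -> int:
        if hasattr(self, "model_"):
            return self.model_.n_parameters()
        return count_parameters(self.model_config())

    # persistence -------------------------------------------------------
    def save(self, path) -> None:
        check_is_fitted(self, "model_")
        from .checkpoint import save_checkpoint

        save_checkpoint(
            path, self.model_,
            extra={"params": self.get_params(), "history": self.history_},
        )

    @classmethod
    def load(cls, path) -> "SWUNetSegmenter":
        from .checkpoint import load_checkpoint

        model, extra = load_checkpoint(path)
        est = cls(**extra.get("params", {})) if extra.get("params") else cls()
        est.model_ = model
        est.history_ = extra.get("history", [])
        est.n_iter_ = len(est.history_)
        est.classes_ = np.arange(model.cfg.n_classes)
        return est
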