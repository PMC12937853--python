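"""Scikit-learn style estimator wrapping the full pipeline.

`NotchSegmenter` is the user-facing surface: construct with
hyperparameters, `fit(X, y)` on an image stack and label masks,
`predict(X)` for argmax masks, `score(X, y)` for the mean Dice
coefficient.  It composes with sklearn model selection
(`get_params`/`set_params`/`clone`).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from sklearn.base import BaseEstimator

from . import metrics
from .augment import AugmentConfig
from .losses import LossConfig
from .network import NetworkConfig
from .phantom import ImageSample
from .train import TrainConfig, predict as _predict, train as _train


class NotchSegmenter(BaseEstimator):
    """Wavelet multi-scale contextual attention segmenter.

    Parameters mirror the underlying network/loss/training configs; see
    `NetworkConfig`, `LossConfig` and `TrainConfig` for semantics.

    Attributes (after `fit`)
    ------------------------
    network_ : the trained SegmentationNetwork
    history_ : per-epoch RunRecord
    classes_ : array of label values
    """

    def __init__(self, backbone="residual_cnn", stage_channels=(32, 64, 128, 256),
                 use_detail=True, use_wavelet=True, use_multiscale=True, use_attention=True,
                 n_classes=2, deep_supervision=True, detail_channels=32,
                 attention_resolution_cap=4096, alpha=0.5, beta=0.5, gamma=2.0,
                 lr_initial=1e-4, max_epochs=100, batch_size=8, patience=20,
                 augment=False, val_fraction=0.0, seed=0):
        self.backbone = backbone
        self.stage_channels = stage_channels
        self.use_detail = use_detail
        self.use_wavelet = use_wavelet
        self.use_multiscale = use_multiscale
        self.use_attention = use_attention
        self.n_classes = n_classes
        self.deep_supervision = deep_supervision
        self.detail_channels = detail_channels
        self.attention_resolution_cap = attention_resolution_cap
        self.alpha = alpha
        self.beta = beta
        self.gamma = gamma
        self.lr_initial = lr_initial
        self.max_epochs = max_epochs
        self.batch_size = batch_size
        self.patience = patience
        self.augment = augment
        self.val_fraction = val_fraction
        self.seed = seed

    def _train_config(self, input_size: int) -> TrainConfig:
        net = NetworkConfig(
            backbone=self.backbone,
            stage_channels=tuple(self.stage_channels),
            use_detail=self.use_detail,
            use_wavelet=self.use_wavelet,
            use_multiscale=self.use_multiscale,
            use_attention=self.use_attention,
            n_classes=self.n_classes,
            deep_supervision=self.deep_supervision,
            detail_channels=self.detail_channels,
            attention_resolution_cap=self.attention_resolution_cap,
            input_size_px=input_size,
        )
        return TrainConfig(
            network=net,
            loss=LossConfig(alpha=self.alpha, beta=self.beta, gamma=self.gamma),
            augmentation=AugmentConfig(enabled=self.augment),
            lr_initial=self.lr_initial,
            max_epochs=self.max_epochs,
            batch_size=self.batch_size,
            early_stop_patience_epochs=self.patience,
            seed=self.seed,
        )

    def fit(self, X, y, spacing_mm: float = 0.5):
        """Fit on (n, H, W) images and (n, H, W) integer masks.

        With `val_fraction` = 0 the training set itself is the early-
        stopping monitor (appropriate for deliberate overfitting runs);
        otherwise a seeded tail fraction is held out.
        """
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        if X.ndim != 3 or X.shape != y.shape:
            raise ValueError(
                f"expected matching (n, H, W) stacks, got {X.shape} / {y.shape}"
            )
        samples = [
            ImageSample(xi, yi.astype(np.int64), spacing_mm)
            for xi, yi in zip(X, y)
        ]
        if self.val_fraction > 0:
            rng = np.random.default_rng(self.seed)
            order = rng.permutation(len(samples))
            n_val = max(1, int(round(self.val_fraction * len(samples))))
            val = [samples[i] for i in order[:n_val]]
            tr = [samples[i] for i in order[n_val:]]
        else:
            tr, val = samples, samples
        cfg = self._train_config(X.shape[-1])
        self.network_, self.history_ = _train(cfg, tr, val)
        self.classes_ = np.arange(self.n_classes)
        return self

    def predict(self, X) -> np.ndarray:
        self._check_fitted()
        return _predict(self.network_, np.asarray(X, dtype=np.float64))

    def predict_proba(self, X) -> np.ndarray:
        self._check_fitted()
        return self.network_.predict_proba(np.asarray(X, dtype=np.float64))

    def score(self, X, y) -> float:
        """Mean foreground Dice coefficient over the stack."""
        self._check_fitted()
        pred = self.predict(X)
        y = np.asarray(y)
        scores = []
        for p, t in zip(pred, y):
            if self.n_classes == 2:
                scores.append(metrics.dsc(metrics.confusion_counts(p, t, 1)))
            else:
                scores.append(
                    metrics.evaluate_multiclass(p, t, 1.0, self.n_classes).dsc
                )
        return float(np.mean(scores))

    def _check_fitted(self):
        if not hasattr(self, "network_"):
            raise RuntimeError("this NotchSegmenter instance is not fitted yet")
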