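"""Scikit-learn style estimator facade.

`TractFormerSegmenter` wraps network construction, progressive-patch
training and whole-volume inference behind the familiar
``fit`` / ``predict`` / ``predict_proba`` / ``score`` surface, so the
segmenter composes with scikit-learn model selection utilities. The
functional layer (:mod:`tractformer3d.model`, :mod:`tractformer3d.train`,
:mod:`tractformer3d.evaluate`) remains available underneath.
"""
from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .evaluate import dice_score
from .io_volumes import PeakVolume, TractLabelVolume
from .model import NetworkConfig, build_network, threshold_probabilities
from .phantom import Phantom
from .train import TrainingSchedule, run_training

__all__ = ["TractFormerSegmenter"]


def _as_peaks(x) -> PeakVolume:
    return x if isinstance(x, PeakVolume) else PeakVolume(np.asarray(x))


def _as_labels(y) -> TractLabelVolume:
    return y if isinstance(y, TractLabelVolume) else TractLabelVolume(np.asarray(y))


class TractFormerSegmenter(BaseEstimator):
    """Multi-label volumetric tract segmenter.

    Parameters mirror the network configuration and the training schedule;
    fitted state lives in trailing-underscore attributes (``net_``,
    ``history_``). ``X`` is a sequence of H x W x D x 9 peak volumes
    (arrays or :class:`PeakVolume`); ``y`` is the paired sequence of
    H x W x D x T binary label volumes.
    """

    def __init__(self, level_channels=(36, 72, 144, 288),
                 blocks_per_level=(1, 2, 4, 8), heads_per_level=(1, 2, 4, 8),
                 ffn_expansion=None, pool_factor=2, use_norm=True,
                 resample_mode="separable", skip_fusion="add",
                 decoder_blocks_mirrored=False, threshold=0.5,
                 stages=((64, 6, 100), (80, 2, 100)),
                 iterations_per_epoch=1000, lr_start=3e-4, lr_end=1e-6,
                 weight_decay=1e-4, nominal_patch=64, random_state=0):
        self.level_channels = level_channels
        self.blocks_per_level = blocks_per_level
        self.heads_per_level = heads_per_level
        self.ffn_expansion = ffn_expansion
        self.pool_factor = pool_factor
        self.use_norm = use_norm
        self.resample_mode = resample_mode
        self.skip_fusion = skip_fusion
        self.decoder_blocks_mirrored = decoder_blocks_mirrored
        self.threshold = threshold
        self.stages = stages
        self.iterations_per_epoch = iterations_per_epoch
        self.lr_start = lr_start
        self.lr_end = lr_end
        self.weight_decay = weight_decay
        self.nominal_patch = nominal_patch
        self.random_state = random_state

    def _config(self, out_channels: int) -> NetworkConfig:
        kw = dict(
            out_channels=out_channels,
            level_channels=tuple(self.level_channels),
            blocks_per_level=tuple(self.blocks_per_level),
            heads_per_level=tuple(self.heads_per_level),
            pool_factor=self.pool_factor,
            use_norm=self.use_norm,
            resample_mode=self.resample_mode,
            skip_fusion=self.skip_fusion,
            decoder_blocks_mirrored=self.decoder_blocks_mirrored,
            threshold=self.threshold,
            nominal_patch=self.nominal_patch,
        )
        if self.ffn_expansion is not None:
            kw["ffn_expansion"] = self.ffn_expansion
        return NetworkConfig(**kw)

    def fit(self, X, y, validation=None):
        pairs = [Phantom(peaks=_as_peaks(x), labels=_as_labels(t))
                 for x, t in zip(X, y)]
        if not pairs:
            raise ValueError("need at least one training volume")
        out_channels = pairs[0].labels.n_tracts
        self.config_ = self._config(out_channels)
        self.net_ = build_network(self.config_, self.random_state)
        schedule = TrainingSchedule(
            stages=tuple(tuple(s) for s in self.stages),
            iterations_per_epoch=self.iterations_per_epoch,
            lr_start=self.lr_start, lr_end=self.lr_end,
            weight_decay=self.weight_decay, seed=self.random_state,
        )
        result = run_training(self.net_, pairs, schedule, validation=validation)
        self.history_ = result.history
        self.n_parameters_ = self.net_.n_parameters()
        return self

    def predict_proba(self, X):
        self._check_fitted()
        return [self.net_.predict_proba(_as_peaks(x)) for x in X]

    def predict(self, X):
        self._check_fitted()
        return [threshold_probabilities(p, self.threshold)
                for p in self.predict_proba(X)]

    def score(self, X, y):
        """Mean per-tract Dice over the given volumes."""
        self._check_fitted()
        scores = []
        for pred, t in zip(self.predict(X), y):
            gt = _as_labels(t).data
            for c in range(gt.shape[-1]):
                scores.append(dice_score(pred[..., c], gt[..., c]))
        return float(np.mean(scores))

    def _check_fitted(self):
        if not hasattr(self, "net_"):
            raise RuntimeError("estimator is not fitted; call fit() first")
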