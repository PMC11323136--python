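"""scikit-learn style estimator wrapping the SEF-UNet training pipeline.

``SEFUNetSegmenter`` follows the sklearn contract: all hyperparameters are
plain ``__init__`` arguments (so ``get_params`` / ``set_params`` / ``clone``
work), ``fit`` consumes arrays of normalized axial slices and label masks,
fitted state lives in trailing-underscore attributes, and ``predict``
returns per-pixel label maps.  3-D cases go through ``predict_volume``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .config import LossConfig, ModelConfig, TrainConfig
from .data import CTVolume, LabelVolume, SlicePair
from .inference import predict_slice, predict_volume
from .metrics import dice_coefficient
from .train import TrainResult, train


class SEFUNetSegmenter(BaseEstimator):
    """Multi-organ 2-D slice segmenter with a 3-D volume interface.

    Parameters mirror the architecture and optimization configuration;
    see :class:`sefunet.config.ModelConfig` and
    :class:`sefunet.config.TrainConfig` for semantics and defaults.
    """

    def __init__(self, depths=(3, 3, 9, 3), dims=(64, 128, 320, 512),
                 decoder_channels=(256, 128, 64, 16), num_classes=9,
                 input_size=224, se_reduction=4, mixer_expansion=1.75,
                 mlp_ratio=3.125, dw_kernel_encoder=5, dw_kernel_decoder=3,
                 decoder_variant="dcup", n_stages=4, activation="relu",
                 learning_rate=0.01, momentum=0.9, weight_decay=1e-4,
                 batch_size=24, epochs=150, max_iterations=None,
                 augment=True, epsilon=1e-5, seed=1234):
        self.depths = depths
        self.dims = dims
        self.decoder_channels = decoder_channels
        self.num_classes = num_classes
        self.input_size = input_size
        self.se_reduction = se_reduction
        self.mixer_expansion = mixer_expansion
        self.mlp_ratio = mlp_ratio
        self.dw_kernel_encoder = dw_kernel_encoder
        self.dw_kernel_decoder = dw_kernel_decoder
        self.decoder_variant = decoder_variant
        self.n_stages = n_stages
        self.activation = activation
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.batch_size = batch_size
        self.epochs = epochs
        self.max_iterations = max_iterations
        self.augment = augment
        self.epsilon = epsilon
        self.seed = seed

    # -- configuration plumbing ---------------------------------------
    def _model_config(self) -> ModelConfig:
        return ModelConfig(
            depths=self.depths, dims=self.dims,
            decoder_channels=self.decoder_channels,
            num_classes=self.num_classes, in_channels=1,
            input_size=self.input_size, se_reduction=self.se_reduction,
            mixer_expansion=self.mixer_expansion, mlp_ratio=self.mlp_ratio,
            dw_kernel_encoder=self.dw_kernel_encoder,
            dw_kernel_decoder=self.dw_kernel_decoder,
            decoder_variant=self.decoder_variant, n_stages=self.n_stages,
            activation=self.activation, seed=self.seed)

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            learning_rate=self.learning_rate, momentum=self.momentum,
            weight_decay=self.weight_decay, batch_size=self.batch_size,
            epochs=self.epochs, max_iterations=self.max_iterations,
            seed=self.seed, augment=self.augment,
            model=self._model_config(), loss=LossConfig(epsilon=self.epsilon))

    # -- sklearn interface --------------------------------------------
    def fit(self, X, y, verbose: bool = False):
        """Train on slices ``X`` (n, H, W) in [0, 1] with masks ``y``."""
        X = np.asarray(X, np.float32)
        y = np.asarray(y)
        if X.ndim != 3 or X.shape != y.shape:
            raise ValueError("X must be (n, H, W) with matching label masks y")
        if X.shape[1] != self.input_size or X.shape[2] != self.input_size:
            raise ValueError(
                f"slices must already be {self.input_size}x{self.input_size}")
        slices = [SlicePair(X[i], y[i].astype(np.int16), slice_index=i)
                  for i in range(len(X))]
        result: TrainResult = train(self._train_config(), slices=slices,
                                    log_fn=print if verbose else None)
        self.model_ = result.model
        self.history_ = result.history
        self.iteration_losses_ = result.iteration_losses
        self.n_iter_ = len(result.iteration_losses)
        self.classes_ = np.arange(self.num_classes)
        return self

    def predict(self, X) -> np.ndarray:
        """Per-pixel label maps for slices ``X`` (n, H, W) in [0, 1]."""
        check_is_fitted(self, "model_")
        X = np.asarray(X, np.float32)
        single = X.ndim == 2
        if single:
            X = X[None]
        out = np.stack([predict_slice(self.model_, img) for img in X])
        return out[0] if single else out

    def predict_volume(self, volume: CTVolume) -> LabelVolume:
        """Slice-wise prediction of a raw HU volume, stacked to 3-D."""
        check_is_fitted(self, "model_")
        return predict_volume(self.model_, volume)

    def score(self, X, y) -> float:
        """Mean foreground Dice over the given slices (fraction in [0, 1])."""
        check_is_fitted(self, "model_")
        pred = self.predict(X)
        y = np.asarray(y)
        scores = [dice_coefficient(pred == c, y == c)
                  for c in range(1, self.num_classes) if (y == c).any()]
        return float(np.mean(scores)) if scores else 1.0
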