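"""Scikit-learn style front end for the dual-head decomposition model.

`DualHeadPix2Pix` is a paired image-to-image regressor: ``fit`` takes
conventional projections X (n, H, W) uint8 and stacked material targets
y (n, 2, H, W) uint8 (bone channel first), ``predict`` returns the two
decomposed uint8 channels.  Hyper-parameters mirror TrainConfig, so the
estimator composes with sklearn model selection while the plain
Trainer/function API underneath remains available for script use.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .losses import LossWeights, LRScheduleSpec
from .trainer import TrainConfig, Trainer


class DualHeadPix2Pix(BaseEstimator):
    """Conditional GAN decomposing one projection into bone + iodine images.

    Parameters follow the training configuration: `epochs`/`batch_size`
    control the loop, `lambda_*` the loss weights, `depth`/`*_width` the
    network capacity, and the warm-up/decay schedule the learning rate.
    A `single_head` estimator keeps one decoder and one discriminator
    (the conventional one-material baseline) and ignores `lambda_excl`.
    """

    def __init__(self, epochs: int = 10, batch_size: int = 4,
                 lambda_adv: float = 1.0, lambda_rec: float = 100.0,
                 lambda_excl: float = 100.0,
                 warmup_iters: int = 10_000, peak_lr: float = 9e-4,
                 lr_decay: float = 0.9, lr_floor: float = 5e-6,
                 depth: int = 8, gen_base_width: int = 64,
                 disc_base_width: int = 64, disc_n_strided: int = 3,
                 noise_kind: str = "dropout",
                 single_head: bool = False, single_head_target: str = "bone",
                 random_state: int = 0):
        self.epochs = epochs
        self.batch_size = batch_size
        self.lambda_adv = lambda_adv
        self.lambda_rec = lambda_rec
        self.lambda_excl = lambda_excl
        self.warmup_iters = warmup_iters
        self.peak_lr = peak_lr
        self.lr_decay = lr_decay
        self.lr_floor = lr_floor
        self.depth = depth
        self.gen_base_width = gen_base_width
        self.disc_base_width = disc_base_width
        self.disc_n_strided = disc_n_strided
        self.noise_kind = noise_kind
        self.single_head = single_head
        self.single_head_target = single_head_target
        self.random_state = random_state

    def _config(self) -> TrainConfig:
        return TrainConfig(
            batch_size=self.batch_size, epochs=self.epochs,
            schedule=LRScheduleSpec(warmup_iters=self.warmup_iters,
                                    peak=self.peak_lr, decay=self.lr_decay,
                                    floor=self.lr_floor),
            weights=LossWeights(lambda_adv=self.lambda_adv,
                                lambda_rec=self.lambda_rec,
                                lambda_excl=self.lambda_excl),
            seed=self.random_state, depth=self.depth,
            gen_base_width=self.gen_base_width,
            disc_base_width=self.disc_base_width,
            disc_n_strided=self.disc_n_strided,
            noise_kind=self.noise_kind, single_head=self.single_head,
            single_head_target=self.single_head_target)

    @staticmethod
    def _validate(X, y=None):
        X = np.asarray(X)
        if X.ndim != 3:
            raise ValueError("X must have shape (n_images, rows, cols)")
        if y is not None:
            y = np.asarray(y)
            if y.shape != (X.shape[0], 2) + X.shape[1:]:
                raise ValueError("y must have shape (n_images, 2, rows, cols) "
                                 "with the bone channel first")
        return X, y

    def fit(self, X, y):
        X, y = self._validate(X, y)
        self.trainer_ = Trainer(self._config())
        self.trainer_.fit_arrays(X, y[:, 0], y[:, 1])
        self.history_ = self.trainer_.history
        self.n_parameters_ = self.trainer_.generator.n_parameters()
        return self

    def predict(self, X):
        check_is_fitted(self, "trainer_")
        X, _ = self._validate(X)
        bone, iodine = self.trainer_.predict(X)
        if self.single_head:
            out = bone if bone is not None else iodine
            return out[:, None]
        return np.stack([bone, iodine], axis=1)

    def score(self, X, y):
        """Negative mean MAE over both channels (higher is better)."""
        from .metrics import mae

        X, y = self._validate(X, y)
        pred = self.predict(X)
        vals = [mae(pred[i, c], y[i, c])
                for i in range(X.shape[0]) for c in range(pred.shape[1])]
        return -float(np.mean(vals))
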