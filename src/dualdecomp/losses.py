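"""Objective terms and learning-rate schedule for the dual-head GAN.

Three loss components per generator update:

* adversarial (non-saturating, per patch, computed in logit space so it is
  overflow-safe),
* reconstruction (mean absolute error against the paired ground truth,
  summed over the two heads),
* mutual exclusivity: for each head, the mean L1 distance to the *other*
  material's ground truth is pushed up; applying the logistic function to
  each scalar distance and rewarding its complement gives a bounded term

      L_excl = (1 - sigmoid(d_bone)) + (1 - sigmoid(d_iodine))  in (0, 2),

  which equals 1.0 when both cross-distances are zero and tends to 0 as
  the heads' outputs separate.  Distances are measured in the model's
  normalized [-1, 1] intensity range, keeping the sigmoid's argument in a
  regime with usable gradient.

The schedule ramps linearly from 0 to the peak rate over the warm-up
iterations, then multiplies by a decay factor per completed epoch, floored
at a minimum rate.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .autodiff import Tensor


@dataclasses.dataclass(frozen=True)
class LossWeights:
    """Weights of the adversarial / reconstruction / exclusivity terms."""

    lambda_adv: float = 1.0
    lambda_rec: float = 100.0
    lambda_excl: float = 100.0

    def __post_init__(self):
        for v in (self.lambda_adv, self.lambda_rec, self.lambda_excl):
            if not (np.isfinite(v) and v >= 0):
                raise ValueError("loss weights must be finite and nonnegative")


@dataclasses.dataclass(frozen=True)
class LRScheduleSpec:
    warmup_iters: int = 10_000
    peak: float = 9e-4
    decay: float = 0.9
    floor: float = 5e-6

    def __post_init__(self):
        if not (0 < self.floor < self.peak):
            raise ValueError("need 0 < floor < peak")
        if self.warmup_iters < 1:
            raise ValueError("warmup must span at least one iteration")
        if not (0 < self.decay < 1):
            raise ValueError("decay factor must lie in (0, 1)")


def lr_at(step: int, epochs_since_warmup: int, spec: LRScheduleSpec) -> float:
    """Learning rate at a global step.

    During warm-up (step < warmup_iters) the rate rises linearly from 0
    to the peak; afterwards it is peak * decay^k floored at the minimum,
    where k = ``epochs_since_warmup`` counts epochs completed after the
    warm-up boundary.  Continuous at the boundary (k = 0 gives the peak).
    """
    if step < 0:
        raise ValueError("step must be nonnegative")
    if step < spec.warmup_iters:
        return spec.peak * step / spec.warmup_iters
    k = max(0, int(epochs_since_warmup))
    return max(spec.floor, spec.peak * spec.decay ** k)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def adversarial_losses(real_logits, fake_logits) -> tuple[Tensor, Tensor]:
    """Patch-averaged BCE-with-logits discriminator and generator losses.

    d_loss = -mean log s(real) - mean log(1 - s(fake));
    g_loss = -mean log s(fake)  (non-saturating form).
    Caller detaches ``fake_logits`` for the discriminator side.
    """
    real, fake = _as_tensor(real_logits), _as_tensor(fake_logits)
    if real.shape != fake.shape:
        raise ValueError("real and fake logit grids must share a shape")
    d_loss = (-real).softplus().mean() + fake.softplus().mean()
    g_loss = (-fake).softplus().mean()
    return d_loss, g_loss


def reconstruction_loss(pred, gt) -> Tensor:
    """Mean absolute difference over pixels (one head's L1 term)."""
    p, g = _as_tensor(pred), _as_tensor(gt)
    if p.shape != g.shape:
        raise ValueError("prediction and ground truth must share a shape")
    return (p - g).abs().mean()


def mutual_exclusivity_loss(bone_pred, iodine_pred, bone_gt, iodine_gt):
    """Bounded cross-material reward; returns (d_bone, d_iodine, loss).

    d_bone is the bone head's mean L1 distance to the iodine ground
    truth, d_iodine the iodine head's distance to the bone ground truth;
    the loss (1-s(d_bone)) + (1-s(d_iodine)) lies in (0, 2) and decreases
    monotonically in each distance.
    """
    bp, ip = _as_tensor(bone_pred), _as_tensor(iodine_pred)
    bg, ig = _as_tensor(bone_gt), _as_tensor(iodine_gt)
    if not (bp.shape == ip.shape == bg.shape == ig.shape):
        raise ValueError("all four images must share a shape")
    d_bone = (ig - bp).abs().mean()
    d_iodine = (bg - ip).abs().mean()
    one = Tensor(np.asarray(1.0, dtype=np.float64))
    loss = (one - d_bone.sigmoid()) + (one - d_iodine.sigmoid())
    return d_bone, d_iodine, loss


def total_generator_loss(adv, rec, excl, weights: LossWeights) -> Tensor:
    """Weighted sum of the generator-side components."""
    return (weights.lambda_adv * _as_tensor(adv)
            + weights.lambda_rec * _as_tensor(rec)
            + weights.lambda_excl * _as_tensor(excl))
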