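"""Adversarial training loop for the dual-head decomposition GAN.

Each iteration updates, in order: the bone discriminator on
(condition, real bone) vs (condition, detached bone prediction); the
iodine discriminator likewise; then the generator on

    lambda_adv * (adv_b + adv_c) + lambda_rec * (L1_b + L1_c)
                                 + lambda_excl * exclusivity,

with the discriminators' parameters frozen so no gradient is spent on
them during the generator pass.  A single learning-rate schedule drives
the Adam optimizers of all three networks.

Every random stream (initialization, dropout noise, batch shuffling) is
spawned from the one config seed, and optimizer/RNG/batch-norm state is
checkpointed, so identical config + seed reproduce identical histories
and a resumed run is step-for-step equivalent to an uninterrupted one.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import data as dio
from . import losses as L
from .autodiff import Tensor
from .networks import (DiscriminatorSpec, DualHeadGenerator, GeneratorSpec,
                       PatchDiscriminator)

CHECKPOINT_VERSION = 1


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 4
    epochs: int = 333
    betas: tuple[float, float] = (0.5, 0.999)
    schedule: L.LRScheduleSpec = dataclasses.field(default_factory=L.LRScheduleSpec)
    weights: L.LossWeights = dataclasses.field(default_factory=L.LossWeights)
    seed: int = 0
    depth: int = 8
    gen_base_width: int = 64
    disc_base_width: int = 64
    disc_n_strided: int = 3
    noise_kind: str = "dropout"
    dropout: float = 0.5
    single_head: bool = False
    single_head_target: str = "bone"
    checkpoint_every: int = 0          # epochs; 0 = only final

    def __post_init__(self):
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch size and epochs must be positive")
        if self.single_head_target not in ("bone", "iodine"):
            raise ValueError("single_head_target must be 'bone' or 'iodine'")

    def generator_spec(self) -> GeneratorSpec:
        return GeneratorSpec(depth=self.depth, base_width=self.gen_base_width,
                             dropout=self.dropout, noise_kind=self.noise_kind,
                             heads=1 if self.single_head else 2)

    def discriminator_spec(self) -> DiscriminatorSpec:
        return DiscriminatorSpec(in_channels=2, n_strided=self.disc_n_strided,
                                 base_width=self.disc_base_width)


_CONFIG_SCHEMA = {f.name for f in dataclasses.fields(TrainConfig)}


def config_from_dict(d: dict) -> TrainConfig:
    """Build a TrainConfig from a flat mapping; unknown keys are an error."""
    d = dict(d)
    unknown = set(d) - _CONFIG_SCHEMA
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    if "schedule" in d and isinstance(d["schedule"], dict):
        d["schedule"] = L.LRScheduleSpec(**d["schedule"])
    if "weights" in d and isinstance(d["weights"], dict):
        d["weights"] = L.LossWeights(**d["weights"])
    if "betas" in d:
        d["betas"] = tuple(d["betas"])
    return TrainConfig(**d)


def _config_to_dict(cfg: TrainConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["betas"] = list(d["betas"])
    return d


def _freeze(params, flag: bool):
    for p in params:
        p.requires_grad = flag


def _check_finite(name: str, value: float):
    if not np.isfinite(value):
        raise RuntimeError(f"non-finite loss component '{name}' ({value}); aborting")


class Trainer:
    """Owns the three networks, their optimizers and all RNG streams."""

    def __init__(self, config: TrainConfig):
        from . import nn

        self.config = config
        ss = np.random.SeedSequence(config.seed)
        s_g, s_db, s_dc, s_noise, s_shuffle = ss.spawn(5)
        self.generator = DualHeadGenerator(config.generator_spec(),
                                           init_seed=int(s_g.generate_state(1)[0]))
        dspec = config.discriminator_spec()
        self.disc_b = PatchDiscriminator(dspec, init_seed=int(s_db.generate_state(1)[0]))
        self.disc_c = (None if config.single_head
                       else PatchDiscriminator(dspec, init_seed=int(s_dc.generate_state(1)[0])))
        self.opt_g = nn.Adam(self.generator.parameters(), betas=config.betas)
        self.opt_db = nn.Adam(self.disc_b.parameters(), betas=config.betas)
        self.opt_dc = (None if self.disc_c is None
                       else nn.Adam(self.disc_c.parameters(), betas=config.betas))
        self.noise_rng = np.random.default_rng(s_noise)
        self.shuffle_rng = np.random.default_rng(s_shuffle)
        self.global_step = 0
        self.epochs_done = 0
        self.epochs_since_warmup = 0
        self.history: list[dict] = []
        self.epoch_log: list[dict] = []

    # ------------------------------------------------------------------
    def current_lr(self) -> float:
        return L.lr_at(self.global_step, self.epochs_since_warmup, self.config.schedule)

    def train_step(self, conv: np.ndarray, bone_gt: np.ndarray,
                   iodine_gt: np.ndarray) -> dict:
        """One D_b / D_c / G update on a normalized (N,1,H,W) batch."""
        cfg = self.config
        lr = self.current_lr()
        conv_t = Tensor(conv)
        report = {"step": self.global_step, "lr": lr}

        self.generator.train()
        bone_pred, iodine_pred = self.generator(conv_t, self.noise_rng,
                                                noise_active=True)
        if cfg.single_head and cfg.single_head_target == "iodine":
            # the lone head is trained against the requested material
            bone_pred, iodine_pred = None, bone_pred
            heads = [("c", iodine_pred, Tensor(iodine_gt), self.disc_b, self.opt_db)]
        elif cfg.single_head:
            heads = [("b", bone_pred, Tensor(bone_gt), self.disc_b, self.opt_db)]
        else:
            heads = [("b", bone_pred, Tensor(bone_gt), self.disc_b, self.opt_db),
                     ("c", iodine_pred, Tensor(iodine_gt), self.disc_c, self.opt_dc)]

        # discriminator updates (generator output detached)
        for tag, pred, gt, disc, opt in heads:
            disc.train()
            real_logits = disc(conv_t, gt)
            fake_logits = disc(conv_t, pred.detach())
            d_loss, _ = L.adversarial_losses(real_logits, fake_logits)
            _check_finite(f"d_{tag}", float(d_loss.data))
            disc.zero_grad()
            d_loss.backward()
            opt.step(lr)
            report[f"d_{tag}"] = float(d_loss.data)

        # generator update with discriminators frozen
        frozen = [p for _, _, _, disc, _ in heads for p in disc.parameters()]
        _freeze(frozen, False)
        try:
            g_adv_total = None
            rec_total = None
            for tag, pred, gt, disc, _ in heads:
                fake_logits = disc(conv_t, pred)
                _, g_adv = L.adversarial_losses(fake_logits.detach(), fake_logits)
                rec = L.reconstruction_loss(pred, gt)
                report[f"g_adv_{tag}"] = float(g_adv.data)
                report[f"l2_{tag}"] = float(rec.data)
                g_adv_total = g_adv if g_adv_total is None else g_adv_total + g_adv
                rec_total = rec if rec_total is None else rec_total + rec

            if cfg.single_head:
                excl = Tensor(np.asarray(0.0, dtype=np.float64))
                report["l3_b"] = report["l3_c"] = report["l3"] = 0.0
            else:
                d_b, d_c, excl = L.mutual_exclusivity_loss(
                    bone_pred, iodine_pred, Tensor(bone_gt), Tensor(iodine_gt))
                report["l3_b"] = float(d_b.data)
                report["l3_c"] = float(d_c.data)
                report["l3"] = float(excl.data)
            total = L.total_generator_loss(g_adv_total, rec_total, excl, cfg.weights)
            report["l2"] = report.get("l2_b", 0.0) + report.get("l2_c", 0.0)
            report["g_adv"] = report.get("g_adv_b", 0.0) + report.get("g_adv_c", 0.0)
            report["total"] = float(total.data)
            _check_finite("total", report["total"])
            self.generator.zero_grad()
            total.backward()
            self.opt_g.step(lr)
        finally:
            _freeze(frozen, True)

        self.global_step += 1
        return report

    # ------------------------------------------------------------------
    def fit_arrays(self, conv8: np.ndarray, bone8: np.ndarray, iodine8: np.ndarray,
                   epochs: int | None = None, out_dir=None,
                   log_fn=None) -> list[dict]:
        """Train on stacked uint8 arrays (n, H, W) up to `epochs` total epochs."""
        cfg = self.config
        n = conv8.shape[0]
        if n == 0:
            raise ValueError("empty training set")
        conv = dio.normalize(conv8)[:, None]
        bone = dio.normalize(bone8)[:, None]
        iodine = dio.normalize(iodine8)[:, None]
        total_epochs = cfg.epochs if epochs is None else epochs
        bs = cfg.batch_size
        while self.epochs_done < total_epochs:
            order = self.shuffle_rng.permutation(n)
            for start in range(0, n, bs):
                idx = order[start:start + bs]
                rep = self.train_step(conv[idx], bone[idx], iodine[idx])
                self.history.append(rep)
                if log_fn is not None:
                    log_fn(rep)
            self.epochs_done += 1
            if self.global_step >= cfg.schedule.warmup_iters:
                self.epochs_since_warmup += 1
            recent = self.history[-max(1, n // bs):]
            self.epoch_log.append({
                "epoch": self.epochs_done,
                "mean_total": float(np.mean([r["total"] for r in recent])),
                "mean_l2": float(np.mean([r["l2"] for r in recent])),
                "lr": recent[-1]["lr"],
            })
            if (out_dir is not None and cfg.checkpoint_every
                    and self.epochs_done % cfg.checkpoint_every == 0):
                self.save_checkpoint(Path(out_dir) / f"ckpt_ep{self.epochs_done:04d}.npz")
        if out_dir is not None:
            self.save_checkpoint(Path(out_dir) / "ckpt_final.npz")
            with open(Path(out_dir) / "history.json", "w") as fh:
                json.dump(self.history, fh)
        return self.history

    # ------------------------------------------------------------------
    def predict(self, conv8: np.ndarray) -> tuple[np.ndarray, np.ndarray | None]:
        """Deterministic inference on uint8 (n, H, W); returns uint8 maps."""
        self.generator.eval()
        div = 2 ** self.config.depth
        h, w = conv8.shape[1], conv8.shape[2]
        if h % div or w % div:
            raise ValueError(f"input spatial dims must be divisible by {div}")
        first, second = [], []
        for i in range(conv8.shape[0]):
            x = Tensor(dio.normalize(conv8[i])[None, None])
            bp, ip = self.generator(x, noise_rng=None, noise_active=False)
            first.append(dio.denormalize(bp.data[0, 0]))
            if ip is not None:
                second.append(dio.denormalize(ip.data[0, 0]))
        self.generator.train()
        if self.config.single_head:
            # the lone head predicts the configured target material
            out = np.stack(first)
            if self.config.single_head_target == "iodine":
                return None, out
            return out, None
        return np.stack(first), np.stack(second)

    # ------------------------------------------------------------------
    def save_checkpoint(self, path):
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        meta = {
            "version": CHECKPOINT_VERSION,
            "config": _config_to_dict(self.config),
            "global_step": self.global_step,
            "epochs_done": self.epochs_done,
            "epochs_since_warmup": self.epochs_since_warmup,
            "noise_rng": self.noise_rng.bit_generator.state,
            "shuffle_rng": self.shuffle_rng.bit_generator.state,
            "history": self.history,
            "epoch_log": self.epoch_log,
        }
        arrays = {"meta_json": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)}
        for prefix, module in self._named_modules():
            for k, v in module.state_dict().items():
                arrays[f"{prefix}/{k}"] = v
        for prefix, opt in self._named_opts():
            st = opt.state_dict()
            arrays[f"{prefix}/t"] = np.asarray(st["t"])
            for i, a in enumerate(st["m"]):
                arrays[f"{prefix}/m{i}"] = a
            for i, a in enumerate(st["v"]):
                arrays[f"{prefix}/v{i}"] = a
        np.savez(path, **arrays)

    def _named_modules(self):
        mods = [("generator", self.generator), ("disc_b", self.disc_b)]
        if self.disc_c is not None:
            mods.append(("disc_c", self.disc_c))
        return mods

    def _named_opts(self):
        opts = [("opt_g", self.opt_g), ("opt_db", self.opt_db)]
        if self.opt_dc is not None:
            opts.append(("opt_dc", self.opt_dc))
        return opts

    @classmethod
    def load_checkpoint(cls, path) -> "Trainer":
        with np.load(Path(path)) as z:
            arrays = {k: z[k] for k in z.files}
        meta = json.loads(bytes(arrays.pop("meta_json")).decode())
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta.get('version')!r}; "
                             f"expected {CHECKPOINT_VERSION}")
        trainer = cls(config_from_dict(meta["config"]))
        for prefix, module in trainer._named_modules():
            state = {k[len(prefix) + 1:]: v for k, v in arrays.items()
                     if k.startswith(prefix + "/")}
            module.load_state_dict(state)
        for prefix, opt in trainer._named_opts():
            n = len(opt.m)
            opt.load_state_dict({
                "t": int(arrays[f"{prefix}/t"]),
                "m": [arrays[f"{prefix}/m{i}"] for i in range(n)],
                "v": [arrays[f"{prefix}/v{i}"] for i in range(n)],
            })
        trainer.global_step = int(meta["global_step"])
        trainer.epochs_done = int(meta["epochs_done"])
        trainer.epochs_since_warmup = int(meta["epochs_since_warmup"])
        trainer.noise_rng.bit_generator.state = meta["noise_rng"]
        trainer.shuffle_rng.bit_generator.state = meta["shuffle_rng"]
        trainer.history = meta["history"]
        trainer.epoch_log = meta["epoch_log"]
        return trainer


# ---------------------------------------------------------------------------
# module-level conveniences


def fit(split: dio.DatasetSplit, config: TrainConfig, out_dir=None) -> Trainer:
    """Train on a DatasetSplit's training records; returns the Trainer."""
    if not split.train:
        raise ValueError("empty train split")
    conv, bone, iodine = dio.load_split_arrays(split.train)
    trainer = Trainer(config)
    trainer.fit_arrays(conv, bone, iodine, out_dir=out_dir)
    return trainer


def decompose(checkpoint_path, conv_images: np.ndarray,
              crop_to: tuple[int, int] | None = None):
    """Inference from a checkpoint; optional center-crop first.

    Returns (bone8, iodine8) stacks; iodine8 is None for a single-head
    checkpoint.  Noise is disabled, so outputs are deterministic.
    """
    trainer = Trainer.load_checkpoint(checkpoint_path)
    if crop_to is not None:
        conv_images = np.stack([dio.center_crop(im, crop_to) for im in conv_images])
    return trainer.predict(conv_images)
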