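"""Projection dataset I/O: manifests, per-subject splits, crops, normalization.

All images are 8-bit single-channel PNGs in row-major (row, col)
coordinates with the origin at the top-left; that convention is shared
with the line-profile analysis in :mod:`dualdecomp.metrics`.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .phantom import MANIFEST_COLUMNS


@dataclasses.dataclass(frozen=True)
class SampleRecord:
    subject: str
    angle: int
    conv_path: Path
    bone_path: Path
    iodine_path: Path
    seed: int
    windows: dict


@dataclasses.dataclass
class DatasetSplit:
    """Per-subject stratified train/test partition of the sample records."""

    train: list[SampleRecord]
    test: list[SampleRecord]
    seed: int
    fraction: float


def load_png(path) -> np.ndarray:
    img = Image.open(path)
    if img.mode != "L":
        img = img.convert("L")
    return np.asarray(img, dtype=np.uint8)


def save_png(path, image8: np.ndarray):
    if image8.dtype != np.uint8:
        raise ValueError("expected uint8 image")
    Image.fromarray(image8, mode="L").save(path)


def load_manifest(path) -> list[SampleRecord]:
    """Parse a dataset manifest into records, verifying schema and files."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest schema error: missing column(s) {missing}")
    base = path.parent
    records = []
    for row in df.itertuples(index=False):
        paths = {ch: base / getattr(row, f"{ch}_path")
                 for ch in ("conv", "bone", "iodine")}
        for ch, p in paths.items():
            if not p.exists():
                raise FileNotFoundError(
                    f"missing {ch} image for subject {row.subject} angle {row.angle}: {p}")
        windows = {k: float(getattr(row, k)) for k in MANIFEST_COLUMNS
                   if k.startswith("window_")}
        records.append(SampleRecord(subject=str(row.subject), angle=int(row.angle),
                                    conv_path=paths["conv"], bone_path=paths["bone"],
                                    iodine_path=paths["iodine"], seed=int(row.seed),
                                    windows=windows))
    return records


def split_per_subject(records: list[SampleRecord], fraction: float,
                      seed: int) -> DatasetSplit:
    """Shuffle each subject's views with `seed`; first ceil(fraction*n) train.

    Stratifying within subjects keeps every animal represented in both
    partitions, matching an 80/20-per-subject protocol.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie strictly between 0 and 1")
    subjects: dict[str, list[SampleRecord]] = {}
    for r in records:
        subjects.setdefault(r.subject, []).append(r)
    rng = np.random.default_rng(seed)
    train, test = [], []
    for subject in sorted(subjects):
        recs = sorted(subjects[subject], key=lambda r: r.angle)
        if len(recs) < 2:
            raise ValueError(f"subject {subject} has fewer than 2 records; cannot split")
        order = rng.permutation(len(recs))
        n_train = math.ceil(fraction * len(recs))
        train.extend(recs[i] for i in order[:n_train])
        test.extend(recs[i] for i in order[n_train:])
    return DatasetSplit(train=train, test=test, seed=seed, fraction=fraction)


def center_crop(image: np.ndarray, target_shape: tuple[int, int]) -> np.ndarray:
    """Centered crop with floor offsets; never pads."""
    tr, tc = target_shape
    sr, sc = image.shape[:2]
    if tr > sr or tc > sc:
        raise ValueError(f"crop target {target_shape} exceeds source {(sr, sc)}")
    r0 = (sr - tr) // 2
    c0 = (sc - tc) // 2
    return image[r0:r0 + tr, c0:c0 + tc]


def normalize(image8: np.ndarray) -> np.ndarray:
    """Map uint8 [0, 255] to the generator's tanh range [-1, 1]."""
    return np.asarray(image8, dtype=np.float32) / 127.5 - 1.0


def denormalize(model_image: np.ndarray) -> np.ndarray:
    """Inverse of :func:`normalize`: clip to [-1, 1], rescale, round half-up."""
    v = (np.clip(np.asarray(model_image, dtype=np.float64), -1.0, 1.0) + 1.0) * 127.5
    return np.floor(v + 0.5).astype(np.uint8)


def load_split_arrays(records: list[SampleRecord]):
    """Stack a record list into aligned uint8 arrays (n, rows, cols)."""
    conv = np.stack([load_png(r.conv_path) for r in records])
    bone = np.stack([load_png(r.bone_path) for r in records])
    iodine = np.stack([load_png(r.iodine_path) for r in records])
    return conv, bone, iodine
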