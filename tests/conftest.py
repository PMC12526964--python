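import dataclasses

import numpy as np
import pytest
from hypothesis import settings

from dualdecomp.phantom import AttenuationTable, PhantomSpec, make_triplet_arrays

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

# test-scale phantom: 64x64 detector, coarser pixels so material path
# lengths (and hence contrast) match the full-resolution geometry
TEST_SPEC = PhantomSpec(shape=(64, 64), pixel_size_um=400.0)


@pytest.fixture(scope="session")
def table():
    return AttenuationTable()


@pytest.fixture(scope="session")
def test_spec():
    return TEST_SPEC


@pytest.fixture(scope="session")
def tiny_dataset_dir(tmp_path_factory, table):
    """A 1-subject, 4-angle PNG dataset on disk with its manifest."""
    from dualdecomp.phantom import make_dataset

    out = tmp_path_factory.mktemp("tinyset")
    manifest = make_dataset(1, 4, TEST_SPEC, table, master_seed=11, out_dir=out)
    return manifest


@pytest.fixture(scope="session")
def smoke_arrays(table):
    """200 noisy synthetic triplets at 64x64 (4 subjects x 50 views)."""
    conv, bone, iodine, subjects, windows = make_triplet_arrays(
        4, 50, TEST_SPEC, table, master_seed=2024)
    return {"conv": conv, "bone": bone, "iodine": iodine,
            "subjects": subjects, "windows": windows}


def _train_smoke(arrays, seed, lambda_excl, steps=400):
    """One scaled-down training run; returns held-out per-image MAE lists."""
    from dualdecomp.losses import LossWeights, LRScheduleSpec
    from dualdecomp.metrics import mae
    from dualdecomp.trainer import TrainConfig, Trainer

    subjects = arrays["subjects"]
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for s in np.unique(subjects):
        idx = np.flatnonzero(subjects == s)
        perm = rng.permutation(len(idx))
        n_train = int(np.ceil(0.8 * len(idx)))
        train_idx.extend(idx[perm[:n_train]])
        test_idx.extend(idx[perm[n_train:]])
    train_idx, test_idx = np.asarray(train_idx), np.asarray(test_idx)
    steps_per_epoch = int(np.ceil(len(train_idx) / 4))
    epochs = max(1, steps // steps_per_epoch)
    cfg = TrainConfig(
        batch_size=4, epochs=epochs, depth=6, gen_base_width=8,
        disc_base_width=8, seed=seed,
        schedule=LRScheduleSpec(warmup_iters=100),
        weights=LossWeights(lambda_excl=lambda_excl))
    trainer = Trainer(cfg)
    trainer.fit_arrays(arrays["conv"][train_idx], arrays["bone"][train_idx],
                       arrays["iodine"][train_idx])
    bone_pred, iodine_pred = trainer.predict(arrays["conv"][test_idx])
    out = {"test_idx": test_idx, "bone_pred": bone_pred, "iodine_pred": iodine_pred}
    for name, pred, gt in (("bone", bone_pred, arrays["bone"]),
                           ("iodine", iodine_pred, arrays["iodine"])):
        out[f"mae_{name}"] = [mae(pred[i], gt[t]) for i, t in enumerate(test_idx)]
        out[f"mae_identity_{name}"] = [mae(arrays["conv"][t], gt[t]) for t in test_idx]
    return out


@pytest.fixture(scope="session")
def smoke_runs(smoke_arrays):
    """Three-seed scaled-down training runs, with and without the
    mutual-exclusivity term (shared across the acceptance tests)."""
    runs = {"with_excl": [], "no_excl": []}
    for seed in (0, 1, 2):
        runs["with_excl"].append(_train_smoke(smoke_arrays, seed, lambda_excl=100.0))
        runs["no_excl"].append(_train_smoke(smoke_arrays, seed, lambda_excl=0.0))
    return runs


@pytest.fixture()
def toy_generator_spec():
    from dualdecomp.networks import GeneratorSpec

    return GeneratorSpec(depth=4, base_width=4)


def random_phantom_spec(rng, shape=(64, 64)):
    """Randomized small phantom spec for property-style physics tests."""
    return dataclasses.replace(
        TEST_SPEC,
        shape=shape,
        subject_seed=int(rng.integers(2 ** 31)),
        angle=int(rng.integers(360)),
        n_vertebrae=int(rng.integers(3, 10)),
        vessel_depth=int(rng.integers(1, 5)),
        iodine_scale_cm=float(rng.uniform(0.02, 0.08)),
        vertebra_thickness_cm=float(rng.uniform(0.08, 0.2)),
    )
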