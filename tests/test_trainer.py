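"""Training orchestration: schedule, checkpointing, reproducibility."""

import json

import numpy as np
import pytest

from lesionseg.config import AugmentConfig, ConfigError, TrainConfig
from lesionseg.metrics import mean_metric
from lesionseg.model import build_model
from lesionseg.synth import SynthSpec, generate_dataset, generate_samples
from lesionseg.train import (
    evaluate,
    load_checkpoint,
    load_image_pairs,
    predict_files,
    save_checkpoint,
    train,
)
from lesionseg.metrics import evaluate_predictions

AUG = AugmentConfig(gt_crop_pad=11)


@pytest.fixture(scope="module")
def small_sets():
    spec = SynthSpec.easy(image_size=96)
    return (generate_samples(16, spec, start_seed=0),
            generate_samples(6, spec, start_seed=700))


@pytest.fixture(scope="module")
def short_run(tiny_cfg, small_sets, tmp_path_factory):
    out = tmp_path_factory.mktemp("run")
    cfg = TrainConfig(epochs=2, seed=3, lr=1e-3)
    result = train(tiny_cfg, cfg, *small_sets, augment_cfg=AUG, out_dir=out)
    return result, out, cfg


def test_learning_rate_decays_exponentially(short_run):
    result, _, cfg = short_run
    for entry in result["history"]:
        assert entry["lr"] == pytest.approx(cfg.lr * cfg.lr_gamma ** entry["epoch"])


def test_history_logs_both_task_losses(short_run):
    result, out, _ = short_run
    for entry in result["history"]:
        assert {"L", "L_seg", "L_edge", "val_JA"} <= entry.keys()
        assert np.isfinite(entry["L"])
    lines = [json.loads(l) for l in (out / "train_log.jsonl").read_text().splitlines()]
    assert len(lines) == len(result["history"])


def test_checkpoint_roundtrip(short_run, tiny_cfg, small_sets):
    result, out, _ = short_run
    model2 = load_checkpoint(out / "checkpoint.npz")
    assert model2.cfg == tiny_cfg
    imgs = np.stack([s.image for s in small_sets[1][:2]])
    # resize-only eval inputs are 96px; predict on 64px crops instead
    x = imgs[:, :, :64, :64]
    np.testing.assert_allclose(result["model"].predict(x), model2.predict(x),
                               atol=1e-6)


def test_checkpoint_config_mismatch_raises(short_run, tmp_path, tiny_cfg):
    result, _, _ = short_run
    other = build_model(tiny_cfg, mode="seg_only", seed=0)
    path = tmp_path / "bad.npz"
    save_checkpoint(path, other, tiny_cfg)
    state = dict(np.load(path))
    # emulate a truncated archive: drop one weight
    state.pop([k for k in state if k.startswith("param/decoder")][0])
    np.savez(path, **state)
    with pytest.raises((ConfigError, KeyError)):
        load_checkpoint(path)


def test_empty_dataset_rejected(tiny_cfg):
    with pytest.raises(ConfigError, match="empty"):
        train(tiny_cfg, TrainConfig(epochs=1), [])


def test_training_is_reproducible(tiny_cfg, small_sets):
    cfg = TrainConfig(epochs=1, seed=9, lr=1e-3)
    r1 = train(tiny_cfg, cfg, small_sets[0][:8], augment_cfg=AUG)
    r2 = train(tiny_cfg, cfg, small_sets[0][:8], augment_cfg=AUG)
    assert r1["history"] == r2["history"]
    df1 = evaluate(r1["model"], small_sets[1], tta=False)
    df2 = evaluate(r2["model"], small_sets[1], tta=False)
    assert df1.equals(df2)


def test_loss_decreases_on_easy_data(tiny_cfg, small_sets):
    """Short smoke training: mean joint loss drops over the first epochs."""
    cfg = TrainConfig(epochs=3, seed=5, lr=1e-3)
    result = train(tiny_cfg, cfg, small_sets[0], augment_cfg=AUG)
    losses = [h["L"] for h in result["history"]]
    assert losses[-1] < losses[0]


def test_perfect_oracle_scores_ja_one(small_sets):
    """Feeding the ground truth as prediction gives mean JA = 1."""
    truths = [s.mask for s in small_sets[1]]
    df = evaluate_predictions([t.astype(float) for t in truths], truths)
    assert mean_metric(df, "JA") == 1.0


def test_evaluate_csv_schema_same_with_and_without_tta(short_run, small_sets, tmp_path):
    result, _, _ = short_run
    df1 = evaluate(result["model"], small_sets[1][:2], tta=False,
                   csv_path=tmp_path / "a.csv")
    df2 = evaluate(result["model"], small_sets[1][:2], tta=True,
                   csv_path=tmp_path / "b.csv")
    assert list(df1.columns) == list(df2.columns)


def test_predict_files_outputs_original_size(short_run, tmp_path):
    result, _, _ = short_run
    spec = SynthSpec.easy(image_size=80, seed=42)
    generate_dataset(1, spec, tmp_path / "data", split="t")
    img_path = next(p for p in (tmp_path / "data").glob("t_*.png")
                    if "mask" not in p.name)
    out = predict_files(result["model"], [img_path, tmp_path / "missing.png"],
                        tmp_path / "pred")
    assert "error" in out[1]  # unreadable file reported, batch continued
    import imageio.v3 as iio

    prob = iio.imread(out[0]["prob"])
    assert prob.shape == (80, 80)
    mask = iio.imread(out[0]["mask"])
    assert set(np.unique(mask)) <= {0, 255}


def test_load_image_pairs_roundtrip(tmp_path):
    generate_dataset(3, SynthSpec.easy(image_size=48), tmp_path, split="train")
    samples = load_image_pairs(tmp_path)
    assert len(samples) == 3
    assert samples[0].image.shape == (3, 48, 48)
    assert set(np.unique(samples[0].mask)) <= {0, 1}


def test_ablation_modes_run_and_rank_parameters(tiny_cfg, small_sets):
    sizes = {}
    for mode in ("seg_only", "seg_edge", "full"):
        cfg = TrainConfig(epochs=1, seed=2, mode=mode, lr=1e-3)
        result = train(tiny_cfg, cfg, small_sets[0][:8], augment_cfg=AUG)
        sizes[mode] = result["model"].num_parameters()
    assert sizes["full"] > sizes["seg_edge"] > sizes["seg_only"]
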