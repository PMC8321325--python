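"""End-to-end training, evaluation and prediction orchestration.

Protocol: Adam (initial learning rate 1e-4) with a per-epoch exponential
decay ``lr_e = lr0 * gamma^e`` (gamma = 0.9), batch size 8, 30 epochs at
full scale; online geometric augmentation; joint objective
``L = alpha * L_seg + L_edge`` with per-image class-balanced cross-entropy
on both tasks; model selection by validation Jaccard index of the
segmentation output.  Everything is seeded: weight init, batch shuffling and
per-sample augmentation draws all derive from the run seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from . import nn
from .augment import ImageSample, augment_train, resize_sample
from .config import AugmentConfig, ConfigError, NetConfig, TrainConfig
from .losses import balanced_bce, joint_loss
from .metrics import evaluate_predictions, mean_metric
from .model import LesionNet, build_model
from .targets import predict_tta


def _batch_arrays(samples: list[ImageSample]):
    images = np.stack([s.image for s in samples]).astype(np.float32)
    masks = np.stack([s.mask for s in samples]).astype(np.float32)
    edges = np.stack([s.edge for s in samples]).astype(np.float32)
    return images, masks, edges


def load_image_pairs(data_dir) -> list[ImageSample]:
    """Read `<id>.png` / `<id>_mask.png` pairs (masks 0/255) from a directory."""
    data_dir = Path(data_dir)
    samples = []
    for mask_path in sorted(data_dir.glob("*_mask.png")):
        img_path = data_dir / mask_path.name.replace("_mask", "")
        if not img_path.exists():
            continue
        img = np.asarray(iio.imread(img_path), dtype=np.float64) / 255.0
        mask = (np.asarray(iio.imread(mask_path)) > 127).astype(np.uint8)
        samples.append(ImageSample.from_hwc(img, mask))
    if not samples:
        raise ConfigError(f"no image/mask pairs found under {data_dir}")
    return samples


def _epoch_losses(model: LesionNet, batch, alpha: float):
    images, masks, edges = batch
    out = model.forward(images)
    l_seg = balanced_bce(out["seg"], masks[:, None])
    if out["edge"] is not None:
        l_edge = balanced_bce(out["edge"], edges[:, None])
        total = joint_loss(l_seg, l_edge, alpha)
    else:
        l_edge = None
        total = l_seg
    return total, l_seg, l_edge


def train(net_cfg: NetConfig, train_cfg: TrainConfig,
          train_samples: list[ImageSample], val_samples: list[ImageSample] | None = None,
          augment_cfg: AugmentConfig | None = None, out_dir=None,
          log_fn=None) -> dict:
    """Train a model; returns ``{"model", "history", "best_state", "best_ja"}``.

    ``history`` is a list of per-epoch dicts (lr, L, L_seg, L_edge, val JA).
    When ``out_dir`` is given, JSON-line logs and the best checkpoint are
    written there.
    """
    if not train_samples:
        raise ConfigError("training dataset is empty")
    augment_cfg = augment_cfg or AugmentConfig()
    rng = np.random.default_rng(train_cfg.seed)
    model = build_model(net_cfg, mode=train_cfg.mode,
                        seed=int(rng.integers(2 ** 31)))
    optimizer = nn.Adam(model.parameters(), lr=train_cfg.lr)

    out_dir = Path(out_dir) if out_dir is not None else None
    log_path = None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        log_path = out_dir / "train_log.jsonl"
        log_path.write_text("")

    history = []
    best_ja, best_state = -1.0, None
    n = len(train_samples)
    for epoch in range(train_cfg.epochs):
        optimizer.lr = train_cfg.lr * train_cfg.lr_gamma ** epoch
        order = rng.permutation(n)
        model.train()
        sums = {"L": 0.0, "L_seg": 0.0, "L_edge": 0.0}
        n_batches = 0
        for start in range(0, n, train_cfg.batch_size):
            idx = order[start:start + train_cfg.batch_size]
            if train_cfg.augment:
                batch_samples = [
                    augment_train(train_samples[i], augment_cfg, net_cfg.input_size,
                                  rng_seed=int(rng.integers(2 ** 31)))
                    for i in idx
                ]
            else:
                batch_samples = [resize_sample(train_samples[i], net_cfg.input_size,
                                               augment_cfg.edge_thickness)
                                 for i in idx]
            total, l_seg, l_edge = _epoch_losses(model, _batch_arrays(batch_samples),
                                                 train_cfg.alpha)
            optimizer.zero_grad()
            total.backward()
            optimizer.step()
            sums["L"] += total.item()
            sums["L_seg"] += l_seg.item()
            sums["L_edge"] += l_edge.item() if l_edge is not None else 0.0
            n_batches += 1

        entry = {"epoch": epoch, "lr": optimizer.lr,
                 **{k: v / n_batches for k, v in sums.items()}}
        if val_samples:
            df = evaluate(model, val_samples, tta=False)
            entry["val_JA"] = mean_metric(df, "JA")
            if entry["val_JA"] >= best_ja:
                best_ja = entry["val_JA"]
                best_state = model.state_dict()
        history.append(entry)
        if log_fn is not None:
            log_fn(entry)
        if log_path is not None:
            with open(log_path, "a") as fh:
                fh.write(json.dumps(entry) + "\n")

    if best_state is None:  # no validation set: keep the final weights
        best_state = model.state_dict()
        best_ja = float("nan")
    else:
        model.load_state_dict(best_state)
    if out_dir is not None:
        save_checkpoint(out_dir / "checkpoint.npz", model, net_cfg, train_cfg)
    return {"model": model, "history": history,
            "best_state": best_state, "best_ja": best_ja}


# ---------------------------------------------------------------------------
# evaluation / prediction
# ---------------------------------------------------------------------------

def _predict_probs(model: LesionNet, samples, input_size, tta: bool,
                   batch_size: int = 8):
    """Probability maps at each sample's original resolution."""
    from .augment import apply_step

    resized = [resize_sample(s, input_size) for s in samples]
    probs_small = []
    for start in range(0, len(resized), batch_size):
        images = np.stack([s.image for s in resized[start:start + batch_size]])
        if tta:
            p = predict_tta(model.predict, images)
        else:
            p = model.predict(images)
        probs_small.extend(p)
    probs = []
    for sample, p in zip(samples, probs_small):
        h = sample.mask.shape[0]
        probs.append(apply_step(p.astype(np.float64), {"op": "resize", "size": h},
                                order=1) if h != input_size else p)
    return probs


def evaluate(model: LesionNet, samples: list[ImageSample], tta: bool = False,
             threshold: float = 0.5, csv_path=None) -> pd.DataFrame:
    """Per-image + mean metrics of the segmentation output (only the mask
    prediction is used at test time)."""
    probs = _predict_probs(model, samples, model.cfg.input_size, tta)
    df = evaluate_predictions(probs, [s.mask for s in samples],
                              threshold=threshold)
    if csv_path is not None:
        df.to_csv(csv_path, index=False)
    return df


def predict_files(model: LesionNet, image_paths, out_dir, tta: bool = False,
                  threshold: float = 0.5) -> list:
    """Predict probability + binary mask PNGs at each image's original size.

    Unreadable files produce a per-file error entry; the batch continues.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results = []
    for path in map(Path, image_paths):
        try:
            img = np.asarray(iio.imread(path), dtype=np.float64) / 255.0
            if img.ndim == 2:
                img = np.stack([img] * 3, axis=-1)
            sample = ImageSample.from_hwc(img[..., :3],
                                          np.zeros(img.shape[:2], dtype=np.uint8))
        except Exception as exc:  # noqa: BLE001 - surfaced per file
            results.append({"image": str(path), "error": str(exc)})
            continue
        prob = _predict_probs(model, [sample], model.cfg.input_size, tta)[0]
        prob_path = out_dir / f"{path.stem}_prob.png"
        mask_path = out_dir / f"{path.stem}_mask.png"
        iio.imwrite(prob_path, np.clip(prob * 255, 0, 255).astype(np.uint8))
        iio.imwrite(mask_path, ((prob >= threshold) * 255).astype(np.uint8))
        results.append({"image": str(path), "prob": str(prob_path),
                        "mask": str(mask_path)})
    return results


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, model: LesionNet, net_cfg: NetConfig,
                    train_cfg: TrainConfig | None = None) -> None:
    """Single-file weight archive with the embedded configuration."""
    meta = {"model": asdict(net_cfg), "mode": model.mode,
            "train": asdict(train_cfg) if train_cfg else None}
    state = {f"param/{k}": v for k, v in model.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **state)


def load_checkpoint(path) -> LesionNet:
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        state = {k[len("param/"):]: archive[k] for k in archive.files
                 if k.startswith("param/")}
    net_cfg = NetConfig(**{k: tuple(v) if isinstance(v, list) else v
                           for k, v in meta["model"].items()})
    model = build_model(net_cfg, mode=meta["mode"])
    try:
        model.load_state_dict(state)
    except (KeyError, ValueError) as exc:
        raise ConfigError(f"checkpoint {path} does not match its config: {exc}") from exc
    model.eval()
    return model
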