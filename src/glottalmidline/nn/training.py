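"""Training loop, datasets and evaluation for the keypoint networks.

Datasets are generated by the six-mass pipeline: the input is either
the peak frame or the normalised 2r+1-frame temporal sum, downscaled to
a small grid for desk-scale training; targets are the posterior and
anterior points as [0, 1] image fractions.  The optimizer is RMSprop
(rho 0.9) with learning-rate decay, and model selection keeps the epoch
with the best validation loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..benchmark import BenchmarkConfig, build_sequence
from ..detectors import Midline
from ..metrics import mape_point, miou_midline
from .. import temporal
from .autodiff import Tensor
from .losses import get_loss
from .models import MidlineNet, RecurrentMidlineNet, GlottisNet

__all__ = ["TrainConfig", "KeypointDataset", "make_keypoint_dataset",
           "train", "evaluate", "split_dataset"]


@dataclass
class TrainConfig:
    epochs: int = 50
    batch_size: int = 8
    learning_rate: float = 1e-4
    rho: float = 0.9                  # RMSprop moving-average momentum
    decay: float = 0.5e-6             # learning-rate decay per update
    test_fraction: float = 0.25
    val_fraction: float = 0.10        # of the training split
    seed: int = 0
    keypoint_loss: str = "mse"
    seg_loss: str = "dice"
    seg_weight: float = 1.0           # multi-task head weighting
    epsilon: float = 1e-8

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1 or not 0 < self.val_fraction < 1:
            raise ValueError("split fractions must be in (0, 1)")


@dataclass
class KeypointDataset:
    """Images [N, 1, h, w] in [0, 1]; keypoints [N, 4] image fractions
    (x_P, y_P, x_A, y_A); full-resolution peak masks and pixel-space
    ground truth for mIoU evaluation."""

    images: np.ndarray
    keypoints: np.ndarray
    masks: np.ndarray
    gt_px: np.ndarray                 # [N, 2, 2] P/A in mask pixels
    frames: np.ndarray | None = None  # [N, T, 1, h, w] for recurrent nets

    def __len__(self) -> int:
        return len(self.images)

    def subset(self, idx) -> "KeypointDataset":
        return KeypointDataset(
            self.images[idx], self.keypoints[idx], self.masks[idx],
            self.gt_px[idx],
            None if self.frames is None else self.frames[idx])


def _downscale(img: np.ndarray, size: int) -> np.ndarray:
    """Block-mean downscale of a square image to size x size."""
    H, W = img.shape
    f = H // size
    return img[:f * size, :f * size].reshape(size, f, size, f).mean(axis=(1, 3))


def make_keypoint_dataset(n_sequences: int, seed: int = 0,
                          half_range: int = 10, image_size: int = 32,
                          peaks_per_sequence: int = 2,
                          with_frames: bool = False,
                          frame_stride: int = 4,
                          bench: BenchmarkConfig | None = None) -> KeypointDataset:
    """Build a keypoint-regression dataset from fresh simulations.

    One sample per GAW peak (at most ``peaks_per_sequence`` per
    sequence): the 2*half_range+1 frame sum normalised to [0, 1] (the
    single peak frame when ``half_range`` is 0), downscaled.  With
    ``with_frames`` a strided stack of the window's raw frames is kept
    for recurrent models.
    """
    bench = bench or BenchmarkConfig(n_simulations=n_sequences, seed=seed)
    images, kps, masks_out, gts, frame_stacks = [], [], [], [], []
    for i in range(n_sequences):
        seq, _, _, _ = build_sequence(bench, i)
        H, W = seq.masks.shape[1:]
        peaks = temporal.detect_maxima(temporal.compute_gaw(seq))
        peaks = [p for p in peaks
                 if p - half_range >= 0 and p + half_range < len(seq)]
        for p in peaks[:peaks_per_sequence]:
            img = temporal.sum_frames(seq, p, half_range)
            img = img.astype(float) / (2 * half_range + 1)
            images.append(_downscale(img, image_size)[None])
            gt = seq.gt_midline[p]
            kps.append(np.array([gt[0, 0] / W, gt[0, 1] / H,
                                 gt[1, 0] / W, gt[1, 1] / H]))
            masks_out.append(seq.masks[p])
            gts.append(gt)
            if with_frames:
                idx = range(p - half_range, p + half_range + 1, frame_stride)
                frame_stacks.append(np.stack(
                    [_downscale(seq.masks[t].astype(float), image_size)[None]
                     for t in idx]))
    return KeypointDataset(
        np.stack(images), np.stack(kps), np.stack(masks_out), np.stack(gts),
        np.stack(frame_stacks) if with_frames else None)


def split_dataset(ds: KeypointDataset, cfg: TrainConfig):
    """75/25 train/test, then 90/10 train/val (seeded shuffle)."""
    rng = np.random.default_rng(cfg.seed)
    idx = rng.permutation(len(ds))
    n_test = max(1, int(round(cfg.test_fraction * len(ds))))
    test, rest = idx[:n_test], idx[n_test:]
    n_val = max(1, int(round(cfg.val_fraction * len(rest))))
    val, train_ = rest[:n_val], rest[n_val:]
    return ds.subset(train_), ds.subset(val), ds.subset(test)


class _RMSprop:
    def __init__(self, params, cfg: TrainConfig):
        self.params = params
        self.cfg = cfg
        self.acc = [np.zeros_like(p.data) for p in params]
        self.iterations = 0

    def step(self) -> None:
        c = self.cfg
        lr = c.learning_rate / (1.0 + c.decay * self.iterations)
        for p, a in zip(self.params, self.acc):
            if p.grad is None:
                continue
            a *= c.rho
            a += (1.0 - c.rho) * p.grad ** 2
            p.data -= lr * p.grad / (np.sqrt(a) + c.epsilon)
        self.iterations += 1


def _forward_loss(model, batch_x, batch_y, batch_masks, cfg: TrainConfig):
    kp_loss = get_loss(cfg.keypoint_loss)
    if isinstance(model, GlottisNet):
        seg, kp = model(Tensor(batch_x))
        seg_target = batch_masks[:, None].astype(float)
        loss = kp_loss(Tensor(batch_y), kp) + \
            cfg.seg_weight * get_loss(cfg.seg_loss)(Tensor(seg_target), seg)
        return loss
    if isinstance(model, RecurrentMidlineNet):
        frames = [Tensor(batch_x[:, t]) for t in range(batch_x.shape[1])]
        return kp_loss(Tensor(batch_y), model(frames))
    return kp_loss(Tensor(batch_y), model(Tensor(batch_x)))


def _model_inputs(model, ds: KeypointDataset, idx):
    if isinstance(model, RecurrentMidlineNet):
        return ds.frames[idx]
    return ds.images[idx]


def _seg_targets(model, ds: KeypointDataset, idx, size: int):
    if not isinstance(model, GlottisNet):
        return None
    return np.stack([_downscale(m.astype(float), size) for m in ds.masks[idx]])


def train(model, dataset: KeypointDataset, cfg: TrainConfig | None = None,
          verbose: bool = False) -> dict:
    """Mini-batch training with best-validation-epoch selection.

    Returns a history dict with per-epoch ``train_loss`` / ``val_loss``,
    the selected ``best_epoch`` and the held-out ``test`` subset.
    Raises on non-finite loss with epoch/batch context.
    """
    cfg = cfg or TrainConfig()
    tr, val, test = split_dataset(dataset, cfg)
    params = model.parameters()
    opt = _RMSprop(params, cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    size = dataset.images.shape[-1]
    history = {"train_loss": [], "val_loss": []}
    best = (np.inf, None)
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(tr))
        losses = []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            x = _model_inputs(model, tr, idx)
            masks = _seg_targets(model, tr, idx, size)
            loss = _forward_loss(model, x, tr.keypoints[idx], masks, cfg)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch {start}")
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        vx = _model_inputs(model, val, slice(None))
        vmasks = _seg_targets(model, val, slice(None), size)
        vloss = float(_forward_loss(model, vx, val.keypoints, vmasks,
                                    cfg).data)
        history["train_loss"].append(float(np.mean(losses)))
        history["val_loss"].append(vloss)
        if vloss < best[0]:
            best = (vloss, [p.data.copy() for p in params])
        if verbose:
            print(f"epoch {epoch}: train {history['train_loss'][-1]:.5f} "
                  f"val {vloss:.5f}")
    if best[1] is not None:
        for p, d in zip(params, best[1]):
            p.data = d
    history["best_epoch"] = int(np.argmin(history["val_loss"]))
    history["test"] = test
    return history


def predict_keypoints(model, ds: KeypointDataset) -> np.ndarray:
    """[N, 4] keypoints as image fractions."""
    x = _model_inputs(model, ds, slice(None))
    if isinstance(model, GlottisNet):
        _, kp = model(Tensor(x))
    elif isinstance(model, RecurrentMidlineNet):
        kp = model([Tensor(x[:, t]) for t in range(x.shape[1])])
    else:
        kp = model(Tensor(x))
    return kp.data


def evaluate(model, ds: KeypointDataset) -> pd.DataFrame:
    """Per-sample MAPE (relative Euclidean) and midline mIoU."""
    preds = predict_keypoints(model, ds)
    rows = []
    for i, kp in enumerate(preds):
        H, W = ds.masks[i].shape
        P = (kp[0] * W, kp[1] * H)
        A = (kp[2] * W, kp[3] * H)
        gt = ds.gt_px[i]
        row = {"mape_P": mape_point(P, gt[0], euclidean=True),
               "mape_A": mape_point(A, gt[1], euclidean=True)}
        try:
            if P[1] > A[1]:
                P, A = A, P
            ml = Midline(P=P, A=A)
            gt_ml = Midline(P=tuple(gt[0]), A=tuple(gt[1]))
            row["miou"] = miou_midline(ds.masks[i], gt_ml, ml)
        except ValueError:
            row["miou"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
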