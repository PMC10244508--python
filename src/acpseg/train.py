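"""Training loop, loss, schedule and the ablation runner.

The recipe follows the common small-dataset segmentation setup: Adam
(betas 0.9/0.999), base learning rate 1e-4 with step decay by 0.1 every 7
epochs, batch size 4, 100 epochs, and a compound loss

    L = w_ce * CrossEntropy + w_dice * SoftDice        (defaults 0.5/0.5).

Everything random — shuffling, augmentation, weight init, dropout — fans
out from one master seed through per-epoch ``SeedSequence`` spawns, so a
run is a pure function of (data, config, seed) and a resumed run continues
bit-identically to an uninterrupted one.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np

from .nn import Tensor, Adam, lr_at_epoch, Dropout
from .model import (ModelConfig, ACPTransUNet, build_variant, count_parameters,
                    save_checkpoint)
from .phantom import ImageSlice, MaskSlice, DatasetSplit, augment, read_dataset
from .metrics import evaluate, dice as dice_score, MetricsReport

__all__ = ["TrainConfig", "segmentation_loss", "train", "run_ablation",
           "TrainResult"]


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 4
    epochs: int = 100
    base_lr: float = 1e-4
    step_size: int = 7
    gamma: float = 0.1
    w_ce: float = 0.5
    w_dice: float = 0.5
    seed: int = 0
    augment_ops: tuple[str, ...] = ("hflip", "vflip", "invert")
    augment_p: float = 0.5
    max_steps: int | None = None
    checkpoint_dir: str | None = None
    log_path: str | None = None

    def __post_init__(self):
        if self.base_lr <= 0:
            raise ValueError("base_lr must be > 0")
        if not 0 < self.gamma <= 1:
            raise ValueError("gamma must be in (0, 1]")
        if self.step_size < 1:
            raise ValueError("step_size must be >= 1")


def segmentation_loss(logits: Tensor, labels: np.ndarray,
                      w_ce: float = 0.5, w_dice: float = 0.5) -> Tensor:
    """Weighted cross-entropy + soft-Dice loss for two-class logits.

    `labels` is a (B, H, W) integer array. The soft-Dice term uses the
    foreground softmax probability against the binary reference, batch
    pooled, with an additive smoothing constant of 1.
    """
    B = logits.shape[0]
    if B == 0:
        raise ValueError("empty batch")
    C = logits.shape[1]
    lab = np.asarray(labels).astype(np.int64)
    onehot = np.eye(C)[lab].transpose(0, 3, 1, 2)  # (B, C, H, W)
    ls = logits.log_softmax(axis=1)
    ce = -(ls * Tensor(onehot)).sum() * (1.0 / lab.size)
    sel = np.zeros((1, C, 1, 1))
    sel[0, 1] = 1.0
    fg = (logits.softmax(axis=1) * Tensor(sel)).sum(axis=1)  # (B, H, W)
    g = Tensor(onehot[:, 1])
    smooth = 1.0
    soft_dice = (fg * g).sum() * 2.0 + smooth
    soft_dice = soft_dice / (fg.sum() + g.sum() + smooth)
    return ce * w_ce + (1.0 - soft_dice) * w_dice


@dataclasses.dataclass
class TrainResult:
    model: ACPTransUNet
    history: list[dict]
    best_val_dice: float
    steps: int


def _seed_rng(master: int, kind: int, epoch: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=master, spawn_key=(kind, epoch)))


def _load_pairs(data) -> tuple[list, DatasetSplit | None]:
    if isinstance(data, (str, Path)):
        return read_dataset(data)
    pairs, split = data
    return list(pairs), split


def _forward_dice(model: ACPTransUNet, pairs: list, ids) -> float:
    model.eval()
    scores = []
    lookup = {id_: (img, msk) for id_, img, msk in pairs}
    for id_ in ids:
        img, msk = lookup[id_]
        out = model.predict(img.pixels)
        scores.append(dice_score(out.mask[0], msk))
    model.train()
    return float(np.mean(scores)) if scores else math.nan


def train(model_cfg: ModelConfig, data, cfg: TrainConfig,
          resume: str | None = None) -> TrainResult:
    """Run the seeded training loop; returns the trained model and history.

    `data` is either a dataset directory or a `(pairs, split)` tuple of
    in-memory phantoms. Per-epoch train loss and validation Dice are
    logged (JSONL if `cfg.log_path` is set); the best-validation-Dice
    checkpoint is kept when `cfg.checkpoint_dir` is set. `resume` restores
    a `last` checkpoint saved by a previous (interrupted) run and
    continues identically.
    """
    pairs, split = _load_pairs(data)
    if split is None:
        ids = [p[0] for p in pairs]
        split = DatasetSplit(tuple(ids), (), ())
    lookup = {id_: (img, msk) for id_, img, msk in pairs}
    train_ids = list(split.train_ids)
    if not train_ids:
        raise ValueError("empty training split")

    model = ACPTransUNet(model_cfg)
    model.initialize(_seed_rng(cfg.seed, 0, 0))
    opt = Adam(model.parameters(), lr=cfg.base_lr)
    history: list[dict] = []
    start_epoch, step = 0, 0
    best = -math.inf

    if resume is not None:
        state = np.load(Path(resume), allow_pickle=False)
        model.load_state_dict({k[6:]: state[k] for k in state.files
                               if k.startswith("model.")})
        opt.load_state_dict({
            "t": int(state["opt.t"]),
            "m": [state[f"opt.m{i}"] for i in range(len(opt.m))],
            "v": [state[f"opt.v{i}"] for i in range(len(opt.v))]})
        start_epoch = int(state["epoch"]) + 1
        step = int(state["step"])
        best = float(state["best"])
        history = json.loads(str(state["history"]))

    log_fh = open(cfg.log_path, "a") if cfg.log_path else None
    ckdir = Path(cfg.checkpoint_dir) if cfg.checkpoint_dir else None
    done = False
    for epoch in range(start_epoch, cfg.epochs):
        opt.lr = lr_at_epoch(epoch, cfg.base_lr, cfg.step_size, cfg.gamma)
        shuffle_rng = _seed_rng(cfg.seed, 1, epoch)
        aug_rng = _seed_rng(cfg.seed, 2, epoch)
        for m in model.modules():
            if isinstance(m, Dropout):
                m.rng = _seed_rng(cfg.seed, 3, epoch)
        order = list(train_ids)
        shuffle_rng.shuffle(order)
        losses = []
        for i in range(0, len(order), cfg.batch_size):
            batch_ids = order[i:i + cfg.batch_size]
            imgs, labs = [], []
            for id_ in batch_ids:
                img, msk = lookup[id_]
                if cfg.augment_ops:
                    img, msk = augment(img, msk, list(cfg.augment_ops),
                                       p=cfg.augment_p,
                                       seed=int(aug_rng.integers(2 ** 31)))
                imgs.append(img.pixels)
                labs.append(msk.labels)
            x = Tensor(np.stack(imgs)[:, None])
            y = np.stack(labs)
            logits = model.forward_logits(x)
            loss = segmentation_loss(logits, y, cfg.w_ce, cfg.w_dice)
            if not math.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, step {step}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            step += 1
            if cfg.max_steps is not None and step >= cfg.max_steps:
                done = True
                break
        val_d = _forward_dice(model, pairs, split.val_ids)
        rec = {"epoch": epoch, "lr": opt.lr,
               "train_loss": float(np.mean(losses)) if losses else math.nan,
               "val_dice": val_d, "step": step}
        history.append(rec)
        if log_fh:
            log_fh.write(json.dumps(rec) + "\n")
            log_fh.flush()
        if ckdir is not None:
            score = val_d if val_d == val_d else -math.inf
            if score >= best:
                best = score
                save_checkpoint(model, ckdir / "best.npz",
                                extra={"epoch": epoch, "val_dice": val_d})
            _save_resume_state(model, opt, epoch, step, best, history,
                               ckdir / "last_state.npz")
        elif val_d == val_d:
            best = max(best, val_d)
        if done:
            break
    if log_fh:
        log_fh.close()
    return TrainResult(model=model, history=history,
                       best_val_dice=best if best > -math.inf else math.nan,
                       steps=step)


def _save_resume_state(model, opt, epoch, step, best, history, path) -> None:
    payload = {f"model.{k}": v for k, v in model.state_dict().items()}
    payload["opt.t"] = np.asarray(opt.t)
    for i, (m, v) in enumerate(zip(opt.m, opt.v)):
        payload[f"opt.m{i}"] = m
        payload[f"opt.v{i}"] = v
    payload["epoch"] = np.asarray(epoch)
    payload["step"] = np.asarray(step)
    payload["best"] = np.asarray(best)
    payload["history"] = np.asarray(json.dumps(history))
    np.savez(Path(path), **payload)


def run_ablation(variants: list[str], data, cfg: TrainConfig,
                 base_model_cfg: ModelConfig | None = None,
                 csv_path=None) -> list[dict]:
    """Train and evaluate each ablation variant under identical seed/data.

    Emits one comparison-table row per variant (overall + per-view Dice%
    and HD95 mm, parameter count). A variant that fails is reported with
    its error and the run continues.
    """
    pairs, split = _load_pairs(data)
    if split is None or not split.test_ids:
        raise ValueError("ablation needs a dataset with a test split")
    base = base_model_cfg if base_model_cfg is not None else ModelConfig()
    lookup = {id_: (img, msk) for id_, img, msk in pairs}
    rows = []
    for name in variants:
        mc = build_variant(name, base)
        try:
            result = train(mc, (pairs, split), cfg)
            model = result.model
            preds = {id_: model.predict(lookup[id_][0].pixels).mask[0]
                     for id_ in split.test_ids}
            refs = {id_: lookup[id_][1] for id_ in split.test_ids}
            report = evaluate(preds, refs)
            rows.append({"model": name, "report": report,
                         "params": count_parameters(model),
                         "config": dataclasses.asdict(mc),
                         "error": None})
        except Exception as exc:  # keep going; surface per-variant failures
            rows.append({"model": name, "report": None, "params": None,
                         "config": dataclasses.asdict(mc), "error": repr(exc)})
    if csv_path is not None:
        csv_path = Path(csv_path)
        if csv_path.exists():
            csv_path.unlink()
        for row in rows:
            if row["report"] is not None:
                row["report"].write_csv(csv_path, model_name=row["model"])
    return rows
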