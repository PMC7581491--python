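"""Participant-balanced k-fold training, model selection and ensembling.

Participants are split into low/high macular-volume groups by the
cohort-median baseline volume; every fold's validation set holds one
participant of each group and a participant's volumes never straddle
the train/validation line.  Each fold trains the network with Adam on
soft Dice loss (batch size 3, samples reshuffled every epoch, on-the-fly
augmentation) and keeps the epoch checkpoint with the highest hard
validation Dice.  Experiments are repeated over runs with seeds derived
as ``base_seed + 1000 * run + fold``.

Two ways of combining the fold networks are provided: averaging each
fold's boundary-error table (``average_fold_errors``) and per-pixel
majority voting of the fold label maps followed by a single graph search
(``majority_vote`` + boundary extraction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import preprocess
from .metrics import dice_overlap
from .nn import Adam
from .nn.autograd import Tensor
from .phantom import CohortManifest
from .preprocess import (AugmentConfig, boundaries_to_regions, enhance_contrast,
                         onehot_regions, pad_top)
from .segnet import NetConfig, SegNet, build_network, dice_loss


@dataclass
class FoldSplit:
    fold_index: int
    train_participants: list
    val_participants: list

    def __post_init__(self):
        if set(self.train_participants) & set(self.val_participants):
            raise ValueError("train and validation participants overlap")
        if not self.train_participants:
            raise ValueError("fold has an empty training set")


@dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 3
    n_runs: int = 5
    n_folds: int = 6
    seed: int = 0
    shuffle_each_epoch: bool = True
    augment: bool = True
    augment_cfg: AugmentConfig = field(default_factory=AugmentConfig)
    enhance: bool = True
    enhance_exponent: float = 2.0
    pad_rows: int = preprocess.PAD_ROWS_DEFAULT

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.n_runs < 1 or self.n_folds < 1:
            raise ValueError("n_runs and n_folds must be >= 1")

    def run_fold_seed(self, run: int, fold: int) -> int:
        """Deterministic seed ledger: base + 1000*run + fold."""
        return int(self.seed + 1000 * run + fold)


# ---------------------------------------------------------------------------
# folds
# ---------------------------------------------------------------------------

def make_folds(manifest: CohortManifest, n_folds: int = 6) -> list:
    """Rotate one (low, high) validation pair per fold over sorted ids.

    With one fold per participant-per-group, every participant validates
    exactly once; training sets keep the low/high balance.
    """
    groups = manifest.groups()
    if any(g not in ("low", "high") for g in groups.values()):
        raise ValueError("all participants must carry a low/high group label")
    low = sorted(p for p, g in groups.items() if g == "low")
    high = sorted(p for p, g in groups.items() if g == "high")
    if not low or not high:
        raise ValueError("both volume groups must be non-empty")
    folds = []
    for k in range(n_folds):
        val = [low[k % len(low)], high[k % len(high)]]
        train = [p for p in sorted(groups) if p not in val]
        folds.append(FoldSplit(fold_index=k, train_participants=train,
                               val_participants=val))
    return folds


def split_test_participants(manifest: CohortManifest, n_test: int):
    """Hold out ``n_test`` participants (balanced low/high) for testing.

    Returns (trainval_manifest, test_manifest).  The last sorted ids of
    each group are held out, so the split is deterministic.
    """
    if n_test % 2:
        raise ValueError("n_test must be even to keep the groups balanced")
    groups = manifest.groups()
    low = sorted(p for p, g in groups.items() if g == "low")
    high = sorted(p for p, g in groups.items() if g == "high")
    if len(low) < n_test // 2 + 1 or len(high) < n_test // 2 + 1:
        raise ValueError("not enough participants per group to hold out")
    test_ids = set(low[-n_test // 2:] + high[-n_test // 2:])
    tv = [p for p in manifest.participants if p.participant_id not in test_ids]
    te = [p for p in manifest.participants if p.participant_id in test_ids]
    mk = lambda ps: CohortManifest(participants=ps, config=manifest.config,
                                   seed=manifest.seed)
    return mk(tv), mk(te)


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------

def prepare_samples(manifest: CohortManifest, participants, cfg: TrainConfig):
    """Preprocess every scan of the given participants.

    Returns (images, labels): float32 images (M, H+pad, W) on the 8-bit
    scale and uint8 region label maps of the same spatial shape.
    """
    images, labels = [], []
    for pid in participants:
        p = manifest.by_id(pid)
        for vol in p.volumes:
            for scan, bnd in zip(vol.bscans, vol.boundaries):
                px = scan.pixels
                if cfg.enhance:
                    px = enhance_contrast(px, cfg.enhance_exponent)
                px, shifted = pad_top(px, bnd, cfg.pad_rows)
                images.append(px.astype(np.float32))
                labels.append(boundaries_to_regions(shifted, px.shape[0],
                                                    px.shape[1]))
    return np.stack(images), np.stack(labels)


def _hard_dice(net: SegNet, images, labels, batch_size=3) -> float:
    """Mean 3-class hard Dice (fraction, not percent) on a sample set."""
    vals = []
    for i in range(0, len(images), batch_size):
        probs = net.predict_proba(images[i:i + batch_size] / 255.0)
        pred = probs.argmax(axis=1)
        for j in range(pred.shape[0]):
            vals.append(dice_overlap(pred[j], labels[i + j])["overall"] / 100.0)
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train_fold(fold: FoldSplit, manifest: CohortManifest, net_cfg: NetConfig,
               train_cfg: TrainConfig, seed: int):
    """Train one fold; return (net at best-validation state, history).

    Minimizes soft Dice loss with Adam; after every epoch the hard Dice
    overlap on the fold's validation participants is evaluated and the
    best checkpoint is retained.  Raises on NaN loss.
    """
    rng = np.random.default_rng(seed)
    tr_img, tr_lab = prepare_samples(manifest, fold.train_participants, train_cfg)
    va_img, va_lab = prepare_samples(manifest, fold.val_participants, train_cfg)
    net = build_network(net_cfg, seed=seed)
    opt = Adam(net.parameters())
    hist = []
    best = (-1.0, None)
    order = np.arange(len(tr_img))
    for epoch in range(train_cfg.epochs):
        if train_cfg.shuffle_each_epoch:
            rng.shuffle(order)
        losses = []
        for i in range(0, len(order), train_cfg.batch_size):
            idx = order[i:i + train_cfg.batch_size]
            xb, tb = [], []
            for j in idx:
                img, lab = tr_img[j], tr_lab[j]
                if train_cfg.augment:
                    bset = None
                    img, _, case = preprocess.augment(img, bset,
                                                      train_cfg.augment_cfg, rng)
                    if "flipped" in case:
                        lab = lab[:, ::-1]
                xb.append(np.asarray(img, dtype=np.float32) / 255.0)
                tb.append(onehot_regions(lab))
            x = Tensor(np.stack(xb)[:, None])
            t = np.stack(tb)
            probs = net(x, training=True, rng=rng)
            loss = dice_loss(probs, t)
            lv = float(loss.data)
            if not np.isfinite(lv):
                raise RuntimeError(
                    f"NaN/inf Dice loss at epoch {epoch}, fold "
                    f"{fold.fold_index}; aborting run")
            loss.backward()
            opt.step()
            opt.zero_grad()
            losses.append(lv)
        val_dice = _hard_dice(net, va_img, va_lab, train_cfg.batch_size)
        hist.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                     "val_dice": val_dice})
        if val_dice > best[0]:
            best = (val_dice, net.get_state())
    net.set_state(best[1])
    history = pd.DataFrame(hist)
    history.attrs["best_val_dice"] = best[0]
    return net, history


def run_experiment(manifest: CohortManifest, net_cfg: NetConfig,
                   train_cfg: TrainConfig, folds: list | None = None):
    """n_runs x n_folds training; returns (models, report).

    ``models``: dict (run, fold_index) -> trained network.
    ``report``: per-run/per-fold best validation Dice plus across-run means.
    """
    folds = folds if folds is not None else make_folds(manifest,
                                                       train_cfg.n_folds)
    models, rows = {}, []
    for run in range(train_cfg.n_runs):
        for fold in folds:
            seed = train_cfg.run_fold_seed(run, fold.fold_index)
            net, history = train_fold(fold, manifest, net_cfg, train_cfg, seed)
            models[(run, fold.fold_index)] = net
            rows.append({"run": run, "fold": fold.fold_index, "seed": seed,
                         "best_val_dice": history.attrs["best_val_dice"],
                         "final_train_loss":
                             float(history["train_loss"].iloc[-1])})
    report = pd.DataFrame(rows)
    report.attrs["mean_val_dice"] = float(report["best_val_dice"].mean())
    return models, report


# ---------------------------------------------------------------------------
# ensembling
# ---------------------------------------------------------------------------

def majority_vote(label_maps, prob_maps=None) -> np.ndarray:
    """Per-pixel modal class over k label maps.

    Ties are broken by the highest mean class probability across the
    networks when ``prob_maps`` (k arrays (3, H, W)) are given, otherwise
    by the lowest class index.
    """
    maps = [np.asarray(m) for m in label_maps]
    if not maps:
        raise ValueError("need at least one label map")
    shape = maps[0].shape
    if any(m.shape != shape for m in maps):
        raise ValueError("label map shapes differ")
    n_classes = 3
    counts = np.stack([sum((m == c).astype(np.int32) for m in maps)
                       for c in range(n_classes)])
    top = counts.max(axis=0)
    is_top = counts == top
    if prob_maps is not None:
        mean_probs = np.mean([np.asarray(p) for p in prob_maps], axis=0)
        score = np.where(is_top, mean_probs, -1.0)
    else:
        score = np.where(is_top, 1.0, -1.0) - np.arange(n_classes)[:, None, None] * 1e-6
    return score.argmax(axis=0).astype(np.uint8)


def average_fold_errors(tables: list) -> pd.DataFrame:
    """Arithmetic mean of per-fold boundary-error tables (per boundary,
    per numeric metric)."""
    if not tables:
        raise ValueError("need at least one fold table")
    cat = pd.concat(tables, ignore_index=True)
    num = cat.select_dtypes("number").columns
    return cat.groupby("boundary", as_index=False)[list(num)].mean()
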