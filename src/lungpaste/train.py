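"""Pretext training loop.

Each batch pairs every sampled normal image with a freshly augmented copy,
so both loss terms (original -> 0, augmented -> 1) are realized for every
image. After every epoch the validation AUC is computed through the same
KDE scoring path used at evaluation time (normal-training embedding bank,
-log density scores), and the best weights are kept.

Per-image augmentation seeds are derived from (global seed, epoch, image
index), so runs are reproducible but augmentations never repeat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import nn
from .augment import AugmentParams, PlacementError, paste_augment
from .metrics import roc_auc
from .model import PretextModel, TrainConfig, build_model, extract_features
from .scoring import kde_raw_scores

__all__ = ["TrainResult", "train"]


@dataclass
class TrainResult:
    model: PretextModel
    log: pd.DataFrame
    best_epoch: int
    best_val_auc: float
    skipped_images: list[int]


def _augmented_batch(
    images: list[np.ndarray],
    masks: list[np.ndarray],
    indices: np.ndarray,
    params: AugmentParams,
    seed: int,
    epoch: int,
) -> tuple[np.ndarray, np.ndarray]:
    originals, augmented = [], []
    for idx in indices:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA7_6, epoch, int(idx)]))
        aug = paste_augment(images[idx], masks[idx], params, rng)
        originals.append(images[idx])
        augmented.append(aug.image)
    x = np.stack(originals + augmented).astype(np.float32)
    labels = np.r_[np.zeros(len(indices), dtype=int), np.ones(len(indices), dtype=int)]
    return x, labels


def train(
    train_images: list[np.ndarray],
    lung_masks: list[np.ndarray],
    val_images: list[np.ndarray],
    val_labels: np.ndarray,
    config: TrainConfig,
    augment_params: AugmentParams | None = None,
) -> TrainResult:
    """Train the pretext classifier; returns the best-AUC model and a log.

    ``train_images`` must be normal images only; ``val_labels`` needs both
    classes (AUC checkpointing is undefined otherwise). Images whose lung
    mask is empty are skipped (with a record) unless the augmentation mode
    ignores segmentation.
    """
    if len(train_images) == 0:
        raise ValueError("empty training set")
    if len(train_images) != len(lung_masks):
        raise ValueError("train_images and lung_masks must be parallel lists")
    val_labels = np.asarray(val_labels).ravel().astype(int)
    if len(np.unique(val_labels)) < 2:
        raise ValueError("validation set must contain both classes for AUC checkpointing")
    if augment_params is None:
        augment_params = AugmentParams.for_image_size(config.image_size)

    need_lungs = augment_params.mode != "no_segmentation"
    usable = [
        i
        for i in range(len(train_images))
        if not need_lungs or np.asarray(lung_masks[i]).any()
    ]
    skipped = sorted(set(range(len(train_images))) - set(usable))
    if not usable:
        raise ValueError("no usable training images: all lung masks are empty")

    model = build_model(config)
    stack = np.stack([train_images[i] for i in usable])
    model.norm_mean = float(stack.mean())
    model.norm_std = float(stack.std()) or 1.0

    optimizer = nn.SGD(
        model.parameters(), lr=config.lr, momentum=config.momentum, weight_decay=config.weight_decay
    )
    pairs_per_batch = max(1, config.batch_size // 2)
    val_stack = np.stack([np.asarray(v) for v in val_images])

    rows = []
    best_auc, best_epoch, best_state = -np.inf, -1, model.state_dict()
    for epoch in range(config.epochs):
        lr = nn.cosine_annealing_lr(config.lr, epoch, config.epochs, config.cycle_len)
        perm_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xE90C, epoch]))
        perm = perm_rng.permutation(len(usable))
        total_loss, total_pairs = 0.0, 0
        for start in range(0, len(perm), pairs_per_batch):
            batch_idx = np.array([usable[j] for j in perm[start : start + pairs_per_batch]])
            try:
                x, labels = _augmented_batch(
                    train_images, lung_masks, batch_idx, augment_params, config.seed, epoch
                )
            except PlacementError:  # pragma: no cover - placement virtually never fails
                continue
            logits, _ = model.forward(x, train=True)
            n_pairs = len(batch_idx)
            loss, glogits = nn.cross_entropy_with_grad(logits, labels, grad_scale=1.0 / n_pairs)
            model.zero_grad()
            model.backward(glogits)
            optimizer.step(lr)
            total_loss += loss * n_pairs
            total_pairs += n_pairs

        bank = extract_features(model, stack, batch_size=config.batch_size)
        val_emb = extract_features(model, val_stack, batch_size=config.batch_size)
        val_auc = roc_auc(kde_raw_scores(val_emb, bank), val_labels)
        epoch_loss = total_loss / max(total_pairs, 1)
        rows.append({"epoch": epoch, "lr": lr, "loss": epoch_loss, "val_auc": val_auc})
        if val_auc > best_auc:
            best_auc, best_epoch = val_auc, epoch
            best_state = model.state_dict()

    model.load_state_dict(best_state)
    log = pd.DataFrame(rows)
    return TrainResult(
        model=model,
        log=log,
        best_epoch=best_epoch,
        best_val_auc=float(best_auc),
        skipped_images=skipped,
    )
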