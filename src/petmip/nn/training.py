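"""Training loop: AdamW + class-weighted BCE, early stopping with best-epoch
restore, reduce-on-plateau LR scheduling, patient-level splitting, grid search.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .losses import auto_class_weights, bce_with_logits_grad, weighted_bce
from .network import MipFusionNetwork, ModelConfig, build_model
from .optim import AdamW

logger = logging.getLogger("petmip.train")


@dataclass
class TrainConfig:
    lr: float = 1e-3
    weight_decay: float = 1e-4
    batch_size: int = 32
    max_epochs: int = 40
    patience: int = 5
    monitor: str = "val_loss"  # or "val_auc"
    lr_factor: float = 0.5
    lr_patience: int = 3
    min_lr: float = 1e-5
    class_weights: object = "auto"  # "auto" | None | {0: w0, 1: w1}
    seed: int = 0
    grid: dict[str, list] | None = None

    def __post_init__(self) -> None:
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.monitor not in ("val_loss", "val_auc"):
            raise ValueError("monitor must be val_loss or val_auc")
        if self.grid:
            for key, values in self.grid.items():
                if not values:
                    raise ValueError(f"empty candidate list for grid key {key!r}")


def split_patients(
    cases: list, dev_fraction: float = 0.8, seed: int = 0
) -> tuple[list, list]:
    """Patient-level 80/20 split, stratified by label; splits are disjoint and
    per-class proportions are preserved to within one patient."""
    ids = [c.case_id for c in cases]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate patient ids")
    labels = np.array([c.label for c in cases])
    for cls in (0, 1):
        if np.sum(labels == cls) < 2:
            raise ValueError(f"fewer than 2 patients in class {cls}")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        perm = rng.permutation(idx)
        n_train = int(round(dev_fraction * len(idx)))
        train_idx += perm[:n_train].tolist()
        test_idx += perm[n_train:].tolist()
    return [cases[i] for i in sorted(train_idx)], [cases[i] for i in sorted(test_idx)]


def _subset(data: dict, idx: np.ndarray) -> dict:
    return {k: np.asarray(v)[idx] for k, v in data.items()}


def _roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    from ..evalstats import roc_auc

    return roc_auc(scores, labels)


def train(
    network: MipFusionNetwork,
    train_data: dict,
    val_data: dict,
    tcfg: TrainConfig,
) -> dict:
    """Optimize the network; returns the training history.

    Validation loss/AUC are computed each epoch; training stops after
    ``patience`` epochs without improvement of the monitored quantity and the
    best-epoch weights are restored.  The learning rate halves after
    ``lr_patience`` stale epochs.  Everything is seeded and deterministic.
    """
    n_train = len(train_data["y"])
    if n_train == 0 or len(val_data["y"]) == 0:
        raise ValueError("train and validation splits must be non-empty")
    y_train = np.asarray(train_data["y"])
    weights = (
        auto_class_weights(y_train)
        if tcfg.class_weights == "auto"
        else tcfg.class_weights
    )
    opt = AdamW(
        network.params(), lr=tcfg.lr, weight_decay=tcfg.weight_decay
    )
    rng = np.random.default_rng(tcfg.seed)

    sign = 1.0 if tcfg.monitor == "val_loss" else -1.0  # minimize signed monitor
    best_value = np.inf
    best_weights = network.get_weights()
    best_epoch = 0
    stale = 0
    lr_stale = 0
    history: dict = {"train_loss": [], "val_loss": [], "val_auc": [], "lr": []}

    for epoch in range(1, tcfg.max_epochs + 1):
        order = rng.permutation(n_train)
        epoch_loss = 0.0
        for start in range(0, n_train, tcfg.batch_size):
            idx = order[start : start + tcfg.batch_size]
            batch = _subset(train_data, idx)
            opt.zero_grad()
            logits = network.forward(batch, train=True)
            loss, dlogits = bce_with_logits_grad(logits, batch["y"], weights)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch} (loss={loss}); "
                    f"lr={opt.lr}, batch size={len(idx)}"
                )
            network.backward(dlogits)
            opt.step()
            epoch_loss += loss * len(idx)
        epoch_loss /= n_train

        val_scores = network.predict_proba(val_data)
        val_loss = weighted_bce(val_scores, val_data["y"], weights)
        try:
            val_auc = _roc_auc(val_scores, val_data["y"])
        except ValueError:
            val_auc = float("nan")
        history["train_loss"].append(epoch_loss)
        history["val_loss"].append(float(val_loss))
        history["val_auc"].append(float(val_auc))
        history["lr"].append(float(opt.lr))

        monitored = val_loss if tcfg.monitor == "val_loss" else val_auc
        value = sign * monitored
        if value < best_value - 1e-12:
            best_value = value
            best_weights = network.get_weights()
            best_epoch = epoch
            stale = 0
            lr_stale = 0
        else:
            stale += 1
            lr_stale += 1
            if lr_stale >= tcfg.lr_patience and opt.lr > tcfg.min_lr:
                opt.lr = max(opt.lr * tcfg.lr_factor, tcfg.min_lr)
                lr_stale = 0
                logger.info("epoch %d: reducing lr to %.2e", epoch, opt.lr)
            if stale >= tcfg.patience:
                break

    network.set_weights(best_weights)
    history["best_epoch"] = best_epoch
    history["stopped_epoch"] = epoch
    history["class_weights"] = {int(k): float(v) for k, v in (weights or {}).items()} if isinstance(weights, dict) else None
    return history


def predict(
    network: MipFusionNetwork, data: dict, unseen_manufacturer: str = "error"
) -> np.ndarray:
    """Deterministic class-1 probabilities for a prepared data dict.

    ``unseen_manufacturer``: 'error' rejects indices outside the trained
    vocabulary; 'mean' substitutes the mean of the learned SCN rows.
    """
    if unseen_manufacturer not in ("error", "mean"):
        raise ValueError("unseen_manufacturer must be 'error' or 'mean'")
    return network.predict_proba(data, fallback=unseen_manufacturer == "mean")


def grid_search(
    base_model_config: ModelConfig,
    base_tcfg: TrainConfig,
    grid: dict[str, list],
    train_data: dict,
    val_data: dict,
) -> tuple[dict, pd.DataFrame]:
    """Exhaustive grid search over TrainConfig/ModelConfig fields.

    Every combination in the Cartesian product is trained from a fresh seeded
    network and scored by validation AUC; ties break on lower validation loss,
    then on enumeration order.  Returns (best combination, leaderboard).
    """
    if not grid:
        raise ValueError("grid must be non-empty")
    keys = list(grid.keys())
    rows = []
    best: tuple | None = None
    for rank, combo in enumerate(itertools.product(*(grid[k] for k in keys))):
        overrides = dict(zip(keys, combo))
        mcfg_fields = {k: v for k, v in overrides.items() if hasattr(base_model_config, k)}
        tcfg_fields = {k: v for k, v in overrides.items() if hasattr(base_tcfg, k)}
        unknown = set(overrides) - set(mcfg_fields) - set(tcfg_fields)
        if unknown:
            raise ValueError(f"unknown grid keys: {sorted(unknown)}")
        mcfg = replace(base_model_config, **mcfg_fields)
        tcfg = replace(base_tcfg, **tcfg_fields, grid=None)
        net = build_model(mcfg, seed=tcfg.seed)
        history = train(net, train_data, val_data, tcfg)
        i = history["best_epoch"] - 1
        val_auc = history["val_auc"][i]
        val_loss = history["val_loss"][i]
        rows.append({**overrides, "val_auc": val_auc, "val_loss": val_loss, "order": rank})
        key = (-val_auc, val_loss, rank)
        if best is None or key < best[0]:
            best = (key, overrides)
    leaderboard = pd.DataFrame(rows).sort_values(
        ["val_auc", "val_loss", "order"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return best[1], leaderboard
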