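"""The dual-view image + clinical fusion network.

Anterior and lateral MIP images pass through a shared-weight convolutional
backbone; each pooled view embedding is harmonized by a shared SCN module;
the two view embeddings are concatenated with the output of a three-layer
clinical encoder and fed to a classifier head emitting a single logit.

The shipped backbone is a small four-block strided CNN sized for CPU
training.  The ImageNet-scale backbone names are recognized configuration
values but require a GPU deep-learning stack this build does not depend on,
so selecting one raises immediately with a clear message.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .layers import Conv2d, Dense, Dropout, GlobalAvgPool, Param, ReLU, Sequential
from .scn import SCNLayer

KNOWN_BACKBONES = ("test_small_cnn", "resnet50", "efficientnetv2_s", "convnext_small")
VIEW_MODES = ("both", "anterior")


@dataclass
class ModelConfig:
    backbone: str = "test_small_cnn"
    pretrained: bool = False
    conv_channels: tuple[int, ...] = (8, 16, 32, 64)
    clinical_hidden: tuple[int, int, int] = (64, 32, 16)
    clinical_input_dim: int = 31
    n_manufacturers: int = 4
    views: str = "both"
    use_clinical: bool = True
    use_scn: bool = True
    scn_epsilon: float = 1e-6
    dropout: float = 0.0
    head_hidden: int = 32

    def __post_init__(self) -> None:
        if self.backbone not in KNOWN_BACKBONES:
            raise ValueError(
                f"unknown backbone {self.backbone!r}; choose one of {KNOWN_BACKBONES}"
            )
        if len(self.clinical_hidden) != 3:
            raise ValueError("the clinical encoder has exactly three dense layers")
        if self.views not in VIEW_MODES:
            raise ValueError(f"views must be one of {VIEW_MODES}")
        if min(self.conv_channels) < 1 or min(self.clinical_hidden) < 1:
            raise ValueError("layer sizes must be >= 1")
        if self.n_manufacturers < 1:
            raise ValueError("need at least one manufacturer")

    @property
    def image_embed_dim(self) -> int:
        return self.conv_channels[-1]


class MipFusionNetwork:
    """Numpy implementation of the fusion classifier with explicit backprop."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        if config.backbone != "test_small_cnn":
            raise NotImplementedError(
                f"backbone {config.backbone!r} needs a GPU deep-learning stack; "
                "this build ships the 'test_small_cnn' backbone"
            )
        self.config = config
        rng = np.random.default_rng(seed)

        conv_layers: list = []
        c_prev = 3
        for c in config.conv_channels:
            conv_layers += [Conv2d(c_prev, c, rng, k=3, stride=2, pad=1), ReLU()]
            c_prev = c
        self.conv = Sequential(conv_layers)
        self.pool = GlobalAvgPool()

        self.scn = SCNLayer(
            config.n_manufacturers, config.image_embed_dim, config.scn_epsilon
        ) if config.use_scn else None

        if config.use_clinical:
            h1, h2, h3 = config.clinical_hidden
            self.clin = Sequential(
                [
                    Dense(config.clinical_input_dim, h1, rng),
                    ReLU(),
                    Dense(h1, h2, rng),
                    ReLU(),
                    Dense(h2, h3, rng),
                    ReLU(),
                ]
            )
        else:
            self.clin = None

        n_views = 2 if config.views == "both" else 1
        self._img_feat_dim = n_views * config.image_embed_dim
        feat_dim = self._img_feat_dim + (
            config.clinical_hidden[-1] if config.use_clinical else 0
        )
        self.head = Sequential(
            [
                Dense(feat_dim, config.head_hidden, rng),
                ReLU(),
                Dropout(config.dropout, rng),
                Dense(config.head_hidden, 1, rng),
            ]
        )
        # Grad-CAM taps, filled on forward/backward
        self.last_conv_act: np.ndarray | None = None
        self.last_conv_grad: np.ndarray | None = None

    # ------------------------------------------------------------------
    def params(self) -> list[Param]:
        out = self.conv.params()
        if self.scn is not None:
            out += self.scn.params()
        if self.clin is not None:
            out += self.clin.params()
        out += self.head.params()
        return out

    def clinical_param_count(self) -> int:
        if self.clin is None:
            return 0
        return sum(p.value.size for p in self.clin.params())

    # ------------------------------------------------------------------
    def _stack_views(self, batch: dict) -> np.ndarray:
        def chw(img: np.ndarray) -> np.ndarray:
            return np.ascontiguousarray(
                np.asarray(img, dtype=np.float32).transpose(0, 3, 1, 2)
            )

        if self.config.views == "both":
            return np.concatenate([chw(batch["anterior"]), chw(batch["lateral"])])
        return chw(batch["anterior"])

    def forward(
        self, batch: dict, train: bool = False, fallback: bool = False
    ) -> np.ndarray:
        """Return logits (N,).  batch keys: anterior, lateral, clinical, s."""
        x = self._stack_views(batch)
        n = batch["anterior"].shape[0]
        s = np.asarray(batch["s"], dtype=int)
        sb = np.concatenate([s, s]) if self.config.views == "both" else s

        act = self.conv.forward(x, train=train)
        self.last_conv_act = act
        pooled = self.pool.forward(act, train=train)
        emb = self.scn.forward(pooled, sb, fallback=fallback) if self.scn else pooled
        emb = emb.astype(np.float32)

        if self.config.views == "both":
            img_feat = np.concatenate([emb[:n], emb[n:]], axis=1)
        else:
            img_feat = emb

        feats = [img_feat]
        if self.clin is not None:
            feats.append(
                self.clin.forward(
                    np.asarray(batch["clinical"], dtype=np.float32), train=train
                )
            )
        self._n = n
        logits = self.head.forward(np.concatenate(feats, axis=1), train=train)
        return logits[:, 0]

    def backward(self, dlogits: np.ndarray) -> None:
        """Backpropagate dL/dlogits; accumulates gradients into params."""
        dfeat = self.head.backward(
            np.asarray(dlogits, dtype=np.float32)[:, None]
        )
        dimg = dfeat[:, : self._img_feat_dim]
        if self.clin is not None:
            self.clin.backward(dfeat[:, self._img_feat_dim :])
        if self.config.views == "both":
            d = self.config.image_embed_dim
            demb = np.concatenate([dimg[:, :d], dimg[:, d:]], axis=0)
        else:
            demb = dimg
        dpooled = self.scn.backward(demb) if self.scn else demb
        dact = self.pool.backward(dpooled)
        self.last_conv_grad = dact
        self.conv.backward(dact)

    def predict_proba(
        self, batch: dict, batch_size: int = 64, fallback: bool = False
    ) -> np.ndarray:
        """Deterministic scores in [0, 1] (eval mode, batched)."""
        n = batch["anterior"].shape[0]
        out = np.empty(n, dtype=np.float64)
        for start in range(0, n, batch_size):
            sl = slice(start, min(start + batch_size, n))
            sub = {k: np.asarray(v)[sl] for k, v in batch.items()}
            z = np.clip(self.forward(sub, train=False, fallback=fallback), -15, 15)
            out[sl] = 1.0 / (1.0 + np.exp(-z))
        return out

    # ------------------------------------------------------------------
    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        own = self.params()
        if len(own) != len(weights):
            raise ValueError("weight list does not match network structure")
        for p, w in zip(own, weights):
            if p.value.shape != w.shape:
                raise ValueError("weight shape mismatch")
            p.value = w.astype(np.float32).copy()

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), *self.get_weights())
        cfg = asdict(self.config)
        path.with_suffix(".json").write_text(json.dumps(cfg, indent=2))

    @classmethod
    def load(cls, path: str | Path, seed: int = 0) -> "MipFusionNetwork":
        path = Path(path)
        cfg = json.loads(path.with_suffix(".json").read_text())
        for key in ("conv_channels", "clinical_hidden"):
            cfg[key] = tuple(cfg[key])
        net = cls(ModelConfig(**cfg), seed=seed)
        data = np.load(path.with_suffix(".npz"))
        net.set_weights([data[k] for k in data.files])
        return net


def build_model(config: ModelConfig, seed: int = 0) -> MipFusionNetwork:
    """Assemble the fusion network from its configuration."""
    return MipFusionNetwork(config, seed=seed)
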