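"""3D convolutional encoders and checkpoint (de)serialization.

Two configurations are provided:

* ``toy`` — a three-layer 3D CNN for desk-scale experiments; a forward pass
  on a 24-voxel patch takes milliseconds on one CPU core.
* ``r3d50`` — a 50-layer residual 3D network (bottleneck blocks, widths
  64/128/256/512, expansion 4) whose pooled representation concatenates the
  global average- and max-pooled 2,048-channel feature map into 4,096
  features per patch.

The projection head (2-layer MLP) is used only during contrastive
pretraining and is excluded from downstream feature extraction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import nn
from .types import Patch


@dataclass(frozen=True)
class EncoderConfig:
    architecture: str = "toy"  # "toy" or "r3d50"
    input_edge: int = 24
    toy_channels: Tuple[int, ...] = (8, 16, 32)
    batchnorm: bool = True
    pool: str = "avgmax"  # avg | max | avgmax
    proj_hidden: int = 64
    proj_dim: int = 32
    use_projection_head: bool = True

    @property
    def feature_dim(self) -> int:
        if self.architecture == "toy":
            c = self.toy_channels[-1]
        elif self.architecture == "r3d50":
            c = 2048
        else:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        return 2 * c if self.pool == "avgmax" else c


FULL_SIZE = EncoderConfig(architecture="r3d50", input_edge=50, proj_hidden=512, proj_dim=128)


def _build_toy(config: EncoderConfig, rng: np.random.Generator) -> nn.Sequential:
    layers: List[nn.Layer] = []
    in_c = 1
    for c in config.toy_channels:
        if config.batchnorm:
            layers += [nn.Conv3d(in_c, c, k=3, stride=2, padding=1, bias=False, rng=rng),
                       nn.BatchNorm3d(c), nn.ReLU()]
        else:
            layers += [nn.Conv3d(in_c, c, k=3, stride=2, padding=1, rng=rng), nn.ReLU()]
        in_c = c
    layers.append(nn.GlobalPool(config.pool))
    return nn.Sequential(layers)


def _build_r3d50(config: EncoderConfig, rng: np.random.Generator) -> nn.Sequential:
    blocks_per_stage = (3, 4, 6, 3)
    mids = (64, 128, 256, 512)
    layers: List[nn.Layer] = [
        nn.Conv3d(1, 64, k=7, stride=2, padding=3, bias=False, rng=rng),
        nn.BatchNorm3d(64),
        nn.ReLU(),
        nn.MaxPool3d(3, 2, 1),
    ]
    in_c = 64
    for stage, (nblocks, mid) in enumerate(zip(blocks_per_stage, mids)):
        out_c = mid * 4
        for b in range(nblocks):
            stride = 2 if (stage > 0 and b == 0) else 1
            layers.append(nn.Bottleneck(in_c, mid, out_c, stride=stride, rng=rng))
            in_c = out_c
    layers.append(nn.GlobalPool(config.pool))
    return nn.Sequential(layers)


class Encoder:
    """Backbone + optional projection head with explicit forward/backward."""

    def __init__(self, config: EncoderConfig, rng: Optional[np.random.Generator] = None):
        rng = np.random.default_rng(rng)
        self.config = config
        if config.architecture == "toy":
            self.backbone = _build_toy(config, rng)
        elif config.architecture == "r3d50":
            self.backbone = _build_r3d50(config, rng)
        else:
            raise ValueError(f"unknown architecture {config.architecture!r}")
        if config.use_projection_head:
            self.projector: Optional[nn.Sequential] = nn.Sequential([
                nn.Linear(config.feature_dim, config.proj_hidden, rng=rng),
                nn.ReLU(),
                nn.Linear(config.proj_hidden, config.proj_dim, rng=rng),
            ])
        else:
            self.projector = None

    # -- forward ----------------------------------------------------------
    @staticmethod
    def _as_batch(patches: Sequence[Patch] | np.ndarray, edge: int) -> np.ndarray:
        if isinstance(patches, np.ndarray):
            arr = patches
            if arr.ndim == 3:
                arr = arr[None]
            if arr.ndim == 4:
                arr = arr[:, None]
        else:
            for p in patches:
                if not p.normalized:
                    raise ValueError("encoder expects normalized patches")
            arr = np.stack([p.values for p in patches])[:, None]
        if arr.shape[-1] != edge:
            raise ValueError(f"patch edge {arr.shape[-1]} does not match encoder input edge {edge}")
        return arr.astype(np.float32)

    def features(self, patches, train: bool = False) -> np.ndarray:
        """Backbone features (projection head excluded); deterministic in eval."""
        x = self._as_batch(patches, self.config.input_edge)
        return self.backbone.forward(x, train=train)

    def project(self, patches, train: bool = False) -> np.ndarray:
        """Unit-normalized projection-space embeddings used by the loss."""
        feats = self.features(patches, train=train)
        if self.projector is not None:
            self._pre_norm = self.projector.forward(feats, train=train)
        else:
            self._pre_norm = feats
        return nn.l2_normalize(self._pre_norm, axis=1)

    def backward_from_embedding_grad(self, grad_z: np.ndarray, guided: bool = False) -> None:
        """Backpropagate a gradient w.r.t. the unit embeddings into all weights."""
        g = nn.l2_normalize_backward(self._pre_norm, grad_z, axis=1).astype(np.float32)
        if self.projector is not None:
            g = self.projector.backward(g, guided=guided)
        self.backbone.backward(g, guided=guided)

    def recalibrate_bn(self, patches, passes: int = 2, momentum: float = 0.5,
                       batch: int = 32) -> None:
        """Re-estimate batch-norm running statistics on unaugmented patches.

        During contrastive pretraining the running statistics are computed
        over augmented lesion views mixed with background negatives, which
        biases eval-mode normalization for plain lesion patches.  A couple
        of forward passes over the (label-free) training patches restores
        calibrated statistics.  No weights are changed.
        """
        bns = [l for l in self.backbone.layers if isinstance(l, nn.BatchNorm3d)]
        if not bns:
            return
        old = [(l.momentum) for l in bns]
        for l in bns:
            l.momentum = momentum
        arr = self._as_batch(patches, self.config.input_edge)
        for _ in range(passes):
            for s in range(0, len(arr), batch):
                self.backbone.forward(arr[s:s + batch], train=True)
        for l, m in zip(bns, old):
            l.momentum = m

    def parameters(self) -> List[nn.Param]:
        params = self.backbone.parameters()
        if self.projector is not None:
            params += self.projector.parameters()
        return params

    def state_arrays(self) -> List[np.ndarray]:
        arrs = self.backbone.state_arrays()
        if self.projector is not None:
            arrs += self.projector.state_arrays()
        return arrs


@dataclass
class Checkpoint:
    """Weights plus everything needed to rebuild the encoder."""

    config: EncoderConfig
    arrays: List[np.ndarray]
    meta: dict = field(default_factory=dict)

    @classmethod
    def from_encoder(cls, encoder: Encoder, **meta) -> "Checkpoint":
        return cls(config=encoder.config,
                   arrays=[a.copy() for a in encoder.state_arrays()], meta=dict(meta))

    def build_encoder(self) -> Encoder:
        enc = Encoder(self.config, rng=np.random.default_rng(0))
        dsts = enc.state_arrays()
        if len(dsts) != len(self.arrays):
            raise ValueError("checkpoint does not match encoder architecture")
        for dst, src in zip(dsts, self.arrays):
            dst[...] = src
        return enc

    def save(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        header = json.dumps({"config": asdict(self.config), "meta": self.meta})
        np.savez(path, __header__=np.frombuffer(header.encode(), dtype=np.uint8),
                 **{f"arr_{i:04d}": a for i, a in enumerate(self.arrays)})
        return path

    @classmethod
    def load(cls, path) -> "Checkpoint":
        with np.load(path) as data:
            header = json.loads(bytes(data["__header__"].tobytes()).decode())
            keys = sorted(k for k in data.files if k.startswith("arr_"))
            arrays = [data[k] for k in keys]
        cfg = header["config"]
        cfg["toy_channels"] = tuple(cfg["toy_channels"])
        return cls(config=EncoderConfig(**cfg), arrays=arrays, meta=header.get("meta", {}))
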