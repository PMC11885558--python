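"""Hybrid ResNeXt-SE + Transformer classifier for S-transform tensors.

The network consumes a 2-channel (real, imaginary) time-frequency image and
produces class logits:

* **Feature extractor** — a 7×7/stride-2 stem with 3×3/stride-2 max-pool,
  then four stages of two ResNeXt bottleneck blocks each (grouped 3×3
  convolutions, squeeze-and-excitation channel gating with reduction 16,
  per-sample stochastic depth on the residual branch); stages 2–4 halve the
  spatial dimensions.  Spatial sizes follow ceil(H/stride) ("same" padding),
  so a 151×1000 input reaches 5×32 after five halvings.
* **Sequence encoder** — the [B, C, H', W'] map is flattened
  frequency-row-major into [B, T, C] (T = H'·W'), a learnable additive 2-D
  positional encoding (one vector per row index plus one per column index)
  is added, four post-norm Transformer encoder blocks follow, a global
  residual connection adds the encoder input back to its output, and mean
  pooling over T yields one embedding per sample.
* **Head** — Linear → LayerNorm → Linear to the class logits.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn
from .nn import Tensor

__all__ = ["ModelConfig", "desk_config", "SEBlock", "ResNeXtSEBlock",
           "HybridECGClassifier", "build_model", "save_checkpoint",
           "load_checkpoint"]


@dataclass(frozen=True)
class ModelConfig:
    in_channels: int = 2
    stage_widths: tuple[int, ...] = (64, 128, 256, 512)
    blocks_per_stage: int = 2
    cardinality: int = 32
    se_reduction: int = 16
    stochastic_depth_p: float = 0.2
    embed_dim: int = 512
    n_transformer_blocks: int = 4
    n_heads: int = 8
    ffn_dim: int = 2048
    dropout: float = 0.2
    head_hidden: int = 256
    n_classes: int = 5
    input_shape: tuple[int, int] = (151, 1000)

    def validate(self):
        if self.embed_dim % self.n_heads:
            raise ValueError(
                f"embed_dim ({self.embed_dim}) must be divisible by "
                f"n_heads ({self.n_heads})")
        for w in self.stage_widths:
            gw = w // 2
            if gw % self.cardinality:
                raise ValueError(
                    f"group width {gw} (= {w}/2) must be divisible by "
                    f"cardinality {self.cardinality}")
        if self.n_classes < 2:
            raise ValueError("n_classes must be at least 2")

    @property
    def feature_shape(self) -> tuple[int, int]:
        """Spatial size of the extractor output: five ceil-halvings."""
        h, w = self.input_shape
        for _ in range(5):
            h = math.ceil(h / 2)
            w = math.ceil(w / 2)
        return h, w


def desk_config(n_classes: int = 4, input_shape=(151, 1000)) -> ModelConfig:
    """A small instance of the same architecture for CPU-scale studies.

    Every structural element (stem, 4×2 ResNeXt-SE blocks, 4 Transformer
    blocks, global skip, mean pooling, 2-layer head) is retained; only the
    widths shrink so that a full training run fits on one CPU core.
    """
    return ModelConfig(stage_widths=(8, 16, 32, 64), cardinality=4,
                       embed_dim=64, n_heads=4, ffn_dim=128, head_hidden=32,
                       n_classes=n_classes, input_shape=input_shape)


class SEBlock(nn.Module):
    """Squeeze-and-excitation: global-average squeeze, two-layer bottleneck
    excitation with sigmoid gate, channelwise rescale."""

    def __init__(self, rng, channels: int, reduction: int = 16):
        super().__init__()
        hidden = max(1, channels // reduction)
        self.fc1 = nn.Linear(rng, channels, hidden)
        self.fc2 = nn.Linear(rng, hidden, channels)

    def gate(self, x: Tensor) -> Tensor:
        s = x.mean(axis=(2, 3))                 # [B, C]
        return self.fc2(self.fc1(s).relu()).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        B, C = x.shape[:2]
        return x * self.gate(x).reshape(B, C, 1, 1)


class ResNeXtSEBlock(nn.Module):
    """ResNeXt bottleneck with SE recalibration and stochastic depth.

    1×1 reduce (in → group_width) → grouped 3×3 (stride) → 1×1 restore
    (→ out), BN+ReLU between, SE gate on the branch, stochastic depth, then
    the residual add (1×1-projected shortcut when the shape changes).
    """

    def __init__(self, rng, in_planes: int, out_planes: int, stride: int,
                 cardinality: int = 32, se_reduction: int = 16,
                 drop_p: float = 0.2):
        super().__init__()
        gw = out_planes // 2
        if gw % cardinality:
            raise ValueError(f"group width {gw} not divisible by "
                             f"cardinality {cardinality}")
        self.conv1 = nn.Conv2d(rng, in_planes, gw, 1, bias=False)
        self.bn1 = nn.BatchNorm2d(gw)
        self.conv2 = nn.Conv2d(rng, gw, gw, 3, stride=stride,
                               groups=cardinality, bias=False)
        self.bn2 = nn.BatchNorm2d(gw)
        self.conv3 = nn.Conv2d(rng, gw, out_planes, 1, bias=False)
        self.bn3 = nn.BatchNorm2d(out_planes)
        self.se: SEBlock | None = SEBlock(rng, out_planes, se_reduction)
        self.drop_path = nn.DropPath(drop_p)
        if stride != 1 or in_planes != out_planes:
            self.proj = nn.Conv2d(rng, in_planes, out_planes, 1, stride=stride,
                                  bias=False)
            self.proj_bn = nn.BatchNorm2d(out_planes)
        else:
            self.proj = None

    def forward(self, x: Tensor) -> Tensor:
        branch = self.bn1(self.conv1(x)).relu()
        branch = self.bn2(self.conv2(branch)).relu()
        branch = self.bn3(self.conv3(branch))
        if self.se is not None:
            branch = self.se(branch)
        branch = self.drop_path(branch)
        shortcut = x if self.proj is None else self.proj_bn(self.proj(x))
        return (shortcut + branch).relu()


class HybridECGClassifier(nn.Module):
    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        config.validate()
        self.config = config
        rng = np.random.default_rng(seed)
        w = config.stage_widths

        self.stem_conv = nn.Conv2d(rng, config.in_channels, w[0], 7, stride=2,
                                   bias=False)
        self.stem_bn = nn.BatchNorm2d(w[0])
        self.pool = nn.MaxPool2d(3, 2, 1)

        self.stages: list[nn.Module] = []
        in_planes = w[0]
        for si, width in enumerate(w):
            for bi in range(config.blocks_per_stage):
                stride = 2 if (si > 0 and bi == 0) else 1
                self.stages.append(ResNeXtSEBlock(
                    rng, in_planes, width, stride, config.cardinality,
                    config.se_reduction, config.stochastic_depth_p))
                in_planes = width

        self.proj = nn.Conv2d(rng, w[-1], config.embed_dim, 1)

        hp, wp = config.feature_shape
        self.pos_row = Tensor(
            rng.normal(0, 0.02, (hp, config.embed_dim)).astype(np.float32),
            requires_grad=True)
        self.pos_col = Tensor(
            rng.normal(0, 0.02, (wp, config.embed_dim)).astype(np.float32),
            requires_grad=True)

        self.blocks = [nn.TransformerBlock(rng, config.embed_dim,
                                           config.n_heads, config.ffn_dim,
                                           config.dropout)
                       for _ in range(config.n_transformer_blocks)]

        self.head_fc1 = nn.Linear(rng, config.embed_dim, config.head_hidden)
        self.head_ln = nn.LayerNorm(config.head_hidden)
        self.head_fc2 = nn.Linear(rng, config.head_hidden, config.n_classes)

    # ----------------------------------------------------------------- parts
    def extract_features(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.config.in_channels:
            raise ValueError(
                f"expected {self.config.in_channels} input channels, "
                f"got {x.shape[1]}")
        y = self.pool(self.stem_bn(self.stem_conv(x)).relu())
        for block in self.stages:
            y = block(y)
        return self.proj(y)

    def encode_sequence(self, f: Tensor, return_sequence: bool = False):
        """Flatten a [B, D, H', W'] map, add the 2-D positional encoding,
        run the Transformer encoder with a global residual skip, and mean-pool
        over the sequence axis."""
        B, C, Hp, Wp = f.shape
        if C != self.config.embed_dim:
            raise ValueError(f"expected {self.config.embed_dim} channels, got {C}")
        if Hp > self.pos_row.shape[0] or Wp > self.pos_col.shape[0]:
            raise ValueError("feature map larger than the positional table")
        seq = f.reshape(B, C, Hp * Wp).transpose(0, 2, 1)   # row-major [B,T,D]
        pe = (self.pos_row[:Hp].reshape(Hp, 1, C)
              + self.pos_col[:Wp].reshape(1, Wp, C)).reshape(1, Hp * Wp, C)
        seq = seq + pe
        x = seq
        for block in self.blocks:
            x = block(x)
        x = x + seq                                          # global skip
        pooled = x.mean(axis=1)
        return (pooled, seq) if return_sequence else pooled

    def head(self, pooled: Tensor) -> Tensor:
        return self.head_fc2(self.head_ln(self.head_fc1(pooled)))

    def forward(self, x) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x))
        return self.head(self.encode_sequence(self.extract_features(x)))

    def trace_shapes(self, x) -> dict[str, tuple]:
        """Forward pass that records the shapes of the named intermediates."""
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x))
        f = self.extract_features(x)
        pooled, seq = self.encode_sequence(f, return_sequence=True)
        logits = self.head(pooled)
        return {"feature_map": f.shape, "sequence": seq.shape,
                "pooled": pooled.shape, "logits": logits.shape}

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


def build_model(config: ModelConfig = ModelConfig(), seed: int = 0) -> HybridECGClassifier:
    """Construct the classifier; raises on config invariant violations."""
    return HybridECGClassifier(config, seed=seed)


def save_checkpoint(model: HybridECGClassifier, path):
    """Weights as an ``.npz`` archive plus a JSON config sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = model.state_dict()
    np.savez(path, **state)
    sidecar = path.with_suffix(".json")
    cfg = asdict(model.config)
    sidecar.write_text(json.dumps(cfg, indent=2))


def load_checkpoint(path) -> HybridECGClassifier:
    path = Path(path)
    cfg = json.loads(path.with_suffix(".json").read_text())
    cfg["stage_widths"] = tuple(cfg["stage_widths"])
    cfg["input_shape"] = tuple(cfg["input_shape"])
    model = build_model(ModelConfig(**cfg))
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as z:
        model.load_state_dict({k: z[k] for k in z.files})
    return model
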