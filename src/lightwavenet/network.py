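"""The LightWaveNet classifier.

Layout: a 7x7/stride-2 stem with 3x3 max pooling (input/4), then four
densely connected stages of wavelet pooling modules (WPM).  Each WPM
compresses its input to the growth rate ``k`` with BN-ReLU-1x1, splits the
channels in half, runs a 5x5 wavelet convolution branch (low-frequency
context) in parallel with a max-pool + 1x1 branch (high-frequency texture),
fuses with a 1x1 convolution and adds the compressed feature back as a
residual.  Between stages a transition block compresses channels by the
coefficient theta and halves resolution with the sum of a 3x3 max pool and
a 3x3 average pool.  Auxiliary linear classifiers hang off the first three
stage outputs (training only); the main head reads the globally averaged
stage-4 feature.

With the default configuration the stage outputs carry 128/192/288/400
channels at 1/4, 1/8, 1/16 and 1/32 of the input resolution, and the
inference network holds 0.28 M learnable parameters.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Union

import numpy as np

from . import _engine as E
from ._engine import autograd as F
from .errors import ConfigError, DimensionError, UsageError
from .wavelet_ops import WTConv2d

__all__ = [
    "NetConfig",
    "NetworkOutput",
    "WPM",
    "DenseBlock",
    "DownsampleBlock",
    "AuxHead",
    "LightWaveNet",
    "count_parameters",
    "complexity_audit",
    "save_checkpoint",
    "load_checkpoint",
]

_AUX_PREFIX = "aux_heads."


@dataclass(frozen=True)
class NetConfig:
    """All architectural constants.

    The channel ledger is fixed by (stem_channels, growth_rate,
    wpm_per_stage, theta): a stage with input C0 and n modules emits
    C0 + n*k channels, and each transition keeps theta of them.  The
    defaults yield stage widths [128, 192, 288, 400].
    """

    num_classes: int = 10
    stem_channels: int = 64
    growth_rate: int = 32
    wpm_per_stage: tuple = (2, 4, 6, 8)
    theta: float = 0.5
    wt_kernel: int = 5
    wt_levels: int = 1
    input_size: int = 224
    lambda_aux: float = 0.1

    def __post_init__(self):
        if self.num_classes < 2:
            raise ConfigError("num_classes must be >= 2")
        if not 0.0 < self.theta <= 1.0:
            raise ConfigError(f"theta must lie in (0, 1], got {self.theta}")
        if self.growth_rate % 2:
            raise ConfigError("growth_rate must be even (WPM splits it in half)")
        if self.wt_kernel % 2 == 0:
            raise ConfigError("wt_kernel must be odd")
        if self.wt_levels < 1:
            raise ConfigError("wt_levels must be >= 1")
        if not 0.0 <= self.lambda_aux <= 1.0:
            raise ConfigError("lambda_aux must lie in [0, 1]")
        if len(self.wpm_per_stage) != 4 or any(n < 1 for n in self.wpm_per_stage):
            raise ConfigError("wpm_per_stage must be 4 positive integers")
        object.__setattr__(self, "wpm_per_stage", tuple(int(n) for n in self.wpm_per_stage))
        self.stage_channels  # validates the theta*C arithmetic

    @property
    def stage_channels(self) -> List[int]:
        """Channel count emitted by each dense stage (before transition)."""
        c = self.stem_channels
        out = []
        for i, n in enumerate(self.wpm_per_stage):
            c = c + n * self.growth_rate
            out.append(c)
            if i < 3:
                tc = self.theta * c
                if abs(tc - round(tc)) > 1e-9:
                    raise ConfigError(
                        f"theta * C must be integral at every transition; "
                        f"got theta={self.theta}, C={c}"
                    )
                c = int(round(tc))
        return out

    @property
    def feature_dim(self) -> int:
        """Dimension of the pooled vector feeding the main classifier."""
        return self.stage_channels[-1]

    @classmethod
    def tiny(cls, num_classes: int = 4, input_size: int = 64) -> "NetConfig":
        """A small configuration for desk-scale experiments and tests."""
        return cls(
            num_classes=num_classes,
            stem_channels=32,
            growth_rate=16,
            wpm_per_stage=(2, 2, 2, 2),
            input_size=input_size,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetConfig":
        d = dict(d)
        if "wpm_per_stage" in d:
            d["wpm_per_stage"] = tuple(d["wpm_per_stage"])
        return cls(**d)


@dataclass
class NetworkOutput:
    """Forward-pass result.

    ``aux_logits`` is present only for a training-mode forward;
    ``stage_features`` holds the globally averaged per-stage vectors when
    requested, ``stage_maps`` the raw stage outputs.
    """

    main_logits: E.Tensor
    aux_logits: Optional[List[E.Tensor]] = None
    stage_features: Optional[List[E.Tensor]] = None
    stage_maps: Optional[List[E.Tensor]] = None


class WPM(E.Module):
    """Wavelet pooling module: compress, split, dual-branch, fuse, residual."""

    def __init__(
        self,
        in_channels: int,
        growth_rate: int,
        *,
        wt_kernel: int = 5,
        wt_levels: int = 1,
        rng: np.random.Generator,
    ):
        super().__init__()
        if growth_rate % 2:
            raise ConfigError(f"growth rate must be even, got {growth_rate}")
        if in_channels < growth_rate:
            raise DimensionError(
                f"WPM input must carry at least growth_rate channels "
                f"({in_channels} < {growth_rate})"
            )
        half = growth_rate // 2
        self.growth_rate = growth_rate
        self.bn_in = E.BatchNorm2d(in_channels)
        self.compress = E.Conv2d(in_channels, growth_rate, 1, bias=False, rng=rng)
        self.wt = WTConv2d(half, wt_kernel, wt_levels, rng=rng)
        self.bn_wt = E.BatchNorm2d(half)
        self.pool = E.MaxPool2d(3, stride=1, padding=1)
        self.conv_hf = E.Conv2d(half, half, 1, bias=False, rng=rng)
        self.bn_hf = E.BatchNorm2d(half)
        self.fuse = E.Conv2d(growth_rate, growth_rate, 1, bias=False, rng=rng)

    def forward(self, x: E.Tensor) -> E.Tensor:
        k = self.growth_rate
        half = k // 2
        z = self.compress(F.relu(self.bn_in(x)))
        x1 = F.narrow(z, 0, half)
        x2 = F.narrow(z, half, half)
        y1 = F.gelu(self.bn_wt(self.wt(x1)))
        y2 = F.gelu(self.bn_hf(self.conv_hf(self.pool(x2))))
        fused = self.fuse(F.concat([y1, y2], axis=1))
        return F.add(fused, z)  # residual over the compressed feature


class DenseBlock(E.Module):
    """n WPM layers, each fed the concatenation of everything before it."""

    def __init__(
        self,
        in_channels: int,
        num_layers: int,
        growth_rate: int,
        *,
        wt_kernel: int = 5,
        wt_levels: int = 1,
        rng: np.random.Generator,
    ):
        super().__init__()
        if num_layers < 1:
            raise ConfigError("a dense block needs at least one layer")
        self.out_channels = in_channels + num_layers * growth_rate
        self.layers = E.ModuleList(
            [
                WPM(
                    in_channels + i * growth_rate,
                    growth_rate,
                    wt_kernel=wt_kernel,
                    wt_levels=wt_levels,
                    rng=rng,
                )
                for i in range(num_layers)
            ]
        )

    def forward(self, x: E.Tensor) -> E.Tensor:
        feats = [x]
        for layer in self.layers:
            inp = feats[0] if len(feats) == 1 else F.concat(feats, axis=1)
            feats.append(layer(inp))
        return F.concat(feats, axis=1)


class DownsampleBlock(E.Module):
    """Transition: BN-ReLU-1x1 to theta*C channels, then max+avg pooled sum."""

    def __init__(self, in_channels: int, theta: float, *, rng: np.random.Generator):
        super().__init__()
        tc = theta * in_channels
        if abs(tc - round(tc)) > 1e-9:
            raise ConfigError(
                f"theta * C must be integral, got theta={theta}, C={in_channels}"
            )
        self.out_channels = int(round(tc))
        self.bn = E.BatchNorm2d(in_channels)
        self.conv = E.Conv2d(in_channels, self.out_channels, 1, bias=False, rng=rng)
        self.maxpool = E.MaxPool2d(3, stride=2, padding=1)
        self.avgpool = E.AvgPool2d(3, stride=2, padding=1)

    def forward(self, x: E.Tensor) -> E.Tensor:
        f = self.conv(F.relu(self.bn(x)))
        return F.add(self.maxpool(f), self.avgpool(f))


class AuxHead(E.Module):
    """GAP + linear projection used for stage-wise supervision."""

    def __init__(self, in_features: int, num_classes: int, *, rng: np.random.Generator):
        super().__init__()
        self.in_features = in_features
        self.fc = E.Linear(in_features, num_classes, bias=True, rng=rng, init="zero")

    def forward(self, fmap: E.Tensor) -> E.Tensor:
        return self.fc(F.gap(fmap))


class LightWaveNet(E.Module):
    """The full classifier; see the module docstring for the layout."""

    def __init__(self, config: NetConfig, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.config = config
        cfg = config
        self.stem_conv = E.Conv2d(3, cfg.stem_channels, 7, stride=2, padding=3, bias=False, rng=rng)
        self.stem_bn = E.BatchNorm2d(cfg.stem_channels)
        self.stem_pool = E.MaxPool2d(3, stride=2, padding=1)

        stages, transitions, aux_heads = [], [], []
        c = cfg.stem_channels
        for i, n in enumerate(cfg.wpm_per_stage):
            block = DenseBlock(
                c, n, cfg.growth_rate, wt_kernel=cfg.wt_kernel, wt_levels=cfg.wt_levels, rng=rng
            )
            c = block.out_channels
            stages.append(block)
            if i < 3:
                aux_heads.append(AuxHead(c, cfg.num_classes, rng=rng))
                tr = DownsampleBlock(c, cfg.theta, rng=rng)
                transitions.append(tr)
                c = tr.out_channels
        self.stages = E.ModuleList(stages)
        self.transitions = E.ModuleList(transitions)
        self.aux_heads = E.ModuleList(aux_heads)
        self.final_bn = E.BatchNorm2d(c)  # normalizes the dense stream before pooling
        self.head = E.Linear(c, cfg.num_classes, bias=True, rng=rng, init="zero")

    # -- pieces exposed for inspection --------------------------------------
    def stem_forward(self, x: E.Tensor) -> E.Tensor:
        if x.shape[1] != 3:
            raise DimensionError(f"expected 3 input channels, got {x.shape[1]}")
        h = F.relu(self.stem_bn(self.stem_conv(x)))
        return self.stem_pool(h)

    def aux_forward(self, stage: int, fmap: E.Tensor) -> np.ndarray:
        """Class probabilities from the auxiliary head of stage 1..3."""
        if stage not in (1, 2, 3):
            raise UsageError(
                f"auxiliary heads exist for stages 1-3 only (stage 4 uses the "
                f"main head); got stage={stage}"
            )
        logits = self.aux_heads[stage - 1](fmap)
        return F.softmax(logits.data, axis=1)

    # -- full forward --------------------------------------------------------
    def forward(
        self,
        x: Union[E.Tensor, np.ndarray],
        *,
        collect_features: bool = False,
        collect_maps: bool = False,
    ) -> NetworkOutput:
        if not isinstance(x, E.Tensor):
            x = E.Tensor(np.asarray(x, dtype=np.float32))
        if x.ndim == 3:
            x = F.reshape(x, (1,) + x.shape)
        h = self.stem_forward(x)
        aux_logits: List[E.Tensor] = []
        stage_features: List[E.Tensor] = []
        stage_maps: List[E.Tensor] = []
        for i, block in enumerate(self.stages):
            h = block(h)
            if collect_maps:
                stage_maps.append(h)
            if collect_features:
                stage_features.append(F.gap(h))
            if i < 3:
                if self.training:
                    aux_logits.append(self.aux_heads[i](h))
                h = self.transitions[i](h)
        main = self.head(F.gap(F.relu(self.final_bn(h))))
        return NetworkOutput(
            main_logits=main,
            aux_logits=aux_logits if self.training else None,
            stage_features=stage_features if collect_features else None,
            stage_maps=stage_maps if collect_maps else None,
        )

    def predict_proba(self, images: np.ndarray, batch_size: int = 32) -> np.ndarray:
        """Eval-mode class probabilities for a (N, 3, H, W) batch."""
        was_training = self.training
        self.eval()
        try:
            outs = []
            with E.no_grad():
                for lo in range(0, len(images), batch_size):
                    out = self.forward(images[lo : lo + batch_size])
                    outs.append(F.softmax(out.main_logits.data, axis=1))
            return np.concatenate(outs, axis=0)
        finally:
            self.train(was_training)


def count_parameters(
    model_or_config: Union[LightWaveNet, NetConfig], include_aux: bool = False
) -> int:
    """Exact count of learnable scalars; aux heads excluded by default."""
    model = (
        model_or_config
        if isinstance(model_or_config, LightWaveNet)
        else LightWaveNet(model_or_config, seed=0)
    )
    total = 0
    for name, p in model.named_parameters():
        if not include_aux and name.startswith(_AUX_PREFIX):
            continue
        total += p.data.size
    return int(total)


def complexity_audit(config: NetConfig, seed: int = 0) -> dict:
    """Parameters, forward MACs, and 32-bit serialized size of the inference net.

    ``flops`` counts multiply-accumulates of one eval-mode forward pass on a
    3 x input_size x input_size image (conv/linear MACs plus 4 MACs per
    wavelet analysis/synthesis coefficient; pooling, normalization and
    activations are free).  ``serialized_bytes`` stores every parameter and
    persistent normalization statistic at 4 bytes.
    """
    model = LightWaveNet(config, seed=seed)
    model.eval()
    params = count_parameters(model, include_aux=False)
    buffers = sum(
        b.size for name, b in model.named_buffers() if not name.startswith(_AUX_PREFIX)
    )
    x = np.zeros((1, 3, config.input_size, config.input_size), dtype=np.float32)
    with E.no_grad(), F.count_macs() as counter:
        model.forward(x)
    return {
        "parameters": params,
        "parameters_with_aux": count_parameters(model, include_aux=True),
        "flops": counter["macs"],
        "serialized_bytes": 4 * (params + buffers),
        "input_size": config.input_size,
    }


def save_checkpoint(model: LightWaveNet, path: Union[str, Path]) -> None:
    """Single-archive checkpoint with the architecture embedded."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = model.state_dict()
    np.savez(path, __config__=json.dumps(model.config.to_dict()), **state)


def load_checkpoint(path: Union[str, Path]) -> LightWaveNet:
    path = Path(path)
    with np.load(path, allow_pickle=False) as archive:
        cfg = NetConfig.from_dict(json.loads(str(archive["__config__"])))
        state = {k: archive[k] for k in archive.files if k != "__config__"}
    model = LightWaveNet(cfg, seed=0)
    model.load_state_dict(state)
    model.eval()
    return model
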