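"""The nucleotide-level coverage-regression network and its companions.

The main model is a U-shaped encoder/decoder: three convolutional blocks with
pooling reduce a one-hot (or one-hot + accessibility) sequence to a bottleneck,
a bidirectional GRU adds long-range context, a pyramid pooling module (SPPM)
injects multi-scale context, and three up-sample blocks restore base
resolution, each fused with the same-level encoder feature through a
refinement residual block (RRB).  The output head is a width-1 linear
convolution producing one predicted coverage value per base.

The network partitions exactly into a *generator* (encoder: conv blocks + GRU
+ SPPM, emitting three skip features plus the bottleneck) and a *predictor*
(RRBs + decoder + output head); the adversarial adaptation stage fine-tunes
the generator only.  A species discriminator and a small sequence-level
baseline (scalar regression on window maxima) complete the cast.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .nn import (
    Adam,
    BatchNorm1d,
    BiGRU,
    Conv1d,
    Dropout,
    Linear,
    Module,
    Tensor,
    concatenate,
)

__all__ = [
    "ModelConfig",
    "NLDNNModel",
    "Generator",
    "Predictor",
    "Discriminator",
    "SeqLevelBaseline",
    "build_nldnn",
    "build_discriminator",
    "build_baseline",
    "split_generator_predictor",
    "save_model",
    "load_model",
]


@dataclass
class ModelConfig:
    in_channels: int = 4  # 5 = one-hot + accessibility channel
    conv_channels: tuple[int, int, int] = (64, 128, 256)
    conv_kernels: tuple[int, int, int] = (15, 5, 3)
    pool_sizes: tuple[int, int, int] = (5, 2, 2)
    dropout: float = 0.2
    gru_hidden: int = 128
    sppm_scales: tuple[int, ...] = (1, 2, 4)
    rrb_channels: int = 64
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")
        if self.in_channels not in (4, 5):
            raise ValueError("in_channels must be 4 or 5")

    @property
    def pool_product(self) -> int:
        return int(np.prod(self.pool_sizes))


class _EncoderBlock(Module):
    """conv -> ELU (pre-pool feature kept as skip) -> max-pool -> dropout."""

    def __init__(self, c_in, c_out, kernel, pool, dropout, rng, drop_rng):
        super().__init__()
        self.conv = Conv1d(c_in, c_out, kernel, rng)
        self.pool = pool
        self.drop = Dropout(dropout, drop_rng)

    def __call__(self, x: Tensor) -> tuple[Tensor, Tensor]:
        pre = self.conv(x).elu()
        return pre, self.drop(pre.maxpool1d(self.pool))


class _SPPM(Module):
    """Simple pyramid pooling: per-scale mean pool, 1x1 conv, upsample, sum."""

    def __init__(self, channels, scales, rng):
        super().__init__()
        self.scales = tuple(scales)
        for i, _ in enumerate(self.scales):
            setattr(self, f"proj{i}", Conv1d(channels, channels, 1, rng))

    def __call__(self, x: Tensor) -> Tensor:
        L = x.shape[2]
        out = x
        for i, s in enumerate(self.scales):
            branch = getattr(self, f"proj{i}")(x.avgpool_to(s)).upsample_to(L)
            out = out + branch
        return out


class Generator(Module):
    """Encoder: three conv blocks, bidirectional GRU, SPPM.

    Returns the three same-level skip features (pre-pool conv activations)
    plus the bottleneck feature map.
    """

    def __init__(self, cfg: ModelConfig, rng, drop_rng):
        super().__init__()
        c = cfg.conv_channels
        chans = (cfg.in_channels, *c)
        for i in range(3):
            setattr(self, f"block{i}", _EncoderBlock(
                chans[i], chans[i + 1], cfg.conv_kernels[i], cfg.pool_sizes[i],
                cfg.dropout, rng, drop_rng,
            ))
        self.gru = BiGRU(c[2], cfg.gru_hidden, rng)
        self.gru_proj = Conv1d(2 * cfg.gru_hidden, c[2], 1, rng)
        self.sppm = _SPPM(c[2], cfg.sppm_scales, rng)

    def __call__(self, x: Tensor) -> tuple[Tensor, Tensor, Tensor, Tensor]:
        skips = []
        h = x
        for i in range(3):
            pre, h = getattr(self, f"block{i}")(h)
            skips.append(pre)
        seq = h.transpose(0, 2, 1)  # (N, B, C)
        g = self.gru(seq).transpose(0, 2, 1)  # (N, 2*hidden, B)
        h = self.gru_proj(g)
        h = self.sppm(h)
        return skips[0], skips[1], skips[2], h


class _RRB(Module):
    """Refinement residual block fusing a skip feature with a decoder feature."""

    def __init__(self, skip_channels, channels, rng):
        super().__init__()
        self.proj = Conv1d(skip_channels, channels, 1, rng)
        self.conv_a = Conv1d(channels, channels, 3, rng)
        self.bn = BatchNorm1d(channels)
        self.conv_b = Conv1d(channels, channels, 3, rng)

    def __call__(self, skip: Tensor, up: Tensor) -> Tensor:
        h = self.proj(skip) + up
        r = self.conv_b(self.bn(self.conv_a(h)).relu())
        return h + r


class _UpBlock(Module):
    """upsample -> BN -> ReLU -> conv (the blending layer)."""

    def __init__(self, c_in, c_out, factor, rng):
        super().__init__()
        self.factor = factor
        self.bn = BatchNorm1d(c_in)
        self.conv = Conv1d(c_in, c_out, 3, rng)

    def __call__(self, x: Tensor) -> Tensor:
        up = x.upsample_to(x.shape[2] * self.factor)
        return self.conv(self.bn(up).relu())


class Predictor(Module):
    """Connection (RRBs) + decoder (up-sample blocks) + linear output head."""

    def __init__(self, cfg: ModelConfig, rng):
        super().__init__()
        c = cfg.conv_channels
        r = cfg.rrb_channels
        p = cfg.pool_sizes
        self.up0 = _UpBlock(c[2], r, p[2], rng)
        self.rrb0 = _RRB(c[2], r, rng)  # fuses block-3 pre-pool skip
        self.up1 = _UpBlock(r, r, p[1], rng)
        self.rrb1 = _RRB(c[1], r, rng)
        self.up2 = _UpBlock(r, r, p[0], rng)
        self.rrb2 = _RRB(c[0], r, rng)
        self.head = Conv1d(r, 1, 1, rng)

    def __call__(self, features) -> Tensor:
        skip1, skip2, skip3, bottleneck = features
        h = self.rrb0(skip3, self.up0(bottleneck))
        h = self.rrb1(skip2, self.up1(h))
        h = self.rrb2(skip1, self.up2(h))
        out = self.head(h)  # (N, 1, L), linear
        n, _, L = out.shape
        return out.reshape(n, L)


class NLDNNModel(Module):
    """Full network = predictor(generator(x)); output length = input length."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        drop_rng = np.random.default_rng([cfg.seed, 1])
        self.generator = Generator(cfg, rng, drop_rng)
        self.predictor = Predictor(cfg, rng)

    def __call__(self, x: Tensor) -> Tensor:
        n, c, L = x.shape
        if c != self.cfg.in_channels:
            raise ValueError(f"expected {self.cfg.in_channels} channels, got {c}")
        pp = self.cfg.pool_product
        pad = (-L) % pp
        if pad:
            x = concatenate([x, Tensor(np.zeros((n, c, pad)))], axis=2)
        out = self.predictor(self.generator(x))
        if pad:
            out = out[:, :L]
        if not np.all(np.isfinite(out.data)):
            raise FloatingPointError("non-finite values in model output")
        return out

    def predict(self, x: np.ndarray, batch_size: int = 128) -> np.ndarray:
        """Eval-mode forward over a numpy batch, without building a tape."""
        was_training = self.training
        self.eval()
        outs = []
        for i in range(0, len(x), batch_size):
            outs.append(self(Tensor(x[i : i + batch_size])).data)
        self.train(was_training)
        return np.concatenate(outs, axis=0)


class Discriminator(Module):
    """Species classifier on generator bottleneck feature maps.

    Three conv blocks (conv, ReLU, max-pool, dropout), a batch-norm layer,
    then two fully-connected layers with ReLU and a final sigmoid.  The
    feature map is adaptively pooled to a fixed width before the dense
    layers so any bottleneck length is accepted.
    """

    def __init__(self, in_channels: int, hidden: int = 32, dropout: float = 0.2,
                 fc_hidden: int = 64, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng([seed, 2])
        drop_rng = np.random.default_rng([seed, 3])
        chans = (in_channels, hidden, hidden, hidden)
        for i in range(3):
            setattr(self, f"conv{i}", Conv1d(chans[i], chans[i + 1], 3, rng))
        self.drop = Dropout(dropout, drop_rng)
        self.bn = BatchNorm1d(hidden)
        self.fc1 = Linear(hidden * 4, fc_hidden, rng)
        self.fc2 = Linear(fc_hidden, 1, rng)

    def __call__(self, feat: Tensor) -> Tensor:
        h = feat
        for i in range(3):
            h = getattr(self, f"conv{i}")(h).relu()
            if h.shape[2] >= 2:
                h = h.maxpool1d(2)
            h = self.drop(h)
        h = self.bn(h).avgpool_to(4)
        n = h.shape[0]
        h = h.reshape(n, -1)
        h = self.fc1(h).relu()
        p = self.fc2(h).sigmoid()
        return p.reshape(n)


class SeqLevelBaseline(Module):
    """Small conv net + global max pool + linear head: one scalar per window."""

    def __init__(self, in_channels: int = 4, channels: int = 32, kernel: int = 15,
                 seed: int = 0):
        super().__init__()
        rng = np.random.default_rng([seed, 4])
        self.conv = Conv1d(in_channels, channels, kernel, rng)
        self.fc = Linear(channels, 1, rng)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.conv(x).relu().max(axis=2)
        n = h.shape[0]
        return self.fc(h).reshape(n)

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        was_training = self.training
        self.eval()
        outs = [self(Tensor(x[i : i + batch_size])).data
                for i in range(0, len(x), batch_size)]
        self.train(was_training)
        return np.concatenate(outs, axis=0)


# ------------------------------------------------------------------ builders
def build_nldnn(config: ModelConfig) -> NLDNNModel:
    return NLDNNModel(config)


def build_discriminator(config: ModelConfig, **kwargs) -> Discriminator:
    return Discriminator(config.conv_channels[2], seed=config.seed, **kwargs)


def build_baseline(config: ModelConfig) -> SeqLevelBaseline:
    return SeqLevelBaseline(config.in_channels, seed=config.seed)


def split_generator_predictor(model: NLDNNModel) -> tuple[Generator, Predictor]:
    """The exact parameter partition used by adversarial adaptation."""
    return model.generator, model.predictor


# ---------------------------------------------------------------- checkpoint
def save_model(model: NLDNNModel, path: str, extra: dict | None = None):
    state = model.state_dict()
    meta = {"config": asdict(model.cfg), "extra": extra or {}}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **state)


def load_model(path: str) -> NLDNNModel:
    archive = np.load(path if str(path).endswith(".npz") else f"{path}.npz")
    meta = json.loads(bytes(archive["__meta__"]).decode())
    cfg_dict = meta["config"]
    for key in ("conv_channels", "conv_kernels", "pool_sizes", "sppm_scales"):
        cfg_dict[key] = tuple(cfg_dict[key])
    model = NLDNNModel(ModelConfig(**cfg_dict))
    model.load_state_dict({k: archive[k] for k in archive.files if k != "__meta__"})
    return model
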