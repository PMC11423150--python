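"""Cross-species adversarial adaptation (dual-path fine-tuning).

A source-species network is split into generator and predictor.  The frozen
source generator provides "real" feature maps; a target generator,
initialized from it, provides "fake" ones; a species discriminator is trained
to tell them apart while the target generator learns to fool it (inverted
label GAN objective).  The predictor is never touched: after adaptation,
target-species coverage is predicted by the adapted generator composed with
the frozen source predictor.

A transfer-learning baseline fine-tunes the generator through a small
species-classification head instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .evaluation import classification_metrics, window_max
from .model import Discriminator, Generator, NLDNNModel, Predictor, build_nldnn
from .nn import Adam, Linear, Module, Tensor, clip_grad_value

log = logging.getLogger(__name__)

__all__ = [
    "AdaptConfig",
    "AdaptState",
    "build_target_data",
    "discriminator_loss",
    "generator_loss",
    "adapt",
    "transfer_finetune",
]

_EPS = 1e-7


@dataclass
class AdaptConfig:
    betas: tuple[float, float] = (0.5, 0.9)
    weight_decay: float = 1e-5
    lr_generator: float = 1e-5
    lr_discriminator: float = 1e-4
    d_steps: int = 1400  # per round; desk-scale runs override (default desk value 100)
    g_steps: int = 1
    clip_value: float = 0.05  # 0.02 or 0.05
    binding_proportion: float = 0.1  # p in {0, 0.001, 0.1, 0.5, 1}
    batch_size: int = 500
    max_rounds: int = 10
    patience: int = 1  # rounds without val improvement before stopping
    min_rounds: int = 1  # burn-in before the stopping rule applies
    seed: int = 0

    def __post_init__(self):
        if self.lr_generator <= 0 or self.lr_discriminator <= 0:
            raise ValueError("learning rates must be positive")
        if not 0 <= self.binding_proportion <= 1:
            raise ValueError("binding_proportion must lie in [0, 1]")
        if self.clip_value <= 0:
            raise ValueError("clip_value must be positive")


@dataclass
class AdaptState:
    source_generator: Generator
    target_generator: Generator
    discriminator: Discriminator
    predictor: Predictor
    round: int = 0
    history: list = field(default_factory=list)


def build_target_data(
    target_windows: np.ndarray,
    target_binding_windows: np.ndarray,
    p: float,
    n_total: int,
    seed: int = 0,
) -> np.ndarray:
    """Target-species adaptation set: arbitrary windows plus binding windows.

    Draws (1-p)*n_total windows uniformly from the target training windows and
    p*n_total from the target binding (positive) windows.  p=0 uses arbitrary
    sequences only; p=1 uses binding sequences only.
    """
    if p > 0 and len(target_binding_windows) == 0:
        raise ValueError("binding_proportion > 0 but no target binding windows given")
    rng = np.random.default_rng([seed, 21])
    n_bind = int(round(p * n_total))
    n_arb = n_total - n_bind
    parts = []
    if n_arb:
        idx = rng.choice(len(target_windows), size=n_arb,
                         replace=len(target_windows) < n_arb)
        parts.append(target_windows[idx])
    if n_bind:
        idx = rng.choice(len(target_binding_windows), size=n_bind,
                         replace=len(target_binding_windows) < n_bind)
        parts.append(target_binding_windows[idx])
    return np.concatenate(parts, axis=0)


def _clamped_log(p: Tensor) -> Tensor:
    return p.clamp(_EPS, 1.0 - _EPS).log()


def discriminator_loss(d_source: Tensor, d_target: Tensor) -> Tensor:
    """-E[log D(G_s(X_s))] - E[log(1 - D(G_t(X_t)))], natural log."""
    one = Tensor(np.ones_like(d_target.data))
    return -(_clamped_log(d_source).mean()) - (_clamped_log(one - d_target).mean())


def generator_loss(d_target: Tensor) -> Tensor:
    """Inverted-label GAN loss: -E[log D(G_t(X_t))]."""
    return -(_clamped_log(d_target).mean())


def _features(generator: Generator, x: np.ndarray, batch: int = 64) -> np.ndarray:
    """Eval-mode bottleneck feature maps without autodiff bookkeeping."""
    was = generator.training
    generator.eval()
    outs = [generator(Tensor(x[i : i + batch]))[3].data for i in range(0, len(x), batch)]
    generator.train(was)
    return np.concatenate(outs, axis=0)


def _predict_compose(generator: Generator, predictor: Predictor, x: np.ndarray,
                     batch: int = 64) -> np.ndarray:
    gwas, pwas = generator.training, predictor.training
    generator.eval()
    predictor.eval()
    outs = [predictor(generator(Tensor(x[i : i + batch]))).data
            for i in range(0, len(x), batch)]
    generator.train(gwas)
    predictor.train(pwas)
    return np.concatenate(outs, axis=0)


def _val_prauc(generator, predictor, x_val_pos, x_val_neg) -> float:
    scores = np.concatenate([
        window_max(_predict_compose(generator, predictor, x_val_pos)),
        window_max(_predict_compose(generator, predictor, x_val_neg)),
    ])
    labels = np.concatenate([np.ones(len(x_val_pos)), np.zeros(len(x_val_neg))])
    prauc, _ = classification_metrics(scores, labels)
    return prauc


def adapt(
    source_model: NLDNNModel,
    x_source: np.ndarray,
    x_target: np.ndarray,
    config: AdaptConfig,
    x_val_pos: np.ndarray | None = None,
    x_val_neg: np.ndarray | None = None,
) -> AdaptState:
    """Adversarially fine-tune a target generator against a discriminator.

    Per round: `d_steps` discriminator updates on cached feature maps (both
    generators are frozen while the discriminator trains, so features are
    computed once per round), then `g_steps` generator updates with the
    discriminator frozen.  Gradients are value-clipped on every update.
    Stops when the target-validation PR-AUC (through the frozen predictor)
    fails to improve, or at max_rounds; returns the best-round generator.
    The source generator is never modified.
    """
    source_gen = source_model.generator
    predictor = source_model.predictor
    source_hash = source_gen.param_hash()

    target_model = build_nldnn(source_model.cfg)
    target_model.load_state_dict(source_model.state_dict())
    target_gen = target_model.generator

    disc = Discriminator(source_model.cfg.conv_channels[2], seed=config.seed)
    d_opt = Adam(disc.parameters(), lr=config.lr_discriminator, betas=config.betas,
                 weight_decay=config.weight_decay)
    g_opt = Adam(target_gen.parameters(), lr=config.lr_generator, betas=config.betas,
                 weight_decay=config.weight_decay)
    rng = np.random.default_rng([config.seed, 31])

    state = AdaptState(source_gen, target_gen, disc, predictor)
    has_val = x_val_pos is not None and len(x_val_pos) > 0

    # round 0 = unadapted baseline
    best_prauc = _val_prauc(target_gen, predictor, x_val_pos, x_val_neg) if has_val else -np.inf
    best_state = target_gen.state_dict()
    prev_prauc = best_prauc
    src_feat_all = _features(source_gen, x_source)

    for rnd in range(1, config.max_rounds + 1):
        tgt_feat_all = _features(target_gen, x_target)
        d_losses = []
        disc.train()
        for _ in range(config.d_steps):
            si = rng.choice(len(src_feat_all), size=min(config.batch_size, len(src_feat_all)), replace=False)
            ti = rng.choice(len(tgt_feat_all), size=min(config.batch_size, len(tgt_feat_all)), replace=False)
            d_src = disc(Tensor(src_feat_all[si]))
            d_tgt = disc(Tensor(tgt_feat_all[ti]))
            loss_d = discriminator_loss(d_src, d_tgt)
            disc.zero_grad()
            loss_d.backward()
            clip_grad_value(disc.parameters(), config.clip_value)
            d_opt.step()
            d_losses.append(float(loss_d.data))
        if np.mean(d_losses) < 1e-4:
            log.warning("discriminator collapse in round %d (loss %.2e)", rnd,
                        np.mean(d_losses))

        g_losses = []
        disc.eval()
        target_gen.train()
        for _ in range(config.g_steps):
            ti = rng.choice(len(x_target), size=min(config.batch_size, len(x_target)), replace=False)
            feat = target_gen(Tensor(x_target[ti]))[3]
            d_tgt = disc(feat)
            loss_g = generator_loss(d_tgt)
            target_gen.zero_grad()
            disc.zero_grad()
            loss_g.backward()
            clip_grad_value(target_gen.parameters(), config.clip_value)
            g_opt.step()
            g_losses.append(float(loss_g.data))
        target_gen.eval()

        record = {"round": rnd, "d_loss": float(np.mean(d_losses)),
                  "g_loss": float(np.mean(g_losses))}
        if has_val:
            prauc = _val_prauc(target_gen, predictor, x_val_pos, x_val_neg)
            record["val_prauc"] = prauc
            if prauc > best_prauc:
                best_prauc = prauc
                best_state = target_gen.state_dict()
            stop = prauc <= prev_prauc
            prev_prauc = prauc
        else:
            stop = False
        state.history.append(record)
        state.round = rnd
        if stop and rnd >= max(config.patience, config.min_rounds):
            break

    target_gen.load_state_dict(best_state)
    if source_gen.param_hash() != source_hash:
        raise RuntimeError("source generator was modified during adaptation")
    return state


class _TransferHead(Module):
    """Global average pool -> FC -> ReLU -> FC -> sigmoid species classifier."""

    def __init__(self, channels: int, hidden: int = 32, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng([seed, 41])
        self.fc1 = Linear(channels, hidden, rng)
        self.fc2 = Linear(hidden, 1, rng)

    def __call__(self, feat: Tensor) -> Tensor:
        h = feat.mean(axis=2)  # global average pool over positions
        h = self.fc1(h).relu()
        n = h.shape[0]
        return self.fc2(h).sigmoid().reshape(n)


def transfer_finetune(
    source_model: NLDNNModel,
    x_source: np.ndarray,
    x_target: np.ndarray,
    config: AdaptConfig,
    epochs: int = 3,
    lr_head: float = 1e-3,
) -> Generator:
    """Transfer-learning baseline: species classification through the generator.

    A classification head (global average pool, two FC layers, ReLU then
    sigmoid) sits on the generator bottleneck; source windows are labeled 1
    and target windows 0.  The generator trains at `lr_generator` and the
    head at `lr_head`; the head is discarded and the fine-tuned generator is
    returned for use with the frozen predictor.
    """
    model = build_nldnn(source_model.cfg)
    model.load_state_dict(source_model.state_dict())
    gen = model.generator
    head = _TransferHead(source_model.cfg.conv_channels[2], seed=config.seed)
    g_opt = Adam(gen.parameters(), lr=config.lr_generator, betas=config.betas,
                 weight_decay=config.weight_decay)
    h_opt = Adam(head.parameters(), lr=lr_head, betas=config.betas,
                 weight_decay=config.weight_decay)
    rng = np.random.default_rng([config.seed, 51])
    x_all = np.concatenate([x_source, x_target])
    y_all = np.concatenate([np.ones(len(x_source)), np.zeros(len(x_target))])
    gen.train()
    for _ in range(epochs):
        order = rng.permutation(len(x_all))
        for i in range(0, len(order), config.batch_size):
            idx = order[i : i + config.batch_size]
            p = head(gen(Tensor(x_all[idx]))[3])
            t = Tensor(y_all[idx])
            one = Tensor(np.ones_like(t.data))
            loss = -((t * _clamped_log(p)).mean() + ((one - t) * _clamped_log(one - p)).mean())
            gen.zero_grad()
            head.zero_grad()
            loss.backward()
            clip_grad_value(gen.parameters() + head.parameters(), config.clip_value)
            if config.lr_generator > 0:
                g_opt.step()
            h_opt.step()
    gen.eval()
    return gen
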