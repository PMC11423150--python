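"""Within-species supervised training.

Each epoch uses every positive window once plus `neg_ratio` times as many
negatives drawn *without replacement* from a rolling shuffled pool, so the
whole negative set is eventually cycled.  The loss is per-nucleotide MSE with
an L2 weight penalty (a Poisson alternative is available for count-like
targets).  Optimization is ADAM with the learning rate decayed by a fixed
factor every ten epochs; a warm-up stage trains several fresh initializations
briefly and keeps the one with the best validation PR-AUC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .evaluation import classification_metrics, fit_metrics, window_max
from .model import ModelConfig, build_nldnn
from .nn import Adam, Tensor

log = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "NegativeSampler",
    "nldnn_loss",
    "epoch_batches",
    "learning_rate",
    "train",
    "warmup_select",
]


@dataclass
class TrainConfig:
    batch_size: int = 500
    epochs: int = 60
    lr0: float = 1e-3
    lr_decay: float = 0.9  # applied every lr_decay_every epochs
    lr_decay_every: int = 10
    neg_ratio: int = 3
    alpha: float = 1e-6  # L2 weight penalty
    warmup_inits: int = 3
    warmup_epochs: int = 2
    seed: int = 0
    loss: str = "mse"  # "mse" | "poisson"
    rc_augment: bool = False  # add reverse-complement copies of each batch

    def __post_init__(self):
        if min(self.batch_size, self.epochs, self.neg_ratio) < 1:
            raise ValueError("batch_size, epochs and neg_ratio must be positive")
        if self.neg_ratio < 1:
            raise ValueError("neg_ratio must be >= 1")


def learning_rate(config: TrainConfig, epoch: int) -> float:
    """lr(e) = lr0 * decay**floor(e / every)."""
    return config.lr0 * config.lr_decay ** (epoch // config.lr_decay_every)


class NegativeSampler:
    """Without-replacement sampling from a rolling shuffled negative pool."""

    def __init__(self, n_pool: int, rng: np.random.Generator):
        if n_pool < 1:
            raise ValueError("negative pool is empty")
        self.n_pool = n_pool
        self.rng = rng
        self._perm = rng.permutation(n_pool)
        self._cursor = 0
        self._warned = False

    def draw(self, n: int) -> np.ndarray:
        if n > self.n_pool and not self._warned:
            log.warning(
                "epoch demands %d negatives but pool has %d; reshuffling mid-epoch",
                n, self.n_pool,
            )
            self._warned = True
        out = []
        remaining = n
        while remaining > 0:
            take = min(remaining, self.n_pool - self._cursor)
            out.append(self._perm[self._cursor : self._cursor + take])
            self._cursor += take
            remaining -= take
            if self._cursor >= self.n_pool:
                self._perm = self.rng.permutation(self.n_pool)
                self._cursor = 0
        return np.concatenate(out)


def nldnn_loss(
    pred: Tensor, true: np.ndarray, model=None, alpha: float = 0.0,
    loss: str = "mse",
) -> Tensor:
    """Per-nucleotide regression loss plus L2 weight penalty.

    mse: (1/(N*L)) * sum (z - zhat)^2 + alpha * ||w||_2^2 over all model
    weight tensors (biases unpenalized).  poisson: mean per-base Poisson
    negative log-likelihood of exp-linked predictions, same penalty.
    """
    true = np.asarray(true)
    if pred.shape != true.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape}, true {true.shape}")
    t = Tensor(true)
    if loss == "mse":
        out = ((pred - t) ** 2).mean()
    elif loss == "poisson":
        out = (pred.exp() - t * pred).mean()
    else:
        raise ValueError(f"unknown loss {loss!r}")
    if alpha and model is not None:
        penalty = None
        for w in model.weights():
            term = (w**2).sum()
            penalty = term if penalty is None else penalty + term
        out = out + alpha * penalty
    return out


def epoch_batches(
    n_pos: int,
    sampler: NegativeSampler,
    config: TrainConfig,
    epoch: int,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Shuffled minibatches of (positive indices, negative indices) per epoch.

    Every epoch contains all positives once plus neg_ratio * n_pos negatives
    from the rolling pool.  Deterministic given config.seed and epoch.
    """
    rng = np.random.default_rng([config.seed, 7, epoch])
    neg = sampler.draw(config.neg_ratio * n_pos)
    # interleave: entry >= 0 is a positive index, entry < 0 encodes negative
    merged = np.concatenate([np.arange(n_pos), -neg - 1])
    rng.shuffle(merged)
    batches = []
    for i in range(0, len(merged), config.batch_size):
        chunk = merged[i : i + config.batch_size]
        batches.append((chunk[chunk >= 0], -chunk[chunk < 0] - 1))
    return batches


def rc_windows(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Reverse-complement encoded windows and mirror their targets.

    Complementing swaps the A/T and C/G one-hot rows; any extra channels
    (accessibility) are only position-reversed.
    """
    xr = x[:, :, ::-1].copy()
    xr[:, :4] = xr[:, 3::-1].copy()
    return xr, y[:, ::-1].copy()


def _validate(model, x_pos, y_pos, x_neg) -> tuple[float, float]:
    pred_pos = model.predict(x_pos)
    pred_neg = model.predict(x_neg)
    scores = np.concatenate([window_max(pred_pos), window_max(pred_neg)])
    labels = np.concatenate([np.ones(len(x_pos)), np.zeros(len(x_neg))])
    prauc, _ = classification_metrics(scores, labels)
    try:
        pearson = fit_metrics(pred_pos, y_pos, scope="positives_max")
    except ValueError:
        pearson = float("nan")
    return prauc, pearson


def train(
    model,
    x_pos: np.ndarray,
    y_pos: np.ndarray,
    x_neg: np.ndarray,
    y_neg: np.ndarray,
    config: TrainConfig,
    x_val_pos: np.ndarray | None = None,
    y_val_pos: np.ndarray | None = None,
    x_val_neg: np.ndarray | None = None,
):
    """Train in place; returns (model, history).

    History records per-epoch train loss, learning rate, and validation
    PR-AUC / Pearson when a validation split is given; the best-validation
    checkpoint is restored before returning.
    """
    has_val = x_val_pos is not None and len(x_val_pos) > 0
    sampler = NegativeSampler(len(x_neg), np.random.default_rng([config.seed, 11]))
    opt = Adam(model.parameters(), lr=learning_rate(config, 0))
    history = []
    best_prauc, best_state = -np.inf, None
    model.train()
    for epoch in range(config.epochs):
        opt.lr = learning_rate(config, epoch)
        losses = []
        for pos_idx, neg_idx in epoch_batches(len(x_pos), sampler, config, epoch):
            xb = np.concatenate([x_pos[pos_idx], x_neg[neg_idx]])
            yb = np.concatenate([y_pos[pos_idx], y_neg[neg_idx]])
            if config.rc_augment:
                xr, yr = rc_windows(xb, yb)
                xb = np.concatenate([xb, xr])
                yb = np.concatenate([yb, yr])
            pred = model(Tensor(xb))
            loss = nldnn_loss(pred, yb, model, config.alpha, config.loss)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}; lr={opt.lr}"
                )
            model.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        record = {"epoch": epoch, "lr": opt.lr, "train_loss": float(np.mean(losses))}
        if has_val:
            prauc, pearson = _validate(model, x_val_pos, y_val_pos, x_val_neg)
            record.update(val_prauc=prauc, val_pearson=pearson)
            # retain on classification + fitting jointly, the two metrics the
            # method is scored on; classification keeps the larger weight
            score = prauc + 0.5 * (pearson if np.isfinite(pearson) else 0.0)
            if score > best_prauc:
                best_prauc, best_state = score, model.state_dict()
        history.append(record)
        model.train()
    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    return model, history


def warmup_select(
    base_config: ModelConfig,
    train_config: TrainConfig,
    x_pos, y_pos, x_neg, y_neg,
    x_val_pos, y_val_pos, x_val_neg,
):
    """Train several fresh initializations briefly; keep the best one.

    Runs `warmup_inits` models (seeds base, base+1, ...) for `warmup_epochs`
    epochs each and returns the one with the highest validation PR-AUC
    (ties resolved toward the lower seed), untrained beyond warm-up.
    """
    from dataclasses import replace

    best = None
    for k in range(train_config.warmup_inits):
        cfg = replace(base_config, seed=base_config.seed + k)
        model = build_nldnn(cfg)
        tc = replace(train_config, epochs=train_config.warmup_epochs,
                     seed=train_config.seed + k)
        model, _ = train(model, x_pos, y_pos, x_neg, y_neg, tc,
                         x_val_pos, y_val_pos, x_val_neg)
        prauc, _ = _validate(model, x_val_pos, y_val_pos, x_val_neg)
        if best is None or prauc > best[0]:
            best = (prauc, k, model)
    return best[2], best[0]
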