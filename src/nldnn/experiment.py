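"""Config-driven end-to-end experiments on synthetic two-species worlds.

One master seed fans out to named sub-seeds (world generation, negative
matching, model initialization, batch sampling, adaptation), so a run is
reproducible bit-for-bit from its config.  Modes build on each other:

- ``within``: train on the source species, evaluate on its held-out test
  chromosome.
- ``cross``: additionally evaluate the source model on the target species.
- ``cross_adapted``: additionally fine-tune the generator adversarially
  and evaluate (target generator + frozen source predictor).
- ``cross_transfer``: additionally run the transfer-learning baseline.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from .adaptation import AdaptConfig, adapt, build_target_data, transfer_finetune
from .evaluation import EvalReport, evaluate_model
from .model import ModelConfig, build_nldnn, save_model
from .synthetic import SyntheticSpec, make_genome
from .training import TrainConfig, train, warmup_select
from .windows import SplitSpec, build_windows, split_by_chromosome, windows_to_arrays

__all__ = [
    "ExperimentConfig",
    "SpeciesData",
    "desk_model_config",
    "desk_train_config",
    "desk_adapt_config",
    "prepare_species",
    "ComposedModel",
    "run_experiment",
]


# ----------------------------------------------------- desk-scale conditions
def desk_model_config(seed: int = 0, in_channels: int = 4) -> ModelConfig:
    """Reduced layer widths sized for minutes-scale CPU runs."""
    return ModelConfig(
        in_channels=in_channels,
        conv_channels=(24, 24, 32),
        conv_kernels=(15, 5, 3),
        pool_sizes=(5, 2, 2),
        dropout=0.2,
        gru_hidden=12,
        rrb_channels=16,
        sppm_scales=(1, 2, 4),
        seed=seed,
    )


def desk_train_config(seed: int = 0, epochs: int = 16) -> TrainConfig:
    return TrainConfig(
        batch_size=32,
        epochs=epochs,
        lr0=3e-3,
        lr_decay=0.75,
        lr_decay_every=6,
        alpha=1e-5,
        warmup_inits=1,
        warmup_epochs=2,
        seed=seed,
        rc_augment=True,
    )


def desk_adapt_config(seed: int = 0, p: float = 0.1) -> AdaptConfig:
    return AdaptConfig(
        d_steps=100,
        g_steps=1,
        lr_generator=2e-4,
        lr_discriminator=5e-4,
        batch_size=64,
        max_rounds=8,
        min_rounds=6,  # one desk round is a single generator update
        binding_proportion=p,
        seed=seed,
    )


@dataclass
class SpeciesData:
    """Encoded window arrays for one species, split train/val/test."""

    genome: object
    truth: object
    x_train_pos: np.ndarray
    y_train_pos: np.ndarray
    x_train_neg: np.ndarray
    y_train_neg: np.ndarray
    x_val_pos: np.ndarray
    y_val_pos: np.ndarray
    x_val_neg: np.ndarray
    x_test_pos: np.ndarray
    y_test_pos: np.ndarray
    x_test_neg: np.ndarray
    y_test_neg: np.ndarray


def prepare_species(
    spec: SyntheticSpec,
    species: str,
    seed: int,
    val_fraction: float = 0.15,
    train_chroms: tuple[str, ...] = ("chr1",),
    test_chroms: tuple[str, ...] = ("chr2",),
    with_accessibility: bool = False,
) -> SpeciesData:
    """Generate one species and build its encoded window splits.

    The test chromosomes are held out entirely; validation windows are a
    random fraction of the training-chromosome windows (at this desk scale a
    third chromosome would leave too few peaks per split).
    """
    genome, truth = make_genome(spec, species)
    pos, neg = build_windows(
        genome, truth.peaks, truth.coverage,
        accessibility=truth.accessibility if with_accessibility else None,
        seed=seed,
    )
    split = SplitSpec(list(train_chroms), [], list(test_chroms))
    tr_pos, _, te_pos = split_by_chromosome(pos, split)
    tr_neg, _, te_neg = split_by_chromosome(neg, split)
    rng = np.random.default_rng([seed, 61])
    n_vp = max(4, int(val_fraction * len(tr_pos)))
    n_vn = max(12, int(val_fraction * len(tr_neg)))
    vp = set(rng.choice(len(tr_pos), n_vp, replace=False).tolist())
    vn = set(rng.choice(len(tr_neg), n_vn, replace=False).tolist())
    val_pos = [tr_pos[i] for i in sorted(vp)]
    val_neg = [tr_neg[i] for i in sorted(vn)]
    tr_pos = [w for i, w in enumerate(tr_pos) if i not in vp]
    tr_neg = [w for i, w in enumerate(tr_neg) if i not in vn]
    acc = with_accessibility
    xp, yp = windows_to_arrays(tr_pos, acc)
    xn, yn = windows_to_arrays(tr_neg, acc)
    xvp, yvp = windows_to_arrays(val_pos, acc)
    xvn, _ = windows_to_arrays(val_neg, acc)
    xtp, ytp = windows_to_arrays(te_pos, acc)
    xtn, ytn = windows_to_arrays(te_neg, acc)
    return SpeciesData(genome, truth, xp, yp, xn, yn, xvp, yvp, xvn,
                       xtp, ytp, xtn, ytn)


class ComposedModel:
    """(generator, predictor) pair exposing the same predict() surface."""

    def __init__(self, generator, predictor):
        self.generator = generator
        self.predictor = predictor

    def predict(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        from .nn import Tensor

        gwas, pwas = self.generator.training, self.predictor.training
        self.generator.eval()
        self.predictor.eval()
        outs = [self.predictor(self.generator(Tensor(x[i : i + batch_size]))).data
                for i in range(0, len(x), batch_size)]
        self.generator.train(gwas)
        self.predictor.train(pwas)
        return np.concatenate(outs, axis=0)


@dataclass
class ExperimentConfig:
    mode: str = "within"  # within | cross | cross_adapted | cross_transfer
    spec: SyntheticSpec = field(default_factory=SyntheticSpec)
    model: ModelConfig | None = None
    train: TrainConfig | None = None
    adapt: AdaptConfig | None = None
    source_species: str = "A"
    target_species: str = "B"
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self):
        if self.mode not in ("within", "cross", "cross_adapted", "cross_transfer"):
            raise ValueError(f"unknown mode {self.mode!r}")


def _train_source(cfg: ExperimentConfig, src: SpeciesData):
    model_cfg = cfg.model or desk_model_config(cfg.seed)
    train_cfg = cfg.train or desk_train_config(cfg.seed)
    if train_cfg.warmup_inits > 1:
        model, _ = warmup_select(
            model_cfg, train_cfg,
            src.x_train_pos, src.y_train_pos, src.x_train_neg, src.y_train_neg,
            src.x_val_pos, src.y_val_pos, src.x_val_neg,
        )
    else:
        model = build_nldnn(model_cfg)
    model, history = train(
        model, src.x_train_pos, src.y_train_pos, src.x_train_neg, src.y_train_neg,
        train_cfg, src.x_val_pos, src.y_val_pos, src.x_val_neg,
    )
    return model, history


def run_experiment(cfg: ExperimentConfig) -> dict:
    """Run the configured pipeline; returns a JSON-serializable report bundle."""
    spec = replace(cfg.spec, seed=cfg.seed) if cfg.spec.seed != cfg.seed else cfg.spec
    src = prepare_species(spec, cfg.source_species, cfg.seed)
    model, history = _train_source(cfg, src)
    reports: dict = {"seed": cfg.seed, "mode": cfg.mode, "history": history}
    reports["within"] = evaluate_model(
        model, src.x_test_pos, src.y_test_pos, src.x_test_neg, src.y_test_neg
    ).to_dict()

    tgt = None
    if cfg.mode in ("cross", "cross_adapted", "cross_transfer"):
        tgt = prepare_species(spec, cfg.target_species, cfg.seed)
        reports["cross"] = evaluate_model(
            model, tgt.x_test_pos, tgt.y_test_pos, tgt.x_test_neg, tgt.y_test_neg
        ).to_dict()

    if cfg.mode in ("cross_adapted", "cross_transfer"):
        adapt_cfg = cfg.adapt or desk_adapt_config(cfg.seed)
        x_source = src.x_train_pos
        x_target_all = np.concatenate([tgt.x_train_pos, tgt.x_train_neg])
        x_target = build_target_data(
            x_target_all, tgt.x_train_pos, adapt_cfg.binding_proportion,
            n_total=len(x_source), seed=cfg.seed,
        )
        if cfg.mode == "cross_adapted":
            state = adapt(model, x_source, x_target, adapt_cfg,
                          tgt.x_val_pos, tgt.x_val_neg)
            composed = ComposedModel(state.target_generator, state.predictor)
            reports["cross_adapted"] = evaluate_model(
                composed, tgt.x_test_pos, tgt.y_test_pos,
                tgt.x_test_neg, tgt.y_test_neg,
            ).to_dict()
            reports["adapt_history"] = state.history
        else:
            gen = transfer_finetune(model, x_source, x_target, adapt_cfg)
            composed = ComposedModel(gen, model.predictor)
            reports["cross_transfer"] = evaluate_model(
                composed, tgt.x_test_pos, tgt.y_test_pos,
                tgt.x_test_neg, tgt.y_test_neg,
            ).to_dict()

    if cfg.out_dir:
        os.makedirs(cfg.out_dir, exist_ok=True)
        snapshot = {
            "seed": cfg.seed,
            "mode": cfg.mode,
            "model": asdict(cfg.model or desk_model_config(cfg.seed)),
            "train": asdict(cfg.train or desk_train_config(cfg.seed)),
        }
        if cfg.mode in ("cross_adapted", "cross_transfer"):
            snapshot["adapt"] = asdict(cfg.adapt or desk_adapt_config(cfg.seed))
        with open(os.path.join(cfg.out_dir, "config.json"), "w") as fh:
            json.dump(snapshot, fh, indent=2, default=str)
        with open(os.path.join(cfg.out_dir, "reports.json"), "w") as fh:
            json.dump(reports, fh, indent=2)
        save_model(model, os.path.join(cfg.out_dir, "source_model.npz"))
    return reports
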