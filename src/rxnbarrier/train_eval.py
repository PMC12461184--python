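"""Training loop, MAE/RMSE evaluation, and permutation feature importance.

Optimisation follows the fixed protocol used across all reported runs:
AdamW (beta1 = 0.9, beta2 = 0.999, eps = 1e-8) with cosine annealing after
a 10-step linear warmup, batches of 50, mean-squared-error loss on
z-scored targets.  Model selection keeps the checkpoint with the lowest
validation MAE.  Warmup/annealing "steps" are scheduler invocations, one
per epoch.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from .data import ReactionDataset
from .dmpnn import FeatureWidths, ModelConfig, ModelState, forward_batch, init_params, make_batch
from .extra_features import permute_feature_column

__all__ = [
    "TrainConfig",
    "Metrics",
    "ImportanceReport",
    "TrainingError",
    "train",
    "evaluate",
    "predict_dataset",
    "permutation_importance",
]

logger = logging.getLogger("rxnbarrier.train")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(name)s %(levelname)s %(message)s"))
    logger.addHandler(_h)


class TrainingError(RuntimeError):
    pass


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    weight_decay: float = 0.0
    warmup_steps: int = 10
    lr_floor_ratio: float = 0.01
    batch_size: int = 50
    epochs: int = 100
    seed: int = 0
    grad_clip: float | None = None

    def __post_init__(self):
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size >= 1 and epochs >= 1 required")


@dataclass
class Metrics:
    mae: float
    rmse: float
    n: int

    def as_dict(self) -> dict:
        return {"mae": self.mae, "rmse": self.rmse, "n": self.n}


@dataclass
class ImportanceReport:
    delta_mae: dict[str, float]
    baseline_mae: float
    repeats: int

    @property
    def ranking(self) -> list[str]:
        return sorted(self.delta_mae, key=lambda c: -self.delta_mae[c])

    def as_dict(self) -> dict:
        return {
            "baseline_mae": self.baseline_mae,
            "repeats": self.repeats,
            "delta_mae": self.delta_mae,
            "ranking": self.ranking,
        }


def _lr_at(step: int, total: int, config: TrainConfig) -> float:
    """Linear warmup over the first `warmup_steps` scheduler ticks, then
    cosine decay to a small floor."""
    base = config.learning_rate
    if step < config.warmup_steps:
        return base * (step + 1) / config.warmup_steps
    span = max(total - config.warmup_steps, 1)
    progress = min((step - config.warmup_steps) / span, 1.0)
    floor = base * config.lr_floor_ratio
    return floor + 0.5 * (base - floor) * (1.0 + np.cos(np.pi * progress))


class _AdamW:
    def __init__(self, params: dict[str, np.ndarray], config: TrainConfig):
        self.config = config
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray], lr: float):
        c = self.config
        self.t += 1
        for k, g in grads.items():
            if c.grad_clip is not None:
                norm = np.linalg.norm(g)
                if norm > c.grad_clip:
                    g = g * (c.grad_clip / norm)
            self.m[k] = c.beta1 * self.m[k] + (1 - c.beta1) * g
            self.v[k] = c.beta2 * self.v[k] + (1 - c.beta2) * g * g
            mhat = self.m[k] / (1 - c.beta1**self.t)
            vhat = self.v[k] / (1 - c.beta2**self.t)
            params[k] -= lr * (mhat / (np.sqrt(vhat) + c.eps) + c.weight_decay * params[k])


def _scaled_targets(dataset: ReactionDataset, mean: float, std: float) -> np.ndarray:
    return (dataset.targets() - mean) / std


def train(
    train_set: ReactionDataset,
    val_set: ReactionDataset,
    model_config: ModelConfig,
    train_config: TrainConfig,
) -> tuple[ModelState, list[dict]]:
    """Fit the model; return the lowest-validation-MAE state and history."""
    if len(train_set) == 0 or len(val_set) == 0:
        raise TrainingError("train and validation partitions must be non-empty")

    y = train_set.targets()
    if np.isnan(y).any():
        raise TrainingError("training set contains records without targets")
    mean, std = float(y.mean()), float(y.std())
    if std <= 0:
        std = 1.0

    rec0 = train_set.records[0]
    widths = FeatureWidths(
        atom=rec0.cgr.atom_features.shape[1],
        bond=rec0.cgr.bond_features.shape[1],
        atom_extra=train_set.atom_extra_width if model_config.extra_route != "none" else 0,
        mol_extra=train_set.mol_extra_width,
    )
    rng = np.random.default_rng(train_config.seed)
    state = init_params(model_config, widths, seed=int(rng.integers(2**31 - 1)))
    state.target_mean, state.target_std = mean, std
    opt = _AdamW(state.params, train_config)
    dropout_rng = np.random.default_rng(int(rng.integers(2**31 - 1)))

    n = len(train_set)
    history: list[dict] = []
    best_state = state.copy()
    best_val = np.inf
    for epoch in range(train_config.epochs):
        lr = _lr_at(epoch, train_config.epochs, train_config)
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, train_config.batch_size):
            idx = order[start : start + train_config.batch_size]
            batch = make_batch([train_set.records[i] for i in idx])
            batch_y = (batch.targets - mean) / std
            params = {k: Tensor(v, requires_grad=True) for k, v in state.params.items()}
            pred = forward_batch(state, batch, training=True, rng=dropout_rng, params=params)
            resid = pred - Tensor(batch_y)
            loss = resid.square().mean()
            if not np.isfinite(loss.data):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            loss.backward()
            grads = {k: t.grad for k, t in params.items() if t.grad is not None}
            opt.step(state.params, grads, lr)
            epoch_loss += float(loss.data) * len(idx)
        epoch_loss /= n

        val_metrics = evaluate(state, val_set)
        history.append(
            {
                "epoch": epoch,
                "lr": lr,
                "train_loss": epoch_loss,
                "val_mae": val_metrics.mae,
                "val_rmse": val_metrics.rmse,
            }
        )
        logger.info(
            "epoch %d lr %.2e train_loss %.4f val_mae %.4f", epoch, lr, epoch_loss, val_metrics.mae
        )
        if val_metrics.mae < best_val:
            best_val = val_metrics.mae
            best_state = state.copy()
    return best_state, history


def predict_dataset(state: ModelState, dataset: ReactionDataset, batch_size: int = 200) -> np.ndarray:
    """Predictions in kcal/mol, record order preserved."""
    out = []
    for start in range(0, len(dataset), batch_size):
        batch = make_batch(dataset.records[start : start + batch_size])
        out.append(forward_batch(state, batch).data * state.target_std + state.target_mean)
    return np.concatenate(out)


def evaluate(state: ModelState, dataset: ReactionDataset) -> Metrics:
    """MAE and RMSE in kcal/mol over a dataset."""
    if len(dataset) == 0:
        raise ValueError("cannot evaluate on an empty dataset")
    pred = predict_dataset(state, dataset)
    err = pred - dataset.targets()
    return Metrics(
        mae=float(np.abs(err).mean()),
        rmse=float(np.sqrt((err**2).mean())),
        n=len(dataset),
    )


def permutation_importance(
    state: ModelState,
    dataset: ReactionDataset,
    seed: int = 0,
    repeats: int = 5,
    columns: list[str] | None = None,
) -> ImportanceReport:
    """Column-wise permutation importance at prediction time.

    Each extra-feature column is shuffled across the dataset (repeats
    times with derived seeds) and the mean increase in MAE over the
    unpermuted baseline is reported; negative values indicate a column
    whose scrambling helps.
    """
    baseline = evaluate(state, dataset).mae
    columns = columns or (dataset.atom_extra_columns + dataset.mol_extra_columns)
    rng = np.random.default_rng(seed)
    deltas: dict[str, float] = {}
    for col in columns:
        accum = 0.0
        for _ in range(repeats):
            shuffled = permute_feature_column(dataset, col, int(rng.integers(2**31 - 1)))
            accum += evaluate(state, shuffled).mae - baseline
        deltas[col] = accum / repeats
    return ImportanceReport(delta_mae=deltas, baseline_mae=baseline, repeats=repeats)
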