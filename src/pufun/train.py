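"""Training loop and run orchestration.

A run trains one residual MLP for one ontology namespace with minibatch
Adam under a triangular cyclic learning-rate schedule, minimizing the
selected PU risk variant.  Everything is deterministic given (config, seed):
parameter initialization, batch shuffling and dropout masks all derive from
the run seed, so repeating a run reproduces the loss trace and checkpoint
bit for bit.
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import metrics as metrics_mod
from .datasets import LabelMatrix, read_split_tsv
from .nn import Adam, CyclicLR, EmbeddingMatrix, ModelSpec, ResidualMLP, ScoreMatrix
from .ontology import PriorVector
from .risk import RiskConfig, pugo_loss


@dataclass
class TrainConfig:
    """Hyperparameters of one training run.

    The default search ranges for random hyperparameter search are batch
    size 30..200, margin factor gamma in [0.01, 0.1], maximum learning rate
    in [5e-6, 1e-2], minimum-learning-rate factor in [1e-4, 1e-1] and base
    prior pi_o in [1e-4, 1e-3]; the defaults below sit inside those ranges.
    """

    variant: str = "pu_go"
    batch_size: int = 128
    max_lr: float = 1e-3
    min_lr_factor: float = 0.1
    gamma: float = 0.05
    pi_o: float = 1e-3
    epochs: int = 40
    patience: int = 10  # 0 disables early stopping
    cycle_epochs: int = 4
    hidden_dim: int = 2048
    dropout: float = 0.1
    seed: int = 0
    restore_best: bool = True  # return the lowest-validation-loss checkpoint

    def __post_init__(self) -> None:
        if self.batch_size < 2:
            raise ValueError("batch size must be >= 2")
        if not 0 < self.min_lr_factor < 1:
            raise ValueError("min_lr_factor must lie in (0, 1)")

    @property
    def min_lr(self) -> float:
        return self.max_lr * self.min_lr_factor


@dataclass
class FitResult:
    """Trained model plus its per-epoch history."""

    model: ResidualMLP
    history: list[dict]
    best_epoch: int
    config: TrainConfig

    @property
    def train_losses(self) -> list[float]:
        return [h["train_loss"] for h in self.history]

    @property
    def valid_losses(self) -> list[float]:
        return [h["valid_loss"] for h in self.history]


def fit(
    X_train: np.ndarray,
    Y_train: np.ndarray,
    X_valid: np.ndarray,
    Y_valid: np.ndarray,
    priors: PriorVector | None,
    config: TrainConfig,
) -> FitResult:
    """Train the classifier on (embeddings, PU labels).

    The best checkpoint is the epoch with the lowest validation loss;
    training stops early after ``patience`` epochs without improvement.
    Batches in which no class has both positives and unlabeled rows are
    skipped (counted in the epoch record).
    """
    X_train = np.asarray(X_train, dtype=float)
    X_valid = np.asarray(X_valid, dtype=float)
    if X_valid.shape[0] == 0:
        raise ValueError("validation split is empty")
    n, d = X_train.shape
    k = Y_train.shape[1]
    risk_cfg = RiskConfig(
        variant=config.variant, pi_o=config.pi_o, gamma=config.gamma
    )
    spec = ModelSpec(
        output_dim=k, input_dim=d, hidden_dim=config.hidden_dim,
        dropout=config.dropout, seed=config.seed,
    )
    model = ResidualMLP(spec)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xB0B]))
    opt = Adam(model.params, lr=config.max_lr)
    steps_per_epoch = max(1, n // config.batch_size)
    sched = CyclicLR(config.min_lr, config.max_lr,
                     step_size_up=max(1, config.cycle_epochs * steps_per_epoch))

    best_loss = np.inf
    best_state: tuple | None = None
    best_epoch = -1
    history: list[dict] = []
    step = 0
    stale = 0
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        batch_losses = []
        skipped_batches = 0
        lr_seen = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            if idx.size < 2:
                continue  # batch statistics need at least two rows
            lr = sched.lr(step)
            lr_seen.append(lr)
            logits, cache = model.forward(X_train[idx], mode="train", rng=rng)
            try:
                report, dlogits = pugo_loss(
                    logits, Y_train[idx], priors, risk_cfg, with_grad=True
                )
            except ValueError:
                skipped_batches += 1
                step += 1
                continue
            if not np.isfinite(report.total):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, step {step}: "
                    f"{report!r}"
                )
            grads = model.backward(cache, dlogits)
            opt.step(grads, lr=lr)
            batch_losses.append(report.total)
            step += 1

        valid_logits = model.predict_logits(X_valid)
        valid_report = pugo_loss(valid_logits, Y_valid, priors, risk_cfg)
        valid_loss = valid_report.total
        record = {
            "epoch": epoch,
            "train_loss": float(np.mean(batch_losses)) if batch_losses else np.nan,
            "valid_loss": float(valid_loss),
            "lr_min": float(min(lr_seen)) if lr_seen else None,
            "lr_max": float(max(lr_seen)) if lr_seen else None,
            "skipped_batches": skipped_batches,
        }
        history.append(record)
        if valid_loss < best_loss - 1e-12:
            best_loss = valid_loss
            best_epoch = epoch
            best_state = (
                {k_: v.copy() for k_, v in model.params.items()},
                {k_: v.copy() for k_, v in model.running.items()},
            )
            stale = 0
        else:
            stale += 1
            if config.patience and stale >= config.patience:
                break

    if config.restore_best and best_state is not None:
        model.params, model.running = best_state
    return FitResult(model=model, history=history, best_epoch=best_epoch,
                     config=config)


def predict(
    model: ResidualMLP, emb: EmbeddingMatrix, index
) -> ScoreMatrix:
    """Sigmoid scores for every protein in an embedding matrix."""
    return ScoreMatrix(
        list(emb.proteins), index, model.predict_scores(emb.values),
        kind="probability",
    )


def propagate_scores(dag, scores: ScoreMatrix) -> ScoreMatrix:
    """Optional hierarchy-consistency step: cumulative max over ancestors.

    Off by default in every pipeline; offered for users who want predicted
    scores that never decrease toward the root.
    """
    values = scores.values.copy()
    index = scores.index
    for j, term in enumerate(index.terms):
        cols = [index.position[a] for a in dag.ancestors(term) if a in index.position]
        if cols:
            np.maximum.at(values.T, cols, values[:, j])
    return ScoreMatrix(scores.proteins, index, values, kind=scores.kind)


def evaluate_predictions(
    pred_path,
    truth: LabelMatrix,
    ic=None,
) -> metrics_mod.MetricsReport:
    """Evaluate a CAFA-style prediction TSV against a propagated truth matrix."""
    scores = metrics_mod.read_cafa_tsv(pred_path, truth.index, truth.proteins)
    ev = metrics_mod.EvaluationInput(predictions=scores, truth=truth, ic=ic)
    return metrics_mod.evaluate(ev)


def aggregate_runs(runs: list, mode: str = "metrics"):
    """Aggregate multiple seeded runs.

    ``mode='metrics'``: arithmetic mean and standard deviation of each
    metric across :class:`~pufun.metrics.MetricsReport` objects.
    ``mode='scores'``: average the score matrices (same proteins and class
    index required) into one matrix for a single evaluation.
    """
    if not runs:
        raise ValueError("need at least one run")
    if mode == "metrics":
        keys = ("fmax", "smin", "aupr", "auc")
        out = {}
        for key in keys:
            vals = [getattr(r, key) for r in runs]
            if any(v is None for v in vals):
                continue
            arr = np.array(vals, dtype=float)
            out[key] = {"mean": float(arr.mean()), "sd": float(arr.std(ddof=0))}
        return out
    if mode == "scores":
        first = runs[0]
        for r in runs[1:]:
            if r.proteins != first.proteins or r.index.terms != first.index.terms:
                raise ValueError("score matrices are not aligned")
        mean = np.mean([r.values for r in runs], axis=0)
        return ScoreMatrix(first.proteins, first.index, mean, kind=first.kind)
    raise ValueError(f"unknown aggregation mode {mode!r}")


# ---------------------------------------------------------------------------
# Random hyperparameter search (config-driven stand-in for a full tuner)

SEARCH_RANGES = {
    "batch_size": (30, 200),
    "gamma": (0.01, 0.1),
    "max_lr": (5e-6, 1e-2),
    "min_lr_factor": (1e-4, 1e-1),
    "pi_o": (1e-4, 1e-3),
}


def sample_config(rng: np.random.Generator, base: TrainConfig | None = None) -> TrainConfig:
    """Draw one hyperparameter configuration from the default search ranges
    (log-uniform for the continuous ones)."""
    base = base or TrainConfig()
    def logu(lo, hi):
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    return TrainConfig(
        variant=base.variant,
        batch_size=int(rng.integers(*SEARCH_RANGES["batch_size"])),
        gamma=logu(*SEARCH_RANGES["gamma"]),
        max_lr=logu(*SEARCH_RANGES["max_lr"]),
        min_lr_factor=logu(*SEARCH_RANGES["min_lr_factor"]),
        pi_o=logu(*SEARCH_RANGES["pi_o"]),
        epochs=base.epochs,
        patience=base.patience,
        cycle_epochs=base.cycle_epochs,
        hidden_dim=base.hidden_dim,
        dropout=base.dropout,
        seed=base.seed,
    )


def random_search(
    n_trials: int,
    seed: int,
    train_fn,
    base: TrainConfig | None = None,
) -> tuple[TrainConfig, float, list[tuple[TrainConfig, float]]]:
    """Seeded random search: ``train_fn(config) -> validation loss``.

    Returns (best config, best loss, all trials).
    """
    rng = np.random.default_rng(seed)
    trials = []
    for _ in range(n_trials):
        cfg = sample_config(rng, base)
        loss = float(train_fn(cfg))
        trials.append((cfg, loss))
    best_cfg, best_loss = min(trials, key=lambda t: t[1])
    return best_cfg, best_loss, trials


def save_run(outdir, result: FitResult, scores: ScoreMatrix | None = None) -> None:
    """Persist a run: checkpoint, history, frozen config, predictions."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.model.save(outdir / "checkpoint.npz")
    with open(outdir / "history.json", "w") as fh:
        json.dump(result.history, fh, indent=2)
    with open(outdir / "config.json", "w") as fh:
        json.dump(asdict(result.config), fh, indent=2)
    if scores is not None:
        metrics_mod.write_cafa_tsv(scores, outdir / "predictions.tsv")
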