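"""Training and cross-validation harness.

Per-task default recipes:

==========  =========  ==========================  =====  ==========
task        model      optimizer                   batch  loss
==========  =========  ==========================  =====  ==========
classify    dcrn       SGD(lr 1e-3, m 0.9, wd 1e-4)  32   cross-entropy
segment     r2unet     Adam(lr 2e-4)                 16   soft Dice (MSE optional)
detect      udnet      Adam(lr 2e-4)                 64   MSE
==========  =========  ==========================  =====  ==========

Defaults are overridable; epochs default to 100 / 250 / 500 respectively and
are usually reduced explicitly for desk-scale runs.  Inside each training
fold a seeded 10% validation split is held out.  Runs are replayable: the
:class:`RunRecord` stores the config snapshot, the per-epoch metric trace and
the random seed.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import architectures as arch
from .evaluation import FoldReport, dice_coefficient, kfold_split, mean_squared_error
from .nn import Adam, SGD, Tensor, losses, no_grad

TASKS = ("classify", "segment", "detect")
_TASK_DEFAULTS = {
    "classify": dict(model_variant="dcrn", optimizer="sgd", learning_rate=1e-3,
                     momentum=0.9, weight_decay=1e-4, loss="cross-entropy",
                     epochs=100, batch_size=32),
    "segment": dict(model_variant="r2unet", optimizer="adam", learning_rate=2e-4,
                    momentum=0.0, weight_decay=0.0, loss="dice",
                    epochs=250, batch_size=16),
    "detect": dict(model_variant="udnet", optimizer="adam", learning_rate=2e-4,
                   momentum=0.0, weight_decay=0.0, loss="mse",
                   epochs=500, batch_size=64),
}


@dataclass(frozen=True)
class TrainConfig:
    task: str
    model_variant: str
    optimizer: str
    learning_rate: float
    momentum: float
    weight_decay: float
    loss: str
    epochs: int
    batch_size: int
    seed: int = 0
    folds: int = 5
    val_fraction: float = 0.1

    def __post_init__(self):
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.optimizer not in ("sgd", "adam"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.loss not in ("cross-entropy", "dice", "mse"):
            raise ValueError(f"unknown loss {self.loss!r}")

    @classmethod
    def for_task(cls, task: str, **overrides) -> "TrainConfig":
        if task not in _TASK_DEFAULTS:
            raise ValueError(f"unknown task {task!r}")
        kw = dict(_TASK_DEFAULTS[task])
        kw.update(overrides)
        return cls(task=task, **kw)

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "TrainConfig":
        return cls(**yaml.safe_load(text))


@dataclass
class RunRecord:
    config: dict
    history: list = field(default_factory=list)   # one dict per epoch
    final: dict = field(default_factory=dict)
    artifacts: dict = field(default_factory=dict)

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "run.json").write_text(json.dumps(
            {"config": self.config, "final": self.final,
             "artifacts": self.artifacts}, indent=2))
        with open(out / "log.jsonl", "w") as fh:
            for row in self.history:
                fh.write(json.dumps(row) + "\n")
        import pandas as pd
        pd.DataFrame(self.history).to_csv(out / "metrics.csv", index=False)
        self.artifacts["run_dir"] = str(out)


# ---------------------------------------------------------------------------
# data adaptation
# ---------------------------------------------------------------------------

def _prepare(task: str, data) -> tuple[np.ndarray, np.ndarray]:
    """Normalise ``(inputs, targets)`` to float32 NHWC in [0, 1]."""
    x, y = data
    x = np.asarray(x, dtype=np.float32)
    if x.size and x.max() > 1.5:
        x = x / 255.0
    if task == "classify":
        return x, np.asarray(y, dtype=int)
    if x.ndim == 3:
        x = x[..., None]
    y = np.asarray(y, dtype=np.float32)
    if task == "segment":
        y = (y > 0.5).astype(np.float32)
    return x, y


def _build(cfg: TrainConfig):
    return arch.build_model(arch.model_spec(cfg.model_variant, seed=cfg.seed))


def _make_optimizer(cfg: TrainConfig, model):
    if cfg.optimizer == "sgd":
        return SGD(model.parameters(), lr=cfg.learning_rate,
                   momentum=cfg.momentum, weight_decay=cfg.weight_decay)
    return Adam(model.parameters(), lr=cfg.learning_rate,
                weight_decay=cfg.weight_decay)


def _batch_loss(cfg: TrainConfig, model, xb: np.ndarray, yb: np.ndarray):
    out = model(Tensor(xb))
    if cfg.loss == "cross-entropy":
        return losses.cross_entropy(out, yb)
    if cfg.loss == "dice":
        return losses.soft_dice(out, yb)
    return losses.mse(out, yb)


def evaluate(cfg: TrainConfig, model, x: np.ndarray, y: np.ndarray,
             batch_size: int | None = None) -> dict:
    """Task metrics on a held-out set (eval mode, no graph)."""
    bs = batch_size or cfg.batch_size
    model.eval()
    preds = []
    with no_grad():
        for i in range(0, len(x), bs):
            preds.append(model(Tensor(x[i:i + bs])).data)
    pred = np.concatenate(preds, axis=0)
    if cfg.task == "classify":
        acc = float((pred.argmax(axis=1) == y).mean())
        return {"accuracy": acc}
    if cfg.task == "segment":
        dcs = [dice_coefficient(t.astype(int), (p > 0.5).astype(int))
               for p, t in zip(pred, y)]
        return {"dice": float(np.mean(dcs)),
                "mse": mean_squared_error(y, pred)}
    return {"mse": mean_squared_error(y, pred)}


def run_training(cfg: TrainConfig, data, out_dir=None, model=None) -> RunRecord:
    """Train on ``data = (inputs, targets)``; returns the run record.

    A seeded ``val_fraction`` split is held out for per-epoch validation
    metrics; the trained model is attached as ``record.model``.
    """
    x, y = _prepare(cfg.task, data)
    if len(x) == 0:
        raise ValueError("empty dataset")
    if model is None:
        model = _build(cfg)
    if cfg.task == "classify" and not isinstance(model, arch.DenseClassifier):
        raise ValueError("classification task requires a classifier model")
    if cfg.task in ("segment", "detect") and not isinstance(model, arch.EncoderDecoder):
        raise ValueError(f"{cfg.task} task requires an encoder/decoder model")

    rng = np.random.default_rng(cfg.seed)
    n_val = int(round(cfg.val_fraction * len(x)))
    order = rng.permutation(len(x))
    val_idx, train_idx = order[:n_val], order[n_val:]
    if len(train_idx) == 0:
        raise ValueError("no training samples left after validation split")
    xv, yv = x[val_idx], y[val_idx]
    xt, yt = x[train_idx], y[train_idx]

    opt = _make_optimizer(cfg, model)
    record = RunRecord(config=dataclasses.asdict(cfg))
    for epoch in range(cfg.epochs):
        model.train()
        perm = rng.permutation(len(xt))
        epoch_loss, nb = 0.0, 0
        for i in range(0, len(xt), cfg.batch_size):
            idx = perm[i:i + cfg.batch_size]
            loss = _batch_loss(cfg, model, xt[idx], yt[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += loss.item()
            nb += 1
        row = {"epoch": epoch, "train_loss": epoch_loss / nb}
        if len(xv):
            row.update({f"val_{k}": v for k, v in
                        evaluate(cfg, model, xv, yv).items()})
        record.history.append(row)
    record.final = dict(record.history[-1]) if record.history else {}
    record.model = model  # type: ignore[attr-defined]
    if out_dir is not None:
        record.save(out_dir)
    return record


def run_crossval(cfg: TrainConfig, data, k: int | None = None) -> FoldReport:
    """k-fold protocol: train on k-1 folds, score the held-out fold."""
    k = k or cfg.folds
    if k < 2:
        raise ValueError("k must be at least 2")
    x, y = _prepare(cfg.task, data)
    if len(x) < k:
        raise ValueError("fewer samples than folds")
    metric = {"classify": "accuracy", "segment": "dice", "detect": "mse"}[cfg.task]
    values = []
    for split in kfold_split(len(x), k, cfg.seed):
        rec = run_training(cfg, (x[split.train_indices], y[split.train_indices]))
        scores = evaluate(cfg, rec.model, x[split.test_indices], y[split.test_indices])
        values.append(scores[metric])
    return FoldReport(metric, values)
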