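"""Training loop, subject-wise cross-validation, checkpointing and evaluation.

Training minimizes mean cross-entropy with decoupled-weight-decay Adam
(AdamW) at a learning rate of 5e-5, stopping early when validation accuracy
has not improved for a patience of epochs and restoring the best-validation
weights.  Cross-validation folds are split by subject so no subject
contributes to more than one of train/validation/test within a fold.

A training run is a pure function of its seed: weight initialization, batch
order, dropout masks and CrossNorm pairings all derive from ``TrainConfig.seed``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from somnostage.autodiff import Tensor, cross_entropy_logits
from somnostage.metrics import MetricsReport, confusion, overall_metrics
from somnostage.model import ModelConfig, SleepStageNet


@dataclass
class TrainConfig:
    """Optimization hyperparameters."""

    lr: float = 5e-5
    weight_decay: float = 0.01
    batch_size: int = 32
    max_epochs: int = 100
    early_stop_patience: int = 10
    k_folds: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.lr < 0:
            raise ValueError(f"lr must be >= 0, got {self.lr}")
        if self.k_folds < 2:
            raise ValueError(f"k_folds must be >= 2, got {self.k_folds}")
        if self.early_stop_patience < 1:
            raise ValueError(f"patience must be >= 1, got {self.early_stop_patience}")


class AdamW:
    """Adam with decoupled weight decay (bias-corrected moments)."""

    def __init__(
        self,
        params: list[Tensor],
        lr: float,
        weight_decay: float = 0.01,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p.data)


# ---------------------------------------------------------------------------
# cross-validation folds
# ---------------------------------------------------------------------------


@dataclass
class Fold:
    train: list[str]
    validation: list[str]
    test: list[str]


def kfold_split(subject_ids: list[str], k: int, seed: int) -> list[Fold]:
    """Subject-wise K-fold partitions with a rotating validation block.

    Test blocks are exhaustive and pairwise disjoint over the folds; within
    each fold roughly 1/k of the non-test subjects (at least one) are held out
    for early stopping.
    """
    subjects = list(subject_ids)
    if k > len(subjects):
        raise ValueError(f"k={k} exceeds the number of subjects ({len(subjects)})")
    order = np.random.default_rng(seed).permutation(len(subjects))
    shuffled = [subjects[i] for i in order]
    test_blocks = [list(b) for b in np.array_split(np.array(shuffled, dtype=object), k)]
    folds = []
    for i, test in enumerate(test_blocks):
        rest = [s for s in shuffled if s not in test]
        n_val = max(1, len(rest) // k)
        offset = (i * n_val) % len(rest)
        validation = [rest[(offset + j) % len(rest)] for j in range(n_val)]
        train = [s for s in rest if s not in validation]
        folds.append(Fold(train=train, validation=validation, test=[str(s) for s in test]))
    return folds


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


@dataclass
class TrainResult:
    state: dict[str, np.ndarray]
    history: dict[str, list[float]]
    best_epoch: int
    best_val_acc: float


def _accuracy(model: SleepStageNet, images: np.ndarray, labels: np.ndarray) -> float:
    probs = model.predict_proba(images)
    return float((probs.argmax(axis=1) == labels).mean())


def train_fold(
    model_cfg: ModelConfig,
    train_data: tuple[np.ndarray, np.ndarray],
    val_data: tuple[np.ndarray, np.ndarray],
    tcfg: TrainConfig,
    verbose: bool = False,
) -> TrainResult:
    """Train one fold to best validation accuracy with early stopping."""
    x_train, y_train = train_data
    x_val, y_val = val_data
    if len(x_train) == 0 or len(x_val) == 0:
        raise ValueError("train and validation sets must be non-empty")
    init_seed, loop_seed = (s.generate_state(1)[0] % 2**31 for s in np.random.SeedSequence(tcfg.seed).spawn(2))
    model = SleepStageNet(model_cfg, seed=int(init_seed))
    rng = np.random.default_rng(int(loop_seed))
    model.apply_rng(rng)
    opt = AdamW(model.parameters(), lr=tcfg.lr, weight_decay=tcfg.weight_decay)

    history: dict[str, list[float]] = {"train_loss": [], "val_acc": []}
    best_state = model.state_dict()
    best_val, best_epoch, stale = -np.inf, -1, 0
    n = len(x_train)
    for epoch in range(tcfg.max_epochs):
        model.train()
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, tcfg.batch_size):
            idx = order[start : start + tcfg.batch_size]
            model.zero_grad()
            loss = cross_entropy_logits(model(x_train[idx]), y_train[idx])
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}, batch start {start}: {loss.data}"
                )
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        val_acc = _accuracy(model, x_val, y_val)
        history["train_loss"].append(float(np.mean(losses)))
        history["val_acc"].append(val_acc)
        if verbose:
            print(f"epoch {epoch}: loss {np.mean(losses):.4f} val_acc {val_acc:.3f}")
        if val_acc > best_val:
            best_val, best_epoch, stale = val_acc, epoch, 0
            best_state = model.state_dict()
        else:
            stale += 1
            if stale >= tcfg.early_stop_patience:
                break
    return TrainResult(state=best_state, history=history, best_epoch=best_epoch, best_val_acc=best_val)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def config_hash(cfg: ModelConfig) -> str:
    payload = json.dumps(asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def save_checkpoint(path: str | Path, state: dict[str, np.ndarray], model_cfg: ModelConfig, seed: int) -> Path:
    """Serialize a layer-name -> array map with a JSON header."""
    path = Path(path)
    header = {
        "config_hash": config_hash(model_cfg),
        "config": asdict(model_cfg),
        "seed": int(seed),
        "class_encoding": {"W": 0, "N1": 1, "N2": 2, "N3": 3, "REM": 4},
    }
    np.savez(path, __header__=np.frombuffer(json.dumps(header, default=str).encode(), dtype=np.uint8), **state)
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_checkpoint(path: str | Path, model_cfg: ModelConfig) -> SleepStageNet:
    """Rebuild a model from a checkpoint; the config hash must match."""
    with np.load(Path(path)) as npz:
        header = json.loads(bytes(npz["__header__"].tobytes()).decode())
        state = {k: npz[k] for k in npz.files if k != "__header__"}
    if header["config_hash"] != config_hash(model_cfg):
        raise ValueError(
            f"checkpoint config hash {header['config_hash']} does not match "
            f"the supplied config ({config_hash(model_cfg)})"
        )
    model = SleepStageNet(model_cfg, seed=int(header["seed"]))
    model.load_state_dict(state)
    return model.eval()


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


@dataclass
class EvalResult:
    report: MetricsReport
    confusion: np.ndarray
    truth: np.ndarray
    predicted: np.ndarray


def evaluate(model: SleepStageNet, images: np.ndarray, labels: np.ndarray) -> EvalResult:
    """Per-epoch predictions aggregated into a confusion matrix and metrics."""
    labels = np.asarray(labels, dtype=np.int64)
    probs = model.predict_proba(images)
    pred = probs.argmax(axis=1)
    cm = confusion(labels, pred)
    return EvalResult(report=overall_metrics(cm), confusion=cm, truth=labels, predicted=pred)
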