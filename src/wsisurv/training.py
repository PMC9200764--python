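"""Weakly supervised training of the risk model with the Cox partial likelihood.

Patches carry only their patient's censored survival label.  Mini-batches
contain at most one patch per patient, so the batch itself is a valid
risk-set universe for the partial likelihood.  Optimization follows an
adaptive-gradient scheme with heavy-ball momentum (0.95), initial learning
rate 1e-4 decayed by 0.97 per epoch.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _coxph
from .model import RiskModel
from .tiling import augment as _augment
from .tiling import normalize as _normalize

__all__ = [
    "SurvivalBatch",
    "TrainConfig",
    "PatientPatches",
    "cox_nll",
    "cox_nll_grad",
    "make_minibatches",
    "train",
]


@dataclass
class SurvivalBatch:
    """One mini-batch of normalized patches from pairwise-distinct patients."""

    patches: np.ndarray           # (n, H, W, 3), normalized
    times: np.ndarray             # months
    events: np.ndarray            # {0, 1}
    patient_ids: list[str]

    def __post_init__(self) -> None:
        n = len(self.patient_ids)
        if not (len(self.patches) == len(self.times) == len(self.events) == n):
            raise ValueError("batch fields must have equal lengths")
        if len(set(self.patient_ids)) != n:
            raise ValueError("patient ids must be pairwise distinct within a batch")


@dataclass
class TrainConfig:
    lr0: float = 1e-4
    lr_decay: float = 0.97
    momentum: float = 0.95
    epochs: int = 10
    batch_size: int = 16
    seed: int = 0
    augment: bool = True
    optimizer: str = "adagrad_momentum"  # or "adagrad", "sgd_momentum"
    ties: str = "breslow"

    def __post_init__(self) -> None:
        if self.lr0 <= 0:
            raise ValueError("lr0 must be > 0")
        if not (0 < self.lr_decay <= 1):
            raise ValueError("lr_decay must be in (0, 1]")


@dataclass
class PatientPatches:
    """Raw [0, 1] patches of one patient plus the weak survival label."""

    patches: np.ndarray  # (n, H, W, 3)
    time_months: float
    event: int


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def cox_nll(risks, times, events, ties: str = "breslow") -> float:
    """Negative log partial likelihood of risks given censored times.

        l = - sum_{m: d_m = 1} [ r_m - log sum_{j: t_j >= t_m} exp(r_j) ]

    computed with max-subtracted log-sum-exp; ties use the Breslow shared
    risk set (Efron via ``ties="efron"``).  Returns 0 when no events.
    """
    return _coxph.nll(risks, times, events, ties=ties)


def cox_nll_grad(risks, times, events, ties: str = "breslow") -> np.ndarray:
    """Gradient of :func:`cox_nll` with respect to the risks."""
    return _coxph.grad_risks(risks, times, events, ties=ties)


# ---------------------------------------------------------------------------
# batching
# ---------------------------------------------------------------------------

def make_minibatches(patch_index, batch_size: int, seed: int, events: dict):
    """Plan one epoch of unique-patient mini-batches.

    ``patch_index`` is a list of ``(patient_id, ref)`` pairs; ``events``
    maps patient id to the event indicator.  Every emitted batch has at
    most one patch per patient and at least one observed event (a batch
    with no events makes the partial likelihood degenerate and is
    dropped); a final short batch is kept only with >= 2 patients and
    >= 1 event.  Deterministic given the seed.
    """
    patients = {}
    for pid, ref in patch_index:
        patients.setdefault(pid, []).append(ref)
    if batch_size > len(patients):
        raise ValueError(
            f"batch_size {batch_size} exceeds number of distinct patients ({len(patients)})"
        )
    rng = np.random.default_rng(seed)
    queues = {}
    for pid in sorted(patients):
        refs = list(patients[pid])
        rng.shuffle(refs)
        queues[pid] = refs

    batches = []
    while True:
        eligible = sorted(pid for pid, q in queues.items() if q)
        if not eligible:
            break
        rng.shuffle(eligible)
        chosen = eligible[:batch_size]
        batch = [(pid, queues[pid].pop()) for pid in chosen]
        n_events = sum(events[pid] for pid, _ in batch)
        if len(batch) < batch_size and (len(batch) < 2 or n_events == 0):
            continue  # leftover batch too degenerate for the loss; drop it
        if n_events == 0:
            continue  # skip event-free batches
        batches.append(batch)
    return batches


# ---------------------------------------------------------------------------
# optimizers
# ---------------------------------------------------------------------------

class _Optimizer:
    def __init__(self, params: dict, momentum: float = 0.95, eps: float = 1e-10):
        self.params = params
        self.momentum = momentum
        self.eps = eps
        self.G = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}


class AdaGradMomentum(_Optimizer):
    """Per-parameter adaptive accumulator plus heavy-ball momentum."""

    def step(self, grads: dict, lr: float) -> None:
        for k, p in self.params.items():
            g = grads[k]
            self.G[k] += g * g
            self.v[k] = self.momentum * self.v[k] + lr * g / (np.sqrt(self.G[k]) + self.eps)
            p -= self.v[k]


class AdaGrad(_Optimizer):
    def step(self, grads: dict, lr: float) -> None:
        for k, p in self.params.items():
            g = grads[k]
            self.G[k] += g * g
            p -= lr * g / (np.sqrt(self.G[k]) + self.eps)


class SGDMomentum(_Optimizer):
    def step(self, grads: dict, lr: float) -> None:
        for k, p in self.params.items():
            self.v[k] = self.momentum * self.v[k] + lr * grads[k]
            p -= self.v[k]


_OPTIMIZERS = {
    "adagrad_momentum": AdaGradMomentum,
    "adagrad": AdaGrad,
    "sgd_momentum": SGDMomentum,
}


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _child_seed(*entropy) -> int:
    return int(np.random.SeedSequence(list(entropy)).generate_state(1)[0] % (2**31 - 1))


def _patient_median_risks(model: RiskModel, dataset: dict) -> dict:
    risks = {}
    for pid, pp in dataset.items():
        x = _normalize(pp.patches).transpose(0, 3, 1, 2)
        risks[pid] = float(np.median(model.forward(x, train=False)))
    return risks


def train(model: RiskModel, dataset: dict, config: TrainConfig, val_dataset: dict | None = None):
    """Optimize ``model`` on a ``{patient_id: PatientPatches}`` dataset.

    Logs per-epoch mean batch loss and, when a validation set is given,
    the validation c-index of patient-median risks; the best-validation
    weights are restored at the end.  Returns ``(model, history)``.
    """
    from .evaluation import concordance_index

    opt_cls = _OPTIMIZERS.get(config.optimizer)
    if opt_cls is None:
        raise ValueError(f"unknown optimizer {config.optimizer!r}")
    params = model.parameters()
    opt = opt_cls(params, momentum=config.momentum)

    patch_index = [
        (pid, i) for pid in sorted(dataset) for i in range(len(dataset[pid].patches))
    ]
    events_map = {pid: dataset[pid].event for pid in dataset}

    best_state, best_val = None, -np.inf
    rows = []
    for epoch in range(config.epochs):
        lr = config.lr0 * config.lr_decay**epoch
        batches = make_minibatches(
            patch_index, config.batch_size, _child_seed(config.seed, epoch), events_map
        )
        loss_sum, event_sum = 0.0, 0
        for step, batch in enumerate(batches):
            imgs = []
            for i, (pid, ref) in enumerate(batch):
                img = dataset[pid].patches[ref]
                if config.augment:
                    img = _augment(img, _child_seed(config.seed, epoch, step, i))
                imgs.append(_normalize(img))
            x = np.stack(imgs).transpose(0, 3, 1, 2)
            times = np.array([dataset[pid].time_months for pid, _ in batch])
            events = np.array([dataset[pid].event for pid, _ in batch])
            risks = model.forward(x, train=True)
            loss = cox_nll(risks, times, events, ties=config.ties)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, step {step}: {loss!r}; "
                    f"risk range [{risks.min()}, {risks.max()}]"
                )
            model.backward(cox_nll_grad(risks, times, events, ties=config.ties))
            opt.step(model.gradients(), lr)
            loss_sum += loss
            event_sum += int(events.sum())

        val_c = np.nan
        if val_dataset:
            risks = _patient_median_risks(model, val_dataset)
            pids = sorted(risks)
            try:
                val_c = concordance_index(
                    np.array([risks[p] for p in pids]),
                    np.array([val_dataset[p].time_months for p in pids]),
                    np.array([val_dataset[p].event for p in pids]),
                )
            except ValueError:
                val_c = np.nan
            if np.isfinite(val_c) and val_c > best_val:
                best_val = val_c
                best_state = copy.deepcopy(model.state_dict())
        # per-event normalization makes the logged loss comparable across epochs
        rows.append(
            {"epoch": epoch, "loss": loss_sum / max(event_sum, 1), "val_cindex": val_c, "lr": lr}
        )

    if best_state is not None:
        model.load_state_dict(best_state)
    return model, pd.DataFrame(rows)
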