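"""Training: combined matrix/energy/force loss, augmentation, Adam, LR schedule.

The loss for one sample is

    ||H - H~||_F^2 + ||S - S~||_F^2 + rho |E - E~|^2
      + (1 - rho)/n_atoms sum_i ||F_i + dE~/dr_i||^2

(tildes = predictions).  The force term contains the analytic position
gradient of the predicted energy, so its parameter gradient is obtained by
double backprop through the autodiff graph.

When augmentation is on, every epoch draws a fresh random rotor per training
sample and rotates geometry, forces and the H/S blocks consistently; the
network then sees many orientations of each reference calculation and learns
the rotational covariance of the matrix blocks.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import autodiff as ad
from .chem import ConfigurationError, ElectronicRecord, build_orbital_index
from .model import Forward, ModelConfig
from .rotations import random_rotation, rotate_record


class DivergenceError(RuntimeError):
    """Non-finite loss encountered during optimization."""


@dataclasses.dataclass
class TrainConfig:
    rho: float = 0.1             # energy/force trade-off in [0, 1]
    lr0: float = 1e-3
    decay: float = 0.8
    patience: int = 15           # epochs without validation improvement
    lr_min: float = 5e-6
    batch_size: int = 8
    max_epochs: int = 100
    seed: int = 0
    augment: bool = True
    val_fraction: float = 0.1
    improvement_tol: float = 1e-4   # relative decrease counting as improvement

    def __post_init__(self):
        if not 0.0 <= self.rho <= 1.0:
            raise ConfigurationError("rho must lie in [0, 1]")
        if not 0.0 < self.decay < 1.0 or self.lr_min >= self.lr0:
            raise ConfigurationError("need 0 < decay < 1 and lr_min < lr0")


@dataclasses.dataclass
class TrainHistory:
    epochs: list = dataclasses.field(default_factory=list)  # dict per epoch
    best_epoch: int = -1

    @property
    def lr_trace(self):
        return [e["lr"] for e in self.epochs]


def combined_loss(fwd: Forward, ref: ElectronicRecord, rho: float):
    """Total loss tensor plus the numeric per-term breakdown."""
    if fwd.H.value.shape != ref.H.shape:
        raise ValueError("prediction/reference shape mismatch")
    dH = fwd.H - ad.constant(ref.H)
    dS = fwd.S - ad.constant(ref.S)
    term_H = ad.tsum(dH * dH)
    term_S = ad.tsum(dS * dS)
    dE = fwd.E - ref.E
    term_E = dE * dE * rho
    dEdr = ad.grad(fwd.E, [fwd.pos])[0]
    dF = ad.constant(ref.F) + dEdr               # F_ref - (-dE/dr)
    term_F = ad.tsum(dF * dF) * ((1.0 - rho) / ref.molecule.n_atoms)
    total = term_H + term_S + term_E + term_F
    terms = {"H": float(term_H.value), "S": float(term_S.value),
             "E": float(term_E.value), "F": float(term_F.value),
             "total": float(total.value)}
    return total, terms


def evaluate_loss(params, config: ModelConfig, records, rho: float, index=None):
    """Mean per-term loss of ``params`` over ``records`` (no parameter update)."""
    agg = {"H": 0.0, "S": 0.0, "E": 0.0, "F": 0.0, "total": 0.0}
    for rec in records:
        fwd = Forward(params, config, rec.molecule, index)
        _, terms = combined_loss(fwd, rec, rho)
        for k in agg:
            agg[k] += terms[k] / len(records)
    return agg


class _Adam:
    def __init__(self, keys, lr):
        self.lr, self.t = lr, 0
        self.m = {k: 0.0 for k in keys}
        self.v = {k: 0.0 for k in keys}

    def step(self, params, grads, b1=0.9, b2=0.999, eps=1e-8):
        self.t += 1
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k].value -= self.lr * mhat / (np.sqrt(vhat) + eps)


def split_dataset(records, val_fraction: float, seed: int):
    """Disjoint train/validation split by seeded shuffle."""
    idx = np.random.default_rng(seed).permutation(len(records))
    n_val = max(1, int(round(val_fraction * len(records))))
    if n_val >= len(records):
        raise ConfigurationError("validation split leaves no training data")
    val = [records[i] for i in idx[:n_val]]
    train = [records[i] for i in idx[n_val:]]
    return train, val


def train(params: dict, config: ModelConfig, records, cfg: TrainConfig,
          basis=None, val_records=None):
    """Optimize ``params`` in place; returns (best parameters, history)."""
    if val_records is None:
        train_recs, val_recs = split_dataset(records, cfg.val_fraction, cfg.seed)
    else:
        train_recs, val_recs = list(records), list(val_records)
    if not train_recs or not val_recs:
        raise ConfigurationError("empty train or validation split")
    index = build_orbital_index(train_recs[0].molecule, basis) if basis is not None else None

    rng = np.random.default_rng(cfg.seed + 1)
    keys = list(params)
    opt = _Adam(keys, cfg.lr0)
    history = TrainHistory()
    best_val, best_params = np.inf, {k: params[k].value.copy() for k in keys}
    stale = 0

    for epoch in range(cfg.max_epochs):
        epoch_recs = train_recs
        if cfg.augment:
            if index is None:
                raise ConfigurationError("augmentation requires the basis set")
            epoch_recs = [rotate_record(r, random_rotation(rng), index)
                          for r in train_recs]
        order = rng.permutation(len(epoch_recs))
        train_terms = {"H": 0.0, "S": 0.0, "E": 0.0, "F": 0.0, "total": 0.0}
        for start in range(0, len(order), cfg.batch_size):
            batch = [epoch_recs[i] for i in order[start:start + cfg.batch_size]]
            total = None
            for rec in batch:
                fwd = Forward(params, config, rec.molecule, index)
                loss, terms = combined_loss(fwd, rec, cfg.rho)
                loss = loss * (1.0 / len(batch))
                total = loss if total is None else total + loss
                for k in train_terms:
                    train_terms[k] += terms[k] / len(order)
            if not np.isfinite(total.value):
                raise DivergenceError(f"non-finite loss at epoch {epoch}")
            gts = ad.grad(total, [params[k] for k in keys])
            opt.step(params, {k: g.value for k, g in zip(keys, gts)})

        val_terms = evaluate_loss(params, config, val_recs, cfg.rho, index)
        history.epochs.append({"lr": opt.lr,
                               **{f"train_{k}": v for k, v in train_terms.items()},
                               **{f"val_{k}": v for k, v in val_terms.items()}})
        if val_terms["total"] < best_val * (1.0 - cfg.improvement_tol):
            best_val = val_terms["total"]
            best_params = {k: params[k].value.copy() for k in keys}
            history.best_epoch = epoch
            stale = 0
        else:
            stale += 1
            if stale >= max(cfg.patience, 1):
                opt.lr *= cfg.decay
                stale = 0
        if opt.lr <= cfg.lr_min:
            break

    best = {k: ad.tensor(v) for k, v in best_params.items()}
    return best, history


def history_to_csv(history: TrainHistory, path) -> None:
    import csv
    if not history.epochs:
        return
    keys = list(history.epochs[0])
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=["epoch"] + keys)
        w.writeheader()
        for e, row in enumerate(history.epochs):
            w.writerow({"epoch": e, **row})
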