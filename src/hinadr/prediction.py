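"""Prediction heads mapping drug embeddings to the three ADR tasks.

Task 1 (``single_drug_se``) ranks side effects for a single drug — a
multi-label problem over the side-effect vocabulary.  Task 2
(``ddi_occurrence``) scores whether an unordered drug pair interacts —
binary.  Task 3 (``ddi_type``) ranks the ADR event types an interacting
pair may cause — multi-label over the same vocabulary.

Every task uses the same fully-connected head ``y' = sigmoid(W_P e + b)``
trained on the summed binary cross-entropy plus a Frobenius penalty
``lambda ||W_P||_F^2`` (bias unpenalized), fit by L-BFGS on the exact loss;
zero initialization makes the fit deterministic.  Pair features are the
concatenation of the two drug embeddings; because an interaction is an
unordered pair, training presents both orders and prediction averages them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import minimize

from .hin_core import EmbeddingMatrix

__all__ = [
    "TASKS",
    "TaskDataset",
    "TaskHead",
    "pair_features",
    "negative_sample",
    "train_head",
    "predict_task",
]

TASKS = ("single_drug_se", "ddi_occurrence", "ddi_type")
_EPS = 1e-12


@dataclass
class TaskDataset:
    """Labeled instances for one prediction task.

    ``instances`` holds drug IDs (task 1) or unordered drug-ID pairs
    (tasks 2-3); ``labels`` is binary, one row per instance (width 1 for
    occurrence, the side-effect vocabulary width for the multi-label
    tasks).  ``split`` assigns each *drug* to train/validation/test; an
    instance belongs to the test fold as soon as any member drug does.
    """

    task: str
    instances: list
    labels: np.ndarray
    split: dict[str, str] = field(default_factory=dict)

    def validate(self, known_drugs: Iterable[str] | None = None) -> "TaskDataset":
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        Y = np.asarray(self.labels)
        if Y.shape[0] != len(self.instances):
            raise ValueError("labels and instances disagree in length")
        if Y.size and not np.isin(Y, (0, 1)).all():
            raise ValueError("labels must be binary")
        if known_drugs is not None:
            known = set(known_drugs)
            for inst in self.instances:
                members = (inst,) if self.task == "single_drug_se" else tuple(inst)
                for m in members:
                    if m not in known:
                        raise ValueError(f"instance references unknown drug {m!r}")
        return self

    def _members(self, inst):
        return (inst,) if self.task == "single_drug_se" else tuple(inst)

    def fold_indices(self, fold: str) -> np.ndarray:
        """Instances whose drugs all sit in ``fold`` (train/validation), or —
        for the test fold — instances touching at least one test drug."""
        out = []
        for k, inst in enumerate(self.instances):
            assigned = {self.split.get(m, "train") for m in self._members(inst)}
            if fold == "test":
                if "test" in assigned:
                    out.append(k)
            elif assigned == {fold}:
                out.append(k)
        return np.asarray(out, dtype=int)


@dataclass
class TaskHead:
    """Fully-connected sigmoid head: ``W_P`` (d_in x n_out), bias, lambda."""

    W: np.ndarray
    b: np.ndarray
    lam: float = 1e-4

    def predict(self, X: np.ndarray) -> np.ndarray:
        z = X @ self.W + self.b
        p = 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))
        # keep scores strictly inside (0, 1) despite float saturation
        return np.clip(p, _EPS, 1.0 - _EPS)


def pair_features(eF: EmbeddingMatrix, pair: Sequence[str]) -> np.ndarray:
    """Concatenated embedding ``[e_i || e_j]`` for a drug pair."""
    i, j = pair
    idx = {d: k for k, d in enumerate(eF.ids)}
    try:
        return np.concatenate([eF.E[idx[i]], eF.E[idx[j]]])
    except KeyError as e:
        raise KeyError(f"unknown drug {e.args[0]!r}") from None


def negative_sample(
    positives: Iterable,
    universe: Sequence,
    ratio: float,
    rng: np.random.Generator,
) -> list:
    """Uniform negatives from ``universe`` minus ``positives``.

    Draws ``floor(ratio * |positives|)`` distinct instances without
    replacement; deterministic for a given generator state.
    """
    if ratio <= 0:
        raise ValueError("negative-sampling ratio must be positive")
    pos = set(positives)
    pool = [u for u in universe if u not in pos]
    count = int(ratio * len(pos))
    if count > len(pool):
        raise ValueError(
            f"universe holds {len(pool)} candidate negatives, {count} requested"
        )
    idx = rng.choice(len(pool), size=count, replace=False)
    return [pool[k] for k in sorted(idx)]


def _loss_and_grad(theta, X, Y, lam, d_in, n_out):
    W = theta[: d_in * n_out].reshape(d_in, n_out)
    b = theta[d_in * n_out :]
    Z = X @ W + b
    P = 1.0 / (1.0 + np.exp(-np.clip(Z, -500, 500)))
    Pc = np.clip(P, _EPS, 1.0 - _EPS)
    loss = -np.sum(Y * np.log(Pc) + (1.0 - Y) * np.log(1.0 - Pc))
    loss += lam * np.sum(W**2)
    G = P - Y
    gW = X.T @ G + 2.0 * lam * W
    gb = G.sum(axis=0)
    return loss, np.concatenate([gW.ravel(), gb])


def train_head(
    X: np.ndarray,
    Y: np.ndarray,
    lam: float = 1.0,
    max_iter: int = 500,
    per_label: bool = False,
) -> TaskHead:
    """Fit the regularized logistic head on binary labels.

    All outputs share the input and are fit jointly by default — with no
    shared hidden layer this is mathematically identical to fitting one
    logistic model per label; ``per_label=True`` runs the literal one-by-one
    protocol.  Degenerate all-one/all-zero label columns produce a warning
    but still fit (the bias absorbs them).
    """
    X = np.asarray(X, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] != X.shape[0]:
        Y = Y.reshape(X.shape[0], -1)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite features")
    col_mean = Y.mean(axis=0) if Y.size else np.array([])
    if Y.size and (np.any(col_mean == 0) or np.any(col_mean == 1)):
        import warnings

        warnings.warn("some label columns are single-class; fit proceeds")
    d_in, n_out = X.shape[1], Y.shape[1]

    if per_label and n_out > 1:
        heads = [train_head(X, Y[:, [j]], lam, max_iter) for j in range(n_out)]
        W = np.hstack([h.W for h in heads])
        b = np.concatenate([h.b for h in heads])
        return TaskHead(W=W, b=b, lam=lam)

    theta0 = np.zeros(d_in * n_out + n_out)
    res = minimize(
        _loss_and_grad,
        theta0,
        args=(X, Y, lam, d_in, n_out),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter},
    )
    W = res.x[: d_in * n_out].reshape(d_in, n_out)
    b = res.x[d_in * n_out :]
    return TaskHead(W=W, b=b, lam=lam)


def _pair_matrix(eF: EmbeddingMatrix, pairs: Sequence, flip: bool) -> np.ndarray:
    idx = {d: k for k, d in enumerate(eF.ids)}
    rows = []
    for i, j in pairs:
        a, b = (j, i) if flip else (i, j)
        rows.append(np.concatenate([eF.E[idx[a]], eF.E[idx[b]]]))
    return np.asarray(rows)


def training_features(eF: EmbeddingMatrix, dataset_like, instances, labels):
    """Feature/label matrices for head training; pairs appear in both orders."""
    task = dataset_like if isinstance(dataset_like, str) else dataset_like.task
    Y = np.atleast_2d(np.asarray(labels, dtype=float))
    if Y.shape[0] != len(instances):
        Y = Y.reshape(len(instances), -1)
    if task == "single_drug_se":
        idx = {d: k for k, d in enumerate(eF.ids)}
        X = np.asarray([eF.E[idx[d]] for d in instances])
        return X, Y
    Xf = _pair_matrix(eF, instances, flip=False)
    Xr = _pair_matrix(eF, instances, flip=True)
    return np.vstack([Xf, Xr]), np.vstack([Y, Y])


def predict_task(
    head: TaskHead,
    eF: EmbeddingMatrix,
    instances: Sequence,
    task: str,
) -> np.ndarray:
    """Score instances; pair tasks average the two orderings (symmetric)."""
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}")
    if task == "single_drug_se":
        if instances and not isinstance(instances[0], str):
            raise ValueError("single-drug task got pair instances")
        idx = {d: k for k, d in enumerate(eF.ids)}
        X = np.asarray([eF.E[idx[d]] for d in instances])
        return head.predict(X)
    if instances and isinstance(instances[0], str):
        raise ValueError(f"{task} expects drug pairs")
    Xf = _pair_matrix(eF, instances, flip=False)
    Xr = _pair_matrix(eF, instances, flip=True)
    return 0.5 * (head.predict(Xf) + head.predict(Xr))
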