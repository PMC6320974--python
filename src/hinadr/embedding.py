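"""Semi-supervised stacked denoising auto-encoders for drug embedding.

Each meta-path sub-network is encoded by its own SDAE: the input of drug i
is row i of the (normalized) proximity matrix, corrupted by randomly zeroing
input neurons, pushed through sigmoid encoder/decoder layers, and trained to
minimize

    L = L1 + alpha * L2 + beta * Lreg

where ``L1 = sum_i ||x_hat_i - x_i||^2`` is the denoising reconstruction
error, ``L2 = sum_ij S_ij ||e_i - e_j||^2`` is the proximity-preservation
supervision (drugs proximate under the meta-path are pulled together in
embedding space), and ``Lreg`` is the squared Frobenius norm of all encoder
and decoder weight matrices.  A secondary SDAE of the same form fuses the
concatenated per-meta-path embeddings into the final drug representation,
supervised by the alpha(p)-weighted average of the meta-path proximities.

Everything is plain NumPy: gradients are derived by hand (the supervision
term enters at the embedding layer as ``4 * alpha * L @ E`` with
``L = diag(S 1) - S``) and optimized with Adam.  Full-batch training is the
default — the drug axis is small — and every source of randomness (weight
init, corruption masks, minibatch sampling) flows from one explicit seed.
Corruption masks are keyed per drug ID, so a consistent permutation of the
drugs permutes the learned embeddings.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .hin_core import EmbeddingMatrix, MetaPathProximity, META_PATHS

__all__ = [
    "SDAEConfig",
    "IntegrationConfig",
    "corrupt",
    "pairwise_supervision_loss",
    "laplacian_supervision_loss",
    "sdae_loss",
    "train_subnetwork_embedding",
    "combine_supervision",
    "train_final_embedding",
    "grid_search_alpha",
    "ALPHA_GRID",
]

#: Grid searched for the meta-path fusion weights alpha(p).
ALPHA_GRID = (0.1, 0.2, 0.3, 0.4, 0.5)


@dataclass
class SDAEConfig:
    """Hyperparameters of one semi-supervised SDAE.

    ``layer_dims`` are the encoder hidden sizes ending at the embedding
    dimension d (the decoder mirrors them); ``corruption_p`` is the
    probability of zeroing each input neuron; ``alpha`` weights the
    proximity supervision and ``beta`` the L2 weight regularizer.
    """

    layer_dims: tuple[int, ...] = (256, 64)
    corruption_p: float = 0.2
    alpha: float = 1e-3
    beta: float = 1e-4
    learning_rate: float = 0.005
    epochs: int = 500
    batch_mode: str = "full"
    batch_size: int = 64
    layerwise_pretrain: bool = False
    pretrain_epochs: int = 50
    seed: int = 0

    def validate(self) -> "SDAEConfig":
        if not (0.0 <= self.corruption_p <= 1.0):
            raise ValueError("corruption_p must be in [0, 1]")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be nonnegative")
        if not self.layer_dims or any(d <= 0 for d in self.layer_dims):
            raise ValueError("layer_dims must be nonempty and positive")
        if self.batch_mode not in ("full", "minibatch"):
            raise ValueError("batch_mode must be 'full' or 'minibatch'")
        return self


@dataclass
class IntegrationConfig:
    """How the per-meta-path embeddings are fused.

    ``alpha_p`` maps each meta-path to its fusion weight; when
    ``grid_search`` is off every weight defaults to 0.3 (the grid midpoint).
    """

    alpha_p: dict[str, float] | None = None
    secondary: SDAEConfig = field(default_factory=SDAEConfig)
    grid_search: bool = False
    labeled_fraction: float = 0.1
    folds: int = 10
    search_mode: str = "coordinate"  # or "exhaustive" (K <= 3 only)
    sweeps: int = 2

    def resolve_weights(self, meta_paths: Sequence[str]) -> dict[str, float]:
        if self.alpha_p is None:
            return {mp: 0.3 for mp in meta_paths}
        if set(self.alpha_p) != set(meta_paths):
            raise ValueError(
                f"alpha_p keys {sorted(self.alpha_p)} do not cover meta-paths "
                f"{sorted(meta_paths)}"
            )
        if any(w <= 0 for w in self.alpha_p.values()):
            raise ValueError("fusion weights must be positive")
        return dict(self.alpha_p)


# ---------------------------------------------------------------------------
# Loss pieces
# ---------------------------------------------------------------------------


def corrupt(x: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Zero each input neuron independently with probability ``p``."""
    if not (0.0 <= p <= 1.0):
        raise ValueError("corruption probability must be in [0, 1]")
    if p == 0.0:
        return x.copy()
    mask = rng.random(x.shape) >= p
    return x * mask


def pairwise_supervision_loss(E: np.ndarray, S: np.ndarray) -> float:
    """Literal pairwise form ``sum_ij S_ij ||e_i - e_j||^2`` (the oracle)."""
    n = E.shape[0]
    total = 0.0
    for i in range(n):
        diff = E - E[i]
        total += float(S[i] @ np.einsum("ij,ij->i", diff, diff))
    return total


def laplacian_supervision_loss(E: np.ndarray, S: np.ndarray) -> float:
    """Efficient graph-Laplacian form ``2 tr(E^T L E)``, ``L = diag(S 1) - S``."""
    deg = S.sum(axis=1)
    LE = deg[:, None] * E - S @ E
    return float(2.0 * np.einsum("ij,ij->", E, LE))


def sdae_loss(
    x: np.ndarray,
    x_hat: np.ndarray,
    E: np.ndarray,
    S: np.ndarray,
    weights: Sequence[np.ndarray],
    alpha: float,
    beta: float,
) -> float:
    """Total loss ``L1 + alpha*L2 + beta*Lreg``.

    ``weights`` is the list of all encoder and decoder weight matrices
    entering the regularizer (biases are not penalized).
    """
    if x.shape != x_hat.shape or E.shape[0] != x.shape[0] or S.shape != (
        x.shape[0],
        x.shape[0],
    ):
        raise ValueError("inconsistent shapes in sdae_loss")
    l1 = float(np.sum((x_hat - x) ** 2))
    # literal double sum over ordered (i, j); for symmetric S this equals the
    # Laplacian form 2 tr(E^T L E) used in training
    sq = np.einsum("ij,ij->i", E, E)
    cross = np.einsum("ij,id,jd->", S, E, E)
    l2 = float(S.sum(axis=1) @ sq + S.sum(axis=0) @ sq - 2.0 * cross)
    lreg = float(sum(np.sum(W**2) for W in weights))
    return l1 + alpha * l2 + beta * lreg


# ---------------------------------------------------------------------------
# The network
# ---------------------------------------------------------------------------


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _drug_mask(drug_id: str, epoch: int, seed: int, width: int, p: float) -> np.ndarray:
    """Corruption mask keyed by (seed, epoch, drug ID), not row position."""
    key = zlib.crc32(str(drug_id).encode())
    rng = np.random.default_rng([seed & 0x7FFFFFFF, epoch, key])
    return rng.random(width) >= p


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        c1 = 1.0 - b1**self.t
        c2 = 1.0 - b2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / c1) / (np.sqrt(v / c2) + eps)


class SDAE:
    """Sigmoid encoder/decoder pair trained on the semi-supervised loss."""

    def __init__(self, n_in: int, cfg: SDAEConfig):
        cfg.validate()
        self.cfg = cfg
        dims = [n_in, *cfg.layer_dims]
        rng = np.random.default_rng(cfg.seed & 0x7FFFFFFF)
        self.W = [self._glorot(rng, a, b) for a, b in zip(dims[:-1], dims[1:])]
        self.b = [np.zeros(b) for b in dims[1:]]
        rdims = dims[::-1]
        self.Wd = [self._glorot(rng, a, b) for a, b in zip(rdims[:-1], rdims[1:])]
        self.bd = [np.zeros(b) for b in rdims[1:]]
        self.log: list[dict[str, float]] = []

    @staticmethod
    def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
        lim = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-lim, lim, size=(fan_in, fan_out))

    # -- forward -----------------------------------------------------------
    def encode(self, x: np.ndarray) -> np.ndarray:
        a = x
        for W, b in zip(self.W, self.b):
            a = _sigmoid(a @ W + b)
        return a

    def _forward(self, x: np.ndarray):
        acts = [x]
        a = x
        for W, b in zip(self.W, self.b):
            a = _sigmoid(a @ W + b)
            acts.append(a)
        dacts = [a]
        for W, b in zip(self.Wd, self.bd):
            a = _sigmoid(a @ W + b)
            dacts.append(a)
        return acts, dacts

    # -- training ----------------------------------------------------------
    def _corrupt_rows(self, X: np.ndarray, ids: Sequence[str], epoch: int) -> np.ndarray:
        p = self.cfg.corruption_p
        if p == 0.0:
            return X
        if p == 1.0:
            return np.zeros_like(X)
        mask = np.stack(
            [_drug_mask(i, epoch, self.cfg.seed, X.shape[1], p) for i in ids]
        )
        return X * mask

    def _step(
        self,
        X: np.ndarray,
        Xc: np.ndarray,
        S: np.ndarray,
        opt: _Adam,
        l2_scale: float = 1.0,
    ) -> tuple[float, float, float]:
        cfg = self.cfg
        acts, dacts = self._forward(Xc)
        E = acts[-1]
        x_hat = dacts[-1]

        l1 = float(np.sum((x_hat - X) ** 2))
        l2 = laplacian_supervision_loss(E, S) * l2_scale
        lreg = float(
            sum(np.sum(W**2) for W in self.W) + sum(np.sum(W**2) for W in self.Wd)
        )

        gW = [np.zeros_like(W) for W in self.W]
        gb = [np.zeros_like(b) for b in self.b]
        gWd = [np.zeros_like(W) for W in self.Wd]
        gbd = [np.zeros_like(b) for b in self.bd]

        # decoder backprop from the reconstruction error
        delta = 2.0 * (x_hat - X) * x_hat * (1.0 - x_hat)
        for k in range(len(self.Wd) - 1, -1, -1):
            a_prev = dacts[k]
            gWd[k] = a_prev.T @ delta + 2.0 * cfg.beta * self.Wd[k]
            gbd[k] = delta.sum(axis=0)
            if k > 0:
                delta = (delta @ self.Wd[k].T) * a_prev * (1.0 - a_prev)
            else:
                delta = delta @ self.Wd[k].T

        # supervision enters at the embedding layer: d/dE sum S_ij||ei-ej||^2 = 4 L E
        deg = S.sum(axis=1)
        delta = delta + cfg.alpha * l2_scale * 4.0 * (deg[:, None] * E - S @ E)

        # encoder backprop
        delta = delta * E * (1.0 - E)
        for k in range(len(self.W) - 1, -1, -1):
            a_prev = acts[k]
            gW[k] = a_prev.T @ delta + 2.0 * cfg.beta * self.W[k]
            gb[k] = delta.sum(axis=0)
            if k > 0:
                delta = (delta @ self.W[k].T) * a_prev * (1.0 - a_prev)

        params = [*self.W, *self.b, *self.Wd, *self.bd]
        grads = [*gW, *gb, *gWd, *gbd]
        opt.step(params, grads)
        return l1, cfg.alpha * l2, cfg.beta * lreg

    def fit(self, X: np.ndarray, S: np.ndarray, ids: Sequence[str]) -> "SDAE":
        cfg = self.cfg
        n = X.shape[0]
        params = [*self.W, *self.b, *self.Wd, *self.bd]
        opt = _Adam(params, cfg.learning_rate)
        batch_rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, 0xBA7C])
        for epoch in range(cfg.epochs):
            Xc = self._corrupt_rows(X, ids, epoch)
            if cfg.batch_mode == "full" or cfg.batch_size >= n:
                l1, l2, lreg = self._step(X, Xc, S, opt)
            else:
                idx = batch_rng.choice(n, size=cfg.batch_size, replace=False)
                frac = (cfg.batch_size / n) ** 2  # pair-sampling fraction
                l1, l2, lreg = self._step(
                    X[idx], Xc[idx], S[np.ix_(idx, idx)], opt, l2_scale=1.0 / frac
                )
            total = l1 + l2 + lreg
            if not np.isfinite(total):
                raise FloatingPointError(
                    f"non-finite SDAE loss at epoch {epoch}: "
                    f"L1={l1}, alpha*L2={l2}, beta*Lreg={lreg}"
                )
            self.log.append(
                {"epoch": epoch, "L1": l1, "L2": l2, "Lreg": lreg, "total": total}
            )
        return self

    def _pretrain(self, X: np.ndarray, ids: Sequence[str]) -> None:
        """Greedy layer-wise warm start: each (W_k, mirrored decoder) pair is
        briefly trained as a one-layer denoising auto-encoder on the previous
        layer's codes before end-to-end training."""
        cfg = self.cfg
        a = X
        for k in range(len(self.W)):
            sub_cfg = replace(
                cfg,
                layer_dims=(self.W[k].shape[1],),
                epochs=cfg.pretrain_epochs,
                alpha=0.0,
                layerwise_pretrain=False,
                seed=cfg.seed + 101 + k,
            )
            sub = SDAE(a.shape[1], sub_cfg)
            sub.W[0] = self.W[k].copy()
            sub.b[0] = self.b[k].copy()
            sub.fit(a, np.zeros((a.shape[0], a.shape[0])), ids)
            self.W[k] = sub.W[0]
            self.b[k] = sub.b[0]
            mirror = len(self.Wd) - 1 - k
            self.Wd[mirror] = sub.Wd[0]
            self.bd[mirror] = sub.bd[0]
            a = sub.encode(a)


def train_subnetwork_embedding(
    S_p: MetaPathProximity,
    cfg: SDAEConfig,
    ids: Sequence[str] | None = None,
) -> EmbeddingMatrix:
    """Encode one meta-path sub-network into a drugs x d embedding.

    The input of drug i is row i of the normalized proximity matrix; the
    same matrix supplies the supervision term.  Deterministic given
    ``cfg.seed`` (single-threaded).
    """
    S = np.asarray(S_p.S, dtype=float)
    n = S.shape[0]
    if ids is None:
        ids = [str(i) for i in range(n)]
    net = SDAE(n, cfg)
    if cfg.layerwise_pretrain:
        net._pretrain(S, ids)
    net.fit(S, S, ids)
    E = net.encode(S)
    emb = EmbeddingMatrix(ids=list(ids), E=E, source=S_p.meta_path).validate()
    emb.training_log = net.log  # type: ignore[attr-defined]
    return emb


def combine_supervision(
    S_list: Mapping[str, MetaPathProximity | np.ndarray],
    alpha_p: Mapping[str, float],
) -> np.ndarray:
    """Weighted average ``S_bar = sum_p alpha(p) S(p) / sum_p alpha(p)``."""
    if set(S_list) != set(alpha_p):
        raise ValueError(
            f"meta-path keys {sorted(S_list)} and weight keys "
            f"{sorted(alpha_p)} differ"
        )
    total = sum(alpha_p.values())
    S_bar = None
    for mp, S in S_list.items():
        M = S.S if isinstance(S, MetaPathProximity) else np.asarray(S, dtype=float)
        term = (alpha_p[mp] / total) * M
        S_bar = term if S_bar is None else S_bar + term
    return S_bar


def train_final_embedding(
    E_list: Mapping[str, EmbeddingMatrix],
    S_list: Mapping[str, MetaPathProximity],
    int_cfg: IntegrationConfig,
) -> EmbeddingMatrix:
    """Fuse per-meta-path embeddings with the secondary semi-supervised SDAE.

    The per-meta-path embeddings are concatenated in canonical meta-path
    order into e_i; the secondary SDAE reconstructs e_i while preserving the
    alpha(p)-weighted average proximity S_bar.
    """
    order = [mp for mp in META_PATHS if mp in E_list]
    ids = E_list[order[0]].ids
    for mp in order:
        if E_list[mp].ids != ids:
            raise ValueError(f"embedding {mp} has a different drug order")
    X = np.hstack([E_list[mp].E for mp in order])
    weights = int_cfg.resolve_weights(order)
    S_bar = combine_supervision({mp: S_list[mp] for mp in order}, weights)

    net = SDAE(X.shape[1], int_cfg.secondary)
    if int_cfg.secondary.layerwise_pretrain:
        net._pretrain(X, ids)
    net.fit(X, S_bar, ids)
    E = net.encode(X)
    emb = EmbeddingMatrix(ids=list(ids), E=E, source="final").validate()
    emb.training_log = net.log  # type: ignore[attr-defined]
    emb.alpha_p = weights  # type: ignore[attr-defined]
    return emb


# ---------------------------------------------------------------------------
# Fusion-weight grid search
# ---------------------------------------------------------------------------


def _cv_auc(
    X: np.ndarray, Y: np.ndarray, folds: int, seed: int
) -> float:
    """Mean micro ROC-AUC of a logistic head over k drug folds."""
    from sklearn.metrics import roc_auc_score

    from .prediction import train_head

    n = X.shape[0]
    if n < folds:
        raise ValueError(f"{n} labeled drugs but {folds} folds requested")
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    order = rng.permutation(n)
    aucs = []
    for f in range(folds):
        test = order[f::folds]
        train = np.setdiff1d(order, test)
        head = train_head(X[train], Y[train])
        scores = head.predict(X[test])
        y_true = Y[test].ravel()
        if y_true.min() == y_true.max():
            continue  # fold carries a single class; skip
        aucs.append(roc_auc_score(y_true, scores.ravel()))
    return float(np.mean(aucs)) if aucs else 0.5


def grid_search_alpha(
    S_list: Mapping[str, MetaPathProximity],
    E_list: Mapping[str, EmbeddingMatrix],
    labels: np.ndarray,
    labeled_drugs: np.ndarray,
    int_cfg: IntegrationConfig,
) -> dict[str, float]:
    """Select fusion weights alpha(p) in {0.1,...,0.5} by cross-validated AUC.

    A downstream logistic head is scored by ``folds``-fold CV on the labeled
    drug subset for each candidate weight map; the default strategy is
    coordinate ascent over the 5-value grid (2 sweeps), with exhaustive
    enumeration available for K <= 3 meta-paths.  Ties keep the
    first-encountered candidate in canonical meta-path order.
    """
    order = [mp for mp in META_PATHS if mp in S_list]
    labels = np.atleast_2d(np.asarray(labels, dtype=float))
    if labels.shape[0] != len(labeled_drugs):
        labels = labels.reshape(len(labeled_drugs), -1)

    def objective(weights: dict[str, float]) -> float:
        cfg = replace(int_cfg, alpha_p=dict(weights), grid_search=False)
        emb = train_final_embedding(E_list, S_list, cfg)
        X = emb.E[labeled_drugs]
        return _cv_auc(X, labels, int_cfg.folds, int_cfg.secondary.seed)

    if len(order) == 1:
        return {order[0]: 0.3}

    if int_cfg.search_mode == "exhaustive":
        if len(order) > 3:
            raise ValueError("exhaustive search is limited to <= 3 meta-paths")
        from itertools import product

        best, best_auc = None, -np.inf
        for combo in product(ALPHA_GRID, repeat=len(order)):
            w = dict(zip(order, combo))
            auc = objective(w)
            if auc > best_auc + 1e-12:
                best, best_auc = w, auc
        return best

    weights = {mp: 0.3 for mp in order}
    best_auc = objective(weights)
    for _ in range(int_cfg.sweeps):
        for mp in order:
            for cand in ALPHA_GRID:
                if cand == weights[mp]:
                    continue
                trial = dict(weights)
                trial[mp] = cand
                auc = objective(trial)
                if auc > best_auc + 1e-12:
                    weights, best_auc = trial, auc
    return weights
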