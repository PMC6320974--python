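"""Drug-level evaluation protocol and ranking metrics.

The protocol holds out *drugs*, not individual labels: a fixed fraction
(default 10%) of drugs form the test set and all of their side-effect and
drug-drug-interaction entries are zeroed in the training network, so
nothing about a test drug's ADRs can leak into proximities, embeddings or
head training.  The remaining drugs split 95/5 into train and validation.
Repetitions re-draw the partition; reports carry per-repetition rows plus
mean/std aggregates of MAP@{20,50,100} and ROC-AUC per task.

AP@K defaults to the standard definition (precision accumulated at the
relevant ranks, normalized by ``min(L, K)``), which keeps MAP in [0, 1]; a
literal mode that sums Precision(k) over *all* k <= K is available via
``as_printed=True`` for comparison.  ROC-AUC is the Mann-Whitney statistic
with midrank tie handling (delegated to scikit-learn; the pairwise
brute-force oracle lives in the tests).
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .embedding import (
    IntegrationConfig,
    SDAEConfig,
    train_final_embedding,
    train_subnetwork_embedding,
)
from .hin_core import DrugHIN, META_PATHS
from .prediction import TaskDataset, negative_sample, predict_task, train_head, training_features
from .proximity import DEFAULT_MU, build_subnetworks

__all__ = [
    "SplitPlan",
    "ProtocolConfig",
    "make_split",
    "scrub_hin",
    "average_precision_at_k",
    "map_at_k",
    "roc_auc",
    "embed_hin",
    "run_protocol",
]


@dataclass
class SplitPlan:
    """One drug-level partition: test / train / validation, seeded."""

    test_drugs: list[str]
    train_drugs: list[str]
    validation_drugs: list[str]
    repetition: int = 0
    seed: int = 0

    def validate(self, drugs: Sequence[str]) -> "SplitPlan":
        t, tr, v = map(set, (self.test_drugs, self.train_drugs, self.validation_drugs))
        if t & tr or t & v or tr & v:
            raise ValueError("split folds overlap")
        if t | tr | v != set(drugs):
            raise ValueError("split folds do not cover the drug registry")
        return self

    def fold_of(self) -> dict[str, str]:
        out = {d: "test" for d in self.test_drugs}
        out.update({d: "train" for d in self.train_drugs})
        out.update({d: "validation" for d in self.validation_drugs})
        return out


def make_split(
    drugs: Sequence[str],
    fractions: tuple[float, float] = (0.10, 0.95),
    seed: int = 0,
    repetition: int = 0,
) -> SplitPlan:
    """Two-stage seeded partition: ``fractions = (test, train-of-remainder)``.

    Sizes use half-up rounding: ``n_test = floor(f_test * n + 0.5)``, then
    the remainder splits with ``n_val = floor((1 - f_train) * rem + 0.5)``.
    For 100 drugs at (0.10, 0.95) this gives 10 / 85 / 5.
    """
    f_test, f_train = fractions
    if not (0 < f_test < 1 and 0 < f_train < 1):
        raise ValueError("fractions must lie strictly between 0 and 1")
    n = len(drugs)
    n_test = int(f_test * n + 0.5)
    rem = n - n_test
    n_val = int((1.0 - f_train) * rem + 0.5)
    if n_test < 1 or n_val < 1 or rem - n_val < 1:
        raise ValueError(f"{n} drugs are too few for a {fractions} split")
    rng = np.random.default_rng([seed & 0x7FFFFFFF, repetition])
    order = rng.permutation(n)
    test = [drugs[i] for i in order[:n_test]]
    val = [drugs[i] for i in order[n_test : n_test + n_val]]
    train = [drugs[i] for i in order[n_test + n_val :]]
    return SplitPlan(
        test_drugs=test, train_drugs=train, validation_drugs=val,
        repetition=repetition, seed=seed,
    ).validate(drugs)


def scrub_hin(hin: DrugHIN, test_drugs: Sequence[str]) -> DrugHIN:
    """Zero every A_dd row/column and M_dse row of the test drugs.

    This is the label-hiding step of the protocol: the training network
    must not contain the held-out drugs' interactions or side effects.
    """
    out = hin.copy()
    idx = [out.drugs.index(d) for d in test_drugs]
    A = out.A_dd.tolil()
    M = out.M_dse.tolil()
    for i in idx:
        A[i, :] = 0
        A[:, i] = 0
        M[i, :] = 0
    out.A_dd = A.tocsr()
    out.A_dd.eliminate_zeros()
    out.M_dse = M.tocsr()
    out.M_dse.eliminate_zeros()
    return out.validate()


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def average_precision_at_k(
    ranking: Sequence,
    relevant_set: set,
    K: int,
    as_printed: bool = False,
) -> float:
    """AP@K of one ranked list against a relevance set.

    Default: ``sum_{k<=K} Precision(k) * rel(k) / min(L, K)`` — precision is
    accumulated only at ranks holding a relevant item, so the value lies in
    [0, 1].  ``as_printed=True`` accumulates Precision(k) at *every* rank
    k <= K (which can exceed 1, e.g. L=1, K=3 on a perfect ranking gives
    ~1.83).  Returns 0 with a warning when the relevance set is empty.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if len(set(ranking)) != len(ranking):
        raise ValueError("ranking contains duplicate items")
    L = len(relevant_set)
    if L == 0:
        warnings.warn("empty relevance set; AP@K defined as 0")
        return 0.0
    hits = 0
    acc = 0.0
    for k, item in enumerate(ranking[:K], start=1):
        if item in relevant_set:
            hits += 1
        prec = hits / k
        if as_printed:
            acc += prec
        elif item in relevant_set:
            acc += prec
    return acc / min(L, K)


def map_at_k(
    rankings: Sequence[Sequence],
    relevants: Sequence[set],
    K: int,
    as_printed: bool = False,
) -> float:
    """Unweighted mean AP@K over instances; empty-relevance instances are
    excluded from the mean."""
    if len(rankings) != len(relevants):
        raise ValueError("rankings and relevance sets differ in length")
    if not rankings:
        raise ValueError("empty test set")
    vals = [
        average_precision_at_k(r, rel, K, as_printed)
        for r, rel in zip(rankings, relevants)
        if len(rel) > 0
    ]
    return float(np.mean(vals)) if vals else 0.0


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney ROC-AUC with midrank tie handling; needs both classes."""
    labels = np.asarray(labels).ravel()
    scores = np.asarray(scores).ravel()
    if labels.min() == labels.max():
        raise ValueError("ROC-AUC undefined for single-class labels")
    return float(roc_auc_score(labels, scores))


def _rank_items(score_row: np.ndarray) -> list[int]:
    # stable sort: ties broken by ascending item index
    return list(np.argsort(-score_row, kind="stable"))


# ---------------------------------------------------------------------------
# Full protocol
# ---------------------------------------------------------------------------


@dataclass
class ProtocolConfig:
    """Everything one repeated evaluation run needs."""

    repetitions: int = 5
    fractions: tuple[float, float] = (0.10, 0.95)
    mu: float = DEFAULT_MU
    kernel_method: str = "solve"
    meta_paths: tuple[str, ...] = META_PATHS
    sdae: SDAEConfig = field(default_factory=SDAEConfig)
    integration: IntegrationConfig = field(default_factory=IntegrationConfig)
    tasks: tuple[str, ...] = ("single_drug_se", "ddi_occurrence", "ddi_type")
    neg_ratio: float = 1.0
    lam: float = 1.0
    ks: tuple[int, ...] = (20, 50, 100)
    seed: int = 0
    variant: str = "full"


def _stage_seed(master: int, label: str, repetition: int = 0) -> int:
    """Deterministic per-stage seed fan-out (documented hash)."""
    ss = np.random.SeedSequence(
        [master & 0x7FFFFFFF, zlib.crc32(label.encode()), repetition]
    )
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def embed_hin(
    hin: DrugHIN,
    cfg: ProtocolConfig,
    repetition: int = 0,
):
    """Proximities -> per-meta-path SDAEs -> secondary fusion; returns
    (final EmbeddingMatrix, proximity dict, per-path embedding dict)."""
    prox = build_subnetworks(
        hin, mu=cfg.mu, method=cfg.kernel_method, meta_paths=cfg.meta_paths
    )
    E_list = {}
    for mp, S_p in prox.items():
        sub_cfg = replace(cfg.sdae, seed=_stage_seed(cfg.seed, f"sdae:{mp}", repetition))
        E_list[mp] = train_subnetwork_embedding(S_p, sub_cfg, ids=hin.drugs)
    int_cfg = replace(
        cfg.integration,
        secondary=replace(
            cfg.integration.secondary,
            seed=_stage_seed(cfg.seed, "sdae:final", repetition),
        ),
    )
    eF = train_final_embedding(E_list, prox, int_cfg)
    return eF, prox, E_list


def _task1_metrics(eF, hin_train, hin_full, plan, cfg):
    ids = eF.ids
    idx = {d: k for k, d in enumerate(ids)}
    Y_train_src = np.asarray(hin_train.M_dse.todense())
    Y_true = np.asarray(hin_full.M_dse.todense())
    train_idx = [idx[d] for d in plan.train_drugs]
    test_idx = [idx[d] for d in plan.test_drugs]
    head = train_head(eF.E[train_idx], Y_train_src[train_idx], lam=cfg.lam)
    scores = head.predict(eF.E[test_idx])
    rankings = [_rank_items(row) for row in scores]
    relevants = [set(np.flatnonzero(Y_true[i])) for i in test_idx]
    out = {
        f"MAP@{K}": map_at_k(rankings, relevants, K) for K in cfg.ks
    }
    out["ROC_AUC"] = roc_auc(scores.ravel(), Y_true[test_idx].ravel())
    return out


def _task2_metrics(eF, hin_train, hin_full, plan, cfg, rng):
    ids = eF.ids
    idx = {d: k for k, d in enumerate(ids)}
    A_full = np.asarray(hin_full.A_dd.todense())
    train_drugs = sorted(plan.train_drugs, key=idx.get)
    pos, universe = [], []
    for a in range(len(train_drugs)):
        for b in range(a + 1, len(train_drugs)):
            da, db = train_drugs[a], train_drugs[b]
            universe.append((da, db))
            if A_full[idx[da], idx[db]] > 0:
                pos.append((da, db))
    neg = negative_sample(pos, universe, cfg.neg_ratio, rng)
    insts = pos + neg
    labels = np.concatenate([np.ones(len(pos)), np.zeros(len(neg))]).reshape(-1, 1)
    X, Y = training_features(eF, "ddi_occurrence", insts, labels)
    head = train_head(X, Y, lam=cfg.lam)

    rankings, relevants, flat_scores, flat_labels = [], [], [], []
    for t in plan.test_drugs:
        cand = train_drugs
        pairs = [(t, c) for c in cand]
        sc = predict_task(head, eF, pairs, "ddi_occurrence").ravel()
        lab = np.asarray([A_full[idx[t], idx[c]] for c in cand])
        order = _rank_items(sc)
        rankings.append([cand[k] for k in order])
        relevants.append({c for c, l in zip(cand, lab) if l > 0})
        flat_scores.append(sc)
        flat_labels.append(lab)
    out = {f"MAP@{K}": map_at_k(rankings, relevants, K) for K in cfg.ks}
    out["ROC_AUC"] = roc_auc(np.concatenate(flat_scores), np.concatenate(flat_labels))
    return out


def _task3_metrics(eF, hin_full, plan, cfg, type_lookup, n_types, rng):
    ids = eF.ids
    idx = {d: k for k, d in enumerate(ids)}
    A_full = np.asarray(hin_full.A_dd.todense())
    train_set = set(plan.train_drugs)
    pos_insts, pos_labels, universe = [], [], []
    for pair, vec in type_lookup.items():
        a, b = tuple(pair)
        if a in train_set and b in train_set:
            pos_insts.append((a, b))
            pos_labels.append(vec)
    for a in sorted(train_set, key=idx.get):
        for b in sorted(train_set, key=idx.get):
            if idx[a] < idx[b] and A_full[idx[a], idx[b]] == 0:
                universe.append((a, b))
    n_neg = min(int(cfg.neg_ratio * len(pos_insts)), len(universe))
    neg_idx = rng.choice(len(universe), size=n_neg, replace=False) if n_neg else []
    neg_insts = [universe[k] for k in sorted(neg_idx)]
    insts = pos_insts + neg_insts
    labels = np.vstack(
        [np.asarray(pos_labels), np.zeros((len(neg_insts), n_types))]
    ) if pos_insts else np.zeros((0, n_types))
    X, Y = training_features(eF, "ddi_type", insts, labels)
    head = train_head(X, Y, lam=cfg.lam)

    test_pairs, test_vecs = [], []
    for pair, vec in type_lookup.items():
        a, b = tuple(pair)
        fold = {plan.fold_of().get(a), plan.fold_of().get(b)}
        if "test" in fold:
            test_pairs.append((a, b))
            test_vecs.append(vec)
    if not test_pairs:
        return {f"MAP@{K}": float("nan") for K in cfg.ks} | {"ROC_AUC": float("nan")}
    scores = predict_task(head, eF, test_pairs, "ddi_type")
    rankings = [_rank_items(row) for row in scores]
    relevants = [set(np.flatnonzero(v)) for v in test_vecs]
    out = {f"MAP@{K}": map_at_k(rankings, relevants, K) for K in cfg.ks}
    truth = np.asarray(test_vecs)
    out["ROC_AUC"] = roc_auc(scores.ravel(), truth.ravel())
    return out


def run_protocol(
    hin: DrugHIN,
    datasets: Mapping[str, TaskDataset],
    cfg: ProtocolConfig,
) -> dict:
    """Repeat split -> scrub -> proximities -> embed -> heads -> metrics.

    ``datasets['ddi_type']`` supplies the typed DDI labels (occurrence is
    read from the HIN itself).  Returns a report dict with one row per
    (task, repetition) and mean/std aggregates.
    """
    type_lookup = {}
    n_types = len(hin.ses)
    if "ddi_type" in cfg.tasks and "ddi_type" in datasets:
        ds3 = datasets["ddi_type"]
        type_lookup = {
            frozenset(p): np.asarray(v)
            for p, v in zip(ds3.instances, ds3.labels)
        }
        n_types = ds3.labels.shape[1]

    rows = []
    for rep in range(cfg.repetitions):
        plan = make_split(
            hin.drugs, cfg.fractions, seed=_stage_seed(cfg.seed, "split"), repetition=rep
        )
        hin_train = scrub_hin(hin, plan.test_drugs)
        eF, _, _ = embed_hin(hin_train, cfg, repetition=rep)
        rng = np.random.default_rng(_stage_seed(cfg.seed, "negatives", rep))
        for task in cfg.tasks:
            if task == "single_drug_se":
                metrics = _task1_metrics(eF, hin_train, hin, plan, cfg)
            elif task == "ddi_occurrence":
                metrics = _task2_metrics(eF, hin_train, hin, plan, cfg, rng)
            elif task == "ddi_type":
                metrics = _task3_metrics(
                    eF, hin, plan, cfg, type_lookup, n_types, rng
                )
            else:
                raise ValueError(f"unknown task {task!r}")
            rows.append(
                {"task": task, "variant": cfg.variant, "repetition": rep, **metrics}
            )

    aggregates = []
    for task in cfg.tasks:
        vals = [r for r in rows if r["task"] == task]
        agg = {"task": task, "variant": cfg.variant, "repetition": "mean±std"}
        for key in [f"MAP@{K}" for K in cfg.ks] + ["ROC_AUC"]:
            arr = np.asarray([v[key] for v in vals], dtype=float)
            agg[key] = float(np.nanmean(arr))
            agg[f"{key}_std"] = float(np.nanstd(arr))
        aggregates.append(agg)
    return {"variant": cfg.variant, "rows": rows, "aggregates": aggregates}
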