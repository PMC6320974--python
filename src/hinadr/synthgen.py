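"""Synthetic drug-HIN generator with planted, exactly recoverable structure.

Real integrated pharmacovigilance datasets (TWOSIDES-style DDI tables,
PPI graphs, substructure fingerprints, indication and side-effect lists)
are licence-encumbered and noisy; this module emulates their *schema* —
five node types, six binary relations — at configurable scale with two
planted signals that make every pipeline stage testable:

* **Drug clusters.**  Drugs belong to one of ``n_clusters`` groups; each
  group has prototype chemical-fingerprint, target-set and disease-set
  vectors, and per-drug vectors are prototypes with independent bit flips.
  Clusters also drive drug-drug interactions (within-cluster pairs interact
  at an elevated rate over the background).
* **Mechanistic side effects.**  The PPI graph is a stochastic block model
  whose communities align with cluster target sets.  Each side effect is
  anchored to one protein, and a drug (noise-free) carries the side effect
  iff one of its targets lies within ``propagation_hops`` PPI hops of the
  anchor.  Hop-bounded reachability is exactly computable by breadth-first
  search, giving an independent oracle for the target-propagation
  machinery: with ``propagation_hops >= 2`` the side-effect labels are a
  function of multi-hop reachability — the signal the DP(n)D meta-path is
  designed to capture — so ablating target propagation measurably hurts
  side-effect prediction.

DDI event types reuse the side-effect mechanism on the union of a pair's
targets.  Everything is driven by a single seed and reproducible bit for
bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra

from .hin_core import DrugHIN
from .prediction import TaskDataset, negative_sample

__all__ = ["SynthConfig", "SynthTruth", "generate_hin", "fixture_small",
           "FIXTURE_SEED"]

#: Seed regenerating the checked-in small fixture bit-identically.
FIXTURE_SEED = 30711


@dataclass
class SynthConfig:
    n_drugs: int = 120
    n_chems: int = 60
    n_prots: int = 150
    n_ses: int = 40
    n_dis: int = 30
    n_clusters: int = 4
    bit_flip_noise: float = 0.1
    targets_per_drug: int = 3
    ppi_within_p: float = 0.08
    ppi_between_p: float = 0.005
    propagation_hops: int = 2
    se_noise: float = 0.05
    ddi_base_rate: float = 0.05
    ddi_within_rate: float = 0.35
    neg_ratio: float = 1.0
    seed: int = 0

    def validate(self) -> "SynthConfig":
        for name in ("bit_flip_noise", "ppi_within_p", "ppi_between_p",
                     "se_noise", "ddi_base_rate", "ddi_within_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability, got {v}")
        for name in ("n_drugs", "n_chems", "n_prots", "n_ses", "n_dis",
                     "n_clusters", "targets_per_drug"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_clusters > self.n_drugs:
            raise ValueError("more clusters than drugs")
        if self.targets_per_drug > self.n_prots:
            raise ValueError("targets_per_drug exceeds the protein count")
        if self.propagation_hops < 1:
            raise ValueError("propagation_hops must be >= 1")
        return self


@dataclass
class SynthTruth:
    """Noise-free ground truth behind one synthetic HIN."""

    cluster_of: dict[str, int]
    se_mechanism: dict[str, str]  # side effect -> anchor protein
    planted_labels: dict[str, np.ndarray]  # noise-free dse / dd / ddi_types

    def cluster_array(self, drugs: list[str]) -> np.ndarray:
        return np.asarray([self.cluster_of[d] for d in drugs])


def _flip_bits(proto: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    if p == 0.0:
        return proto.copy()
    flips = rng.random(proto.shape) < p
    return np.where(flips, 1 - proto, proto)


def _sym_bernoulli(n: int, probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Symmetric zero-diagonal 0/1 matrix with entrywise edge probabilities."""
    upper = rng.random((n, n)) < probs
    A = np.triu(upper, k=1)
    return (A + A.T).astype(float)


def generate_hin(cfg: SynthConfig) -> tuple[DrugHIN, SynthTruth, dict[str, TaskDataset]]:
    """Generate a synthetic drug HIN plus ground truth and task datasets."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed & 0x7FFFFFFF)

    drugs = [f"D{i:03d}" for i in range(cfg.n_drugs)]
    chems = [f"C{i:03d}" for i in range(cfg.n_chems)]
    prots = [f"P{i:03d}" for i in range(cfg.n_prots)]
    ses = [f"SE{i:03d}" for i in range(cfg.n_ses)]
    dis = [f"DI{i:03d}" for i in range(cfg.n_dis)]

    # -- clusters and protein communities ---------------------------------
    cluster = np.sort(np.arange(cfg.n_drugs) % cfg.n_clusters)
    community = np.arange(cfg.n_prots) % cfg.n_clusters  # protein -> block

    chem_proto = (rng.random((cfg.n_clusters, cfg.n_chems)) < 0.3).astype(float)
    dis_proto = (rng.random((cfg.n_clusters, cfg.n_dis)) < 0.3).astype(float)

    M_dc = np.stack(
        [_flip_bits(chem_proto[c], cfg.bit_flip_noise, rng) for c in cluster]
    )
    M_ddi = np.stack(
        [_flip_bits(dis_proto[c], cfg.bit_flip_noise, rng) for c in cluster]
    )

    # -- targets: drawn from the drug's community, occasionally rewired ----
    M_dp = np.zeros((cfg.n_drugs, cfg.n_prots))
    for i, c in enumerate(cluster):
        pool = np.flatnonzero(community == c)
        k = min(cfg.targets_per_drug, len(pool))
        targets = rng.choice(pool, size=k, replace=False)
        for t in targets:
            if rng.random() < cfg.bit_flip_noise:
                t = rng.integers(cfg.n_prots)
            M_dp[i, t] = 1.0

    # -- PPI: stochastic block model aligned with the communities ----------
    probs = np.where(
        community[:, None] == community[None, :], cfg.ppi_within_p, cfg.ppi_between_p
    )
    A_pp = _sym_bernoulli(cfg.n_prots, probs, rng)

    # -- side effects planted by hop-bounded reachability ------------------
    anchors = rng.integers(cfg.n_prots, size=cfg.n_ses)
    dist = dijkstra(sp.csr_matrix(A_pp), unweighted=True, indices=anchors,
                    limit=cfg.propagation_hops)
    reach = dist <= cfg.propagation_hops  # (n_ses, n_prots)
    planted_dse = (M_dp @ reach.T.astype(float) > 0).astype(float)
    flips = rng.random(planted_dse.shape) < cfg.se_noise
    M_dse = np.where(flips, 1 - planted_dse, planted_dse)

    # -- drug-drug interactions: cluster-assortative ------------------------
    dd_probs = np.where(
        cluster[:, None] == cluster[None, :], cfg.ddi_within_rate, cfg.ddi_base_rate
    )
    A_dd = _sym_bernoulli(cfg.n_drugs, dd_probs, rng)

    # -- DDI event types: the pair's pooled targets, same mechanism ---------
    pairs = [(i, j) for i in range(cfg.n_drugs) for j in range(i + 1, cfg.n_drugs)
             if A_dd[i, j] > 0]
    ddi_types = np.zeros((len(pairs), cfg.n_ses))
    for k, (i, j) in enumerate(pairs):
        pooled = np.maximum(M_dp[i], M_dp[j])
        ddi_types[k] = (pooled @ reach.T.astype(float) > 0).astype(float)
    type_flips = rng.random(ddi_types.shape) < cfg.se_noise
    ddi_types_obs = np.where(type_flips, 1 - ddi_types, ddi_types)

    hin = DrugHIN(
        drugs=drugs, chems=chems, prots=prots, ses=ses, dis=dis,
        A_dd=sp.csr_matrix(A_dd),
        M_dc=sp.csr_matrix(M_dc),
        M_dp=sp.csr_matrix(M_dp),
        M_dse=sp.csr_matrix(M_dse),
        M_ddi=sp.csr_matrix(M_ddi),
        A_pp=sp.csr_matrix(A_pp),
    ).validate()

    truth = SynthTruth(
        cluster_of={d: int(c) for d, c in zip(drugs, cluster)},
        se_mechanism={ses[s]: prots[anchors[s]] for s in range(cfg.n_ses)},
        planted_labels={
            "dse": planted_dse,
            "dd": A_dd.copy(),
            "ddi_types": ddi_types,
        },
    )

    # -- task datasets ------------------------------------------------------
    ds1 = TaskDataset(
        task="single_drug_se", instances=list(drugs), labels=M_dse.copy()
    ).validate(drugs)

    pos_pairs = [(drugs[i], drugs[j]) for i, j in pairs]
    universe = [
        (drugs[i], drugs[j])
        for i in range(cfg.n_drugs)
        for j in range(i + 1, cfg.n_drugs)
    ]
    neg_rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, 0x5E6])
    neg_pairs = negative_sample(pos_pairs, universe, cfg.neg_ratio, neg_rng)
    ds2 = TaskDataset(
        task="ddi_occurrence",
        instances=pos_pairs + neg_pairs,
        labels=np.concatenate(
            [np.ones(len(pos_pairs)), np.zeros(len(neg_pairs))]
        ).reshape(-1, 1),
    ).validate(drugs)

    ds3 = TaskDataset(
        task="ddi_type", instances=list(pos_pairs), labels=ddi_types_obs
    ).validate(drugs)

    datasets = {"single_drug_se": ds1, "ddi_occurrence": ds2, "ddi_type": ds3}
    return hin, truth, datasets


def fixture_small() -> tuple[DrugHIN, SynthTruth]:
    """Fixed 12-drug / 3-cluster / 20-protein instance for hand checks.

    Noise-free (no bit flips, no label noise), dense enough that every
    meta-path has path instances; regenerated bit-identically from
    :data:`FIXTURE_SEED`.
    """
    cfg = SynthConfig(
        n_drugs=12, n_chems=15, n_prots=20, n_ses=8, n_dis=6,
        n_clusters=3, bit_flip_noise=0.0, targets_per_drug=2,
        ppi_within_p=0.5, ppi_between_p=0.05, propagation_hops=2,
        se_noise=0.0, ddi_base_rate=0.1, ddi_within_rate=0.6,
        seed=FIXTURE_SEED,
    )
    hin, truth, _ = generate_hin(cfg)
    return hin, truth
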