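"""Meta-path-based drug-drug proximities over the drug HIN.

Six meta-paths, all starting and ending at drugs, each yielding a symmetric
drugs x drugs proximity matrix used as supervision for embedding:

* ``DD`` — Jaccard similarity of drug-drug interaction neighbourhoods.
* ``DCD``, ``DPD``, ``DDID``, ``DSED`` — PathSim over the shared-attribute
  bipartite relations (chemical substructure, target protein, disease,
  side effect): twice the cross path-instance count over the sum of the two
  self path-instance counts.
* ``DPnD`` (n >= 2) — target propagation: drug targets diffuse through the
  PPI graph under a damped random walk, and two drugs are proximate when
  the targets of one reach the targets of the other.  The walk kernel is
  the Katz series sum_{m>=1} (mu P)^m = (I - mu P)^{-1} - I over the
  row-stochastic PPI transition matrix P, computed by sparse linear solve
  (a truncated-series backend is kept as an independent cross-check).

Jaccard and PathSim are already in [0, 1]; the unbounded propagation
proximity is min-max scaled so all meta-paths share a supervision scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .hin_core import DrugHIN, MetaPathProximity, META_PATHS

__all__ = [
    "PropagationKernel",
    "jaccard_dd",
    "pathsim",
    "ppi_transition",
    "katz_kernel",
    "target_propagation_proximity",
    "build_subnetworks",
    "DEFAULT_MU",
]

#: Damping factor of the PPI random walk; 0.98 is the conventional choice.
DEFAULT_MU = 0.98

_PATHSIM_RELATION = {"DCD": "M_dc", "DPD": "M_dp", "DDID": "M_ddi", "DSED": "M_dse"}


@dataclass
class PropagationKernel:
    """Katz walk kernel ``K = (I - mu*P)^{-1} - I`` on the PPI graph.

    ``P`` is the degree-normalized transition matrix (rows of isolated
    proteins are identically zero).  With ``method='series'`` the kernel is
    the truncated sum ``sum_{m=1}^{series_terms} (mu P)^m``.
    """

    P: sp.csr_matrix
    mu: float
    K: np.ndarray
    method: str = "solve"
    series_terms: int | None = None

    @property
    def n_prots(self) -> int:
        return self.P.shape[0]


def jaccard_dd(hin: DrugHIN) -> MetaPathProximity:
    """Jaccard proximity of interaction neighbourhoods (meta-path DD).

    ``S[i, j] = |D_i & D_j| / |D_i | D_j|`` over the binary interaction
    vectors (rows of ``A_dd``); 0 when both vectors are empty.
    """
    A = sp.csr_matrix(hin.A_dd, dtype=float)
    inter = np.asarray((A @ A.T).todense())
    deg = np.asarray(A.sum(axis=1)).ravel()
    union = deg[:, None] + deg[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        S = np.where(union > 0, inter / np.maximum(union, 1e-300), 0.0)
    return MetaPathProximity("DD", S, normalized=True).validate()


def pathsim(M: sp.spmatrix, meta_path: str = "DCD") -> MetaPathProximity:
    """PathSim over a drugs x attribute incidence matrix.

    With path-instance counts ``C = M M^T``:
    ``S[i, j] = 2 C[i, j] / (C[i, i] + C[j, j])``, and 0 when the
    denominator vanishes (both drugs isolated in this relation).  The
    diagonal is 1 for every drug with at least one attribute.
    """
    M = sp.csr_matrix(M, dtype=float)
    C = np.asarray((M @ M.T).todense())
    d = np.diag(C)
    denom = d[:, None] + d[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        S = np.where(denom > 0, 2.0 * C / np.maximum(denom, 1e-300), 0.0)
    return MetaPathProximity(meta_path, S, normalized=True).validate()


def ppi_transition(hin: DrugHIN) -> sp.csr_matrix:
    """Row-stochastic random-walk matrix of the undirected PPI graph.

    ``P[u, v] = A_pp[u, v] / degree(u)``; isolated proteins get an all-zero
    row (the walker has nowhere to go).
    """
    A = sp.csr_matrix(hin.A_pp, dtype=float)
    deg = np.asarray(A.sum(axis=1)).ravel()
    inv = np.zeros_like(deg)
    nz = deg > 0
    inv[nz] = 1.0 / deg[nz]
    return sp.diags(inv) @ A


def katz_kernel(
    P: sp.spmatrix,
    mu: float = DEFAULT_MU,
    method: str = "solve",
    series_terms: int = 200,
    needed_cols: np.ndarray | None = None,
) -> PropagationKernel:
    """Compute the Katz walk kernel ``(I - mu*P)^{-1} - I``.

    method='solve'
        Sparse LU solve of ``(I - mu*P) X = I``; when ``needed_cols`` is
        given only those columns of the kernel are materialized (columns
        not requested are left at zero), which is what the drug-target
        propagation actually consumes.
    method='series'
        Truncated geometric series ``sum_{m=1}^{series_terms} (mu P)^m``;
        slower, but an independent construction used for cross-checks.
    """
    if not (0.0 <= mu < 1.0):
        raise ValueError(f"damping factor mu must be in [0, 1), got {mu}")
    P = sp.csr_matrix(P, dtype=float)
    n = P.shape[0]
    if method == "solve":
        K = np.zeros((n, n))
        if mu > 0.0:
            A = (sp.identity(n, format="csc") - mu * P.tocsc()).tocsc()
            lu = spla.splu(A)
            cols = np.arange(n) if needed_cols is None else np.unique(needed_cols)
            if len(cols):
                rhs = np.zeros((n, len(cols)))
                rhs[cols, np.arange(len(cols))] = 1.0
                X = lu.solve(rhs)
                K[:, cols] = X
                K[cols, cols] -= 1.0  # drop the zero-hop term
        return PropagationKernel(P=P, mu=mu, K=K, method="solve")
    if method == "series":
        K = np.zeros((n, n))
        term = np.eye(n)
        muP = (mu * P).toarray()
        for _ in range(series_terms):
            term = term @ muP
            K += term
        return PropagationKernel(
            P=P, mu=mu, K=K, method="series", series_terms=series_terms
        )
    raise ValueError(f"unknown kernel method {method!r}")


def _minmax(S: np.ndarray) -> np.ndarray:
    lo, hi = S.min(), S.max()
    if hi - lo <= 0:
        return np.zeros_like(S)
    return (S - lo) / (hi - lo)


def target_propagation_proximity(
    hin: DrugHIN, kernel: PropagationKernel, normalize: bool = True
) -> MetaPathProximity:
    """Drug-drug proximity along the target-propagation meta-path DP(n)D.

    Raw proximity ``R = M_dp K M_dp^T``: each entry accumulates damped walk
    probability from every target of drug i to every target of drug j
    through at least one PPI hop.  ``R`` inherits the asymmetry of the
    row-normalized walk, so the returned matrix is the symmetrized
    ``(R + R^T) / 2``, min-max scaled to [0, 1] when ``normalize``.  Drugs
    with no targets have an all-zero row and column.
    """
    if kernel.n_prots != len(hin.prots):
        raise ValueError(
            f"kernel over {kernel.n_prots} proteins but HIN registers "
            f"{len(hin.prots)}"
        )
    D = sp.csr_matrix(hin.M_dp, dtype=float).toarray()
    R = D @ kernel.K @ D.T
    S = 0.5 * (R + R.T)
    if normalize:
        S = _minmax(S)
    return MetaPathProximity("DPnD", S, normalized=normalize).validate()


def build_subnetworks(
    hin: DrugHIN,
    mu: float = DEFAULT_MU,
    method: str = "solve",
    series_terms: int = 200,
    meta_paths: tuple[str, ...] = META_PATHS,
) -> dict[str, MetaPathProximity]:
    """Assemble the per-meta-path proximity sub-networks.

    Returns one normalized symmetric proximity per requested meta-path, in
    canonical order.  Dropping ``DPnD`` from ``meta_paths`` yields the
    no-target-propagation ablation variant.
    """
    out: dict[str, MetaPathProximity] = {}
    for mp in meta_paths:
        if mp == "DD":
            out[mp] = jaccard_dd(hin)
        elif mp in _PATHSIM_RELATION:
            out[mp] = pathsim(getattr(hin, _PATHSIM_RELATION[mp]), mp)
        elif mp == "DPnD":
            P = ppi_transition(hin)
            needed = np.unique(sp.coo_matrix(hin.M_dp).col)
            kern = katz_kernel(
                P, mu=mu, method=method, series_terms=series_terms,
                needed_cols=needed,
            )
            out[mp] = target_propagation_proximity(hin, kern)
        else:
            raise ValueError(f"unknown meta-path {mp!r}")
    return out
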