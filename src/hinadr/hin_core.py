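"""Core containers and I/O for the drug heterogeneous information network.

The drug HIN connects five object types — drugs, chemical substructures,
target proteins, side effects and diseases — through six binary relations:
drug-drug interactions (occurrence only; interaction types are handled at
the prediction stage, not here), drug-chemical, drug-protein, drug-side
effect, drug-disease, and protein-protein interactions.  :class:`DrugHIN`
is the single source of truth for network structure; everything downstream
(proximities, embeddings, task datasets) indexes into its registries.

On-disk formats are deliberately boring: one-ID-per-line node registries,
two-column TSV edge lists (``#`` comments allowed) or MatrixMarket
coordinate files for the relations, and a YAML config naming them all.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import scipy.sparse as sp
import yaml

__all__ = [
    "META_PATHS",
    "DrugHIN",
    "MetaPathProximity",
    "EmbeddingMatrix",
    "HINValidationError",
    "read_hin",
    "write_hin",
    "read_embeddings",
    "write_embeddings",
]

#: Canonical meta-path order used everywhere (fusion weights, reports, ...).
META_PATHS = ("DD", "DCD", "DPD", "DPnD", "DDID", "DSED")

#: Relation keys expected in a HIN config, mapped to (row registry, col registry).
_RELATIONS = {
    "dd": ("drugs", "drugs"),
    "dc": ("drugs", "chems"),
    "dp": ("drugs", "prots"),
    "dse": ("drugs", "ses"),
    "ddi": ("drugs", "dis"),
    "pp": ("prots", "prots"),
}

_NODE_KEYS = ("drugs", "chems", "prots", "ses", "dis")


class HINValidationError(ValueError):
    """An invariant of a HIN container was violated."""


def _check_unique(ids: Sequence[str], name: str) -> None:
    if len(set(ids)) != len(ids):
        raise HINValidationError(f"duplicate IDs in {name} registry")


def _check_binary(M: sp.spmatrix, name: str) -> None:
    M = sp.csr_matrix(M)
    M.eliminate_zeros()
    if M.nnz and not np.all(M.data == 1):
        raise HINValidationError(f"{name} must be binary {{0,1}}")


def _check_symmetric_zero_diag(A: sp.spmatrix, name: str) -> None:
    if (A != A.T).nnz != 0:
        raise HINValidationError(f"{name} must be symmetric")
    if A.diagonal().any():
        raise HINValidationError(f"{name} must have zero diagonal")


@dataclass
class DrugHIN:
    """The six typed binary relation matrices plus node-ID registries.

    ``A_dd`` collapses typed drug-drug interactions to occurrence.  Proteins
    that appear only as drug targets (no PPI edge) are retained as isolated
    nodes of ``A_pp``, so every column of ``M_dp`` indexes the same protein
    registry the PPI graph lives on.
    """

    drugs: list[str]
    chems: list[str]
    prots: list[str]
    ses: list[str]
    dis: list[str]
    A_dd: sp.csr_matrix
    M_dc: sp.csr_matrix
    M_dp: sp.csr_matrix
    M_dse: sp.csr_matrix
    M_ddi: sp.csr_matrix
    A_pp: sp.csr_matrix

    @property
    def n_drugs(self) -> int:
        return len(self.drugs)

    def drug_index(self, drug_id: str) -> int:
        try:
            return self.drugs.index(drug_id)
        except ValueError:
            raise KeyError(f"unknown drug ID {drug_id!r}") from None

    def validate(self) -> "DrugHIN":
        """Raise :class:`HINValidationError` on any broken invariant."""
        for key in _NODE_KEYS:
            _check_unique(getattr(self, key), key)
        shapes = {
            "A_dd": (self.n_drugs, self.n_drugs),
            "M_dc": (self.n_drugs, len(self.chems)),
            "M_dp": (self.n_drugs, len(self.prots)),
            "M_dse": (self.n_drugs, len(self.ses)),
            "M_ddi": (self.n_drugs, len(self.dis)),
            "A_pp": (len(self.prots), len(self.prots)),
        }
        for name, want in shapes.items():
            M = getattr(self, name)
            if M.shape != want:
                raise HINValidationError(
                    f"{name} has shape {M.shape}, registries imply {want}"
                )
            _check_binary(M, name)
        _check_symmetric_zero_diag(self.A_dd, "A_dd")
        _check_symmetric_zero_diag(self.A_pp, "A_pp")
        return self

    def copy(self) -> "DrugHIN":
        return replace(
            self,
            drugs=list(self.drugs),
            chems=list(self.chems),
            prots=list(self.prots),
            ses=list(self.ses),
            dis=list(self.dis),
            A_dd=self.A_dd.copy(),
            M_dc=self.M_dc.copy(),
            M_dp=self.M_dp.copy(),
            M_dse=self.M_dse.copy(),
            M_ddi=self.M_ddi.copy(),
            A_pp=self.A_pp.copy(),
        )


@dataclass
class MetaPathProximity:
    """A symmetric drugs x drugs proximity matrix tagged with its meta-path.

    Dense storage: the drug axis is the small one.  After normalization
    entries lie in [0, 1]; PathSim diagonals are 1 for every drug with at
    least one path instance and 0 otherwise.
    """

    meta_path: str
    S: np.ndarray
    normalized: bool = False

    def validate(self) -> "MetaPathProximity":
        if self.meta_path not in META_PATHS:
            raise HINValidationError(f"unknown meta-path {self.meta_path!r}")
        S = self.S
        if S.ndim != 2 or S.shape[0] != S.shape[1]:
            raise HINValidationError("proximity matrix must be square")
        if not np.allclose(S, S.T, atol=1e-12):
            raise HINValidationError(f"{self.meta_path} proximity not symmetric")
        if np.any(S < -1e-12):
            raise HINValidationError(f"{self.meta_path} proximity has negative entries")
        if self.normalized and np.any(S > 1 + 1e-9):
            raise HINValidationError(
                f"{self.meta_path} proximity marked normalized but exceeds 1"
            )
        return self


@dataclass
class EmbeddingMatrix:
    """drugs x d real embedding; row order matches the DrugHIN drug registry."""

    ids: list[str]
    E: np.ndarray
    source: str = "final"

    def validate(self) -> "EmbeddingMatrix":
        if self.E.ndim != 2 or self.E.shape[0] != len(self.ids):
            raise HINValidationError("embedding rows must match the ID registry")
        if not np.all(np.isfinite(self.E)):
            raise HINValidationError("embedding contains non-finite entries")
        return self


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _read_node_list(path: str) -> list[str]:
    ids: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                ids.append(line)
    return ids


def _read_edge_tsv(path: str, rows: dict, cols: dict, shape, name: str) -> sp.csr_matrix:
    ri: list[int] = []
    ci: list[int] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise HINValidationError(
                    f"{path}:{ln}: expected two tab-separated IDs"
                )
            s, t = parts
            if s not in rows:
                raise HINValidationError(f"{path}:{ln}: unregistered node {s!r}")
            if t not in cols:
                raise HINValidationError(f"{path}:{ln}: unregistered node {t!r}")
            ri.append(rows[s])
            ci.append(cols[t])
    M = sp.coo_matrix((np.ones(len(ri)), (ri, ci)), shape=shape).tocsr()
    M.data[:] = 1.0  # duplicate edges collapse to a single 1
    return M


def _load_relation(path: str, rows: dict, cols: dict, shape, name: str) -> sp.csr_matrix:
    if not os.path.exists(path):
        raise FileNotFoundError(f"relation file for {name!r} not found: {path}")
    if path.endswith(".mtx"):
        from scipy.io import mmread

        M = sp.csr_matrix(mmread(path))
        if M.shape != shape:
            raise HINValidationError(
                f"{path}: shape {M.shape} does not match registries {shape}"
            )
        M.data[:] = np.minimum(M.data, 1.0)
        return M
    return _read_edge_tsv(path, rows, cols, shape, name)


def read_hin(config: str | dict, allow_asymmetric: bool = False) -> DrugHIN:
    """Load a :class:`DrugHIN` from a YAML config or an equivalent dict.

    The config has a ``nodes`` section naming the five registry files and a
    ``relations`` section naming the six relation files (TSV edge lists or
    ``.mtx``).  Paths are resolved relative to the config file.  Undirected
    relations (``dd``, ``pp``) given as edge lists are symmetrized — an edge
    is an unordered pair; ``.mtx`` inputs must already be symmetric unless
    ``allow_asymmetric`` requests symmetrization.
    """
    base = "."
    if isinstance(config, (str, os.PathLike)):
        base = os.path.dirname(os.fspath(config)) or "."
        with open(config) as fh:
            config = yaml.safe_load(fh)
    nodes_cfg = config["nodes"]
    rel_cfg = config["relations"]

    registries = {
        key: _read_node_list(os.path.join(base, nodes_cfg[key])) for key in _NODE_KEYS
    }
    for key in _NODE_KEYS:
        _check_unique(registries[key], key)
    index = {key: {v: i for i, v in enumerate(ids)} for key, ids in registries.items()}

    mats: dict[str, sp.csr_matrix] = {}
    for rel, (rk, ck) in _RELATIONS.items():
        shape = (len(registries[rk]), len(registries[ck]))
        path = os.path.join(base, rel_cfg[rel])
        M = _load_relation(path, index[rk], index[ck], shape, rel)
        if rel in ("dd", "pp"):
            if path.endswith(".mtx") and (M != M.T).nnz != 0:
                if not allow_asymmetric:
                    raise HINValidationError(
                        f"{rel} matrix is asymmetric; pass allow_asymmetric=True "
                        "to symmetrize"
                    )
            M = M.maximum(M.T)
            M.setdiag(0)
            M.eliminate_zeros()
        mats[rel] = sp.csr_matrix(M)

    hin = DrugHIN(
        drugs=registries["drugs"],
        chems=registries["chems"],
        prots=registries["prots"],
        ses=registries["ses"],
        dis=registries["dis"],
        A_dd=mats["dd"],
        M_dc=mats["dc"],
        M_dp=mats["dp"],
        M_dse=mats["dse"],
        M_ddi=mats["ddi"],
        A_pp=mats["pp"],
    )
    return hin.validate()


def write_hin(hin: DrugHIN, outdir: str) -> str:
    """Write a HIN as node lists + TSV edge lists plus a ``hin.yaml`` config.

    Returns the config path; ``read_hin`` on it reproduces the matrices
    exactly (undirected relations are emitted once per unordered pair).
    """
    os.makedirs(outdir, exist_ok=True)
    nodes = {}
    for key in _NODE_KEYS:
        fname = f"{key}.txt"
        with open(os.path.join(outdir, fname), "w") as fh:
            fh.write("".join(f"{i}\n" for i in getattr(hin, key)))
        nodes[key] = fname

    attr = {"dd": "A_dd", "dc": "M_dc", "dp": "M_dp", "dse": "M_dse",
            "ddi": "M_ddi", "pp": "A_pp"}
    relations = {}
    for rel, (rk, ck) in _RELATIONS.items():
        fname = f"{rel}.tsv"
        rows_ids = getattr(hin, rk)
        cols_ids = getattr(hin, ck)
        M = sp.coo_matrix(getattr(hin, attr[rel]))
        with open(os.path.join(outdir, fname), "w") as fh:
            fh.write(f"# {rel}: {rk} -> {ck}\n")
            for r, c in zip(M.row, M.col):
                if rel in ("dd", "pp") and r > c:
                    continue  # undirected: one line per unordered pair
                fh.write(f"{rows_ids[r]}\t{cols_ids[c]}\n")
        relations[rel] = fname

    cfg_path = os.path.join(outdir, "hin.yaml")
    with open(cfg_path, "w") as fh:
        yaml.safe_dump({"nodes": nodes, "relations": relations}, fh)
    return cfg_path


def write_embeddings(emb: EmbeddingMatrix, path: str) -> None:
    """Write an embedding as TSV with header ``id, dim_0..dim_{d-1}``."""
    emb.validate()
    d = emb.E.shape[1]
    header = "id\t" + "\t".join(f"dim_{j}" for j in range(d))
    with open(path, "w") as fh:
        fh.write(header.rstrip() + "\n")
        for i, drug in enumerate(emb.ids):
            row = "\t".join(repr(float(v)) for v in emb.E[i])
            fh.write(f"{drug}\t{row}".rstrip() + "\n")


def read_embeddings(path: str, source: str = "final") -> EmbeddingMatrix:
    ids: list[str] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        d = len(header) - 1
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            ids.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    E = np.asarray(rows, dtype=float).reshape(len(ids), d)
    return EmbeddingMatrix(ids=ids, E=E, source=source).validate()
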