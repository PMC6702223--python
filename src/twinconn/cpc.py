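"""Shared cross-paradigm connectivity (CPC) component per subject.

Each paradigm's connectivity matrix is vectorized to its upper triangle,
the paradigm-by-edge stack is decomposed by SVD (uncentered by default),
and the first right-singular vector — the edge pattern shared across
paradigms — is taken as the subject's CPC loadings.  A fixed edge mask
(e.g. a cerebello-thalamo-cortical circuit) reduces the loadings to a
scalar network phenotype.

Edge ordering is canonical throughout: upper triangle, i < j, row-major,
0-based node indices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .connectivity import ConnectivityMatrix

__all__ = [
    "EdgeVector",
    "CpcResult",
    "EdgeMask",
    "n_edges",
    "edge_index",
    "vectorize_edges",
    "devectorize_edges",
    "compute_cpc",
    "network_score",
]


def n_edges(n_nodes: int) -> int:
    return n_nodes * (n_nodes - 1) // 2


@dataclass
class EdgeVector:
    """Upper-triangle edge values of one subject/paradigm matrix."""

    subject_id: str
    paradigm_id: str
    values: np.ndarray
    n_nodes: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size != n_edges(self.n_nodes):
            raise ValueError(
                f"edge vector length {self.values.size} does not match "
                f"n_nodes={self.n_nodes} (expected {n_edges(self.n_nodes)})")


@dataclass
class CpcResult:
    """First-PC edge loadings and the per-component variance split."""

    subject_id: str
    loadings: np.ndarray  # unit-norm, length E
    variance_explained: np.ndarray  # descending, sums to 1
    paradigm_scores: np.ndarray  # projection of each paradigm vector
    paradigm_ids: tuple[str, ...]
    n_nodes: int


@dataclass(frozen=True)
class EdgeMask:
    """Unordered node-pair set selecting a subnetwork's edges."""

    pairs: frozenset

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[int, int]]) -> "EdgeMask":
        norm = set()
        for i, j in pairs:
            i, j = int(i), int(j)
            if i == j:
                raise ValueError(f"self-edge ({i},{j}) not allowed")
            if i < 0 or j < 0:
                raise ValueError(f"negative node index in ({i},{j})")
            norm.add((min(i, j), max(i, j)))
        return cls(frozenset(norm))

    def __len__(self) -> int:
        return len(self.pairs)

    def edge_indices(self, n_nodes: int) -> np.ndarray:
        """Canonical edge indices of the masked pairs, sorted ascending."""
        idx = []
        for i, j in self.pairs:
            if j >= n_nodes:
                raise ValueError(f"node index {j} out of range for n_nodes={n_nodes}")
            idx.append(edge_index(i, j, n_nodes))
        return np.array(sorted(idx), dtype=int)


def edge_index(i: int, j: int, n_nodes: int) -> int:
    """Position of edge (i, j), i < j, in the canonical upper-triangle order."""
    if not 0 <= i < j < n_nodes:
        raise ValueError(f"need 0 <= i < j < n_nodes, got ({i},{j}) with n={n_nodes}")
    # edges before row i, plus offset within row i
    return i * n_nodes - i * (i + 1) // 2 + (j - i - 1)


def vectorize_edges(m: ConnectivityMatrix) -> EdgeVector:
    """Upper triangle (i < j, row-major) of a symmetric matrix."""
    v = m.values
    if not np.allclose(v, v.T, atol=1e-8):
        raise ValueError("matrix asymmetric beyond 1e-8; refusing to vectorize")
    iu = np.triu_indices(m.n_nodes, k=1)
    return EdgeVector(m.subject_id, m.paradigm_id, v[iu], m.n_nodes)


def devectorize_edges(vec: EdgeVector, diagonal: float = 1.0) -> ConnectivityMatrix:
    """Inverse of :func:`vectorize_edges`, restoring a unit diagonal."""
    n = vec.n_nodes
    out = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    out[iu] = vec.values
    out = out + out.T
    np.fill_diagonal(out, diagonal)
    return ConnectivityMatrix(vec.subject_id, vec.paradigm_id, out)


def compute_cpc(vectors: Sequence[EdgeVector], center: bool = False) -> CpcResult:
    """First shared component of one subject's paradigm edge vectors.

    SVD of the k x E stack (k paradigms).  By default no edge-wise
    centering is applied, so the first component captures the dominant
    common pattern including its mean level.  Variance explained per
    component is sigma_c^2 / sum(sigma^2).

    Sign convention: loadings are flipped so the paradigm scores sum to a
    positive value; an exactly zero sum falls back to making the
    largest-magnitude loading positive.
    """
    if len(vectors) < 2:
        raise ValueError(f"need >= 2 paradigm vectors, got {len(vectors)}")
    subject = vectors[0].subject_id
    n_nodes = vectors[0].n_nodes
    lengths = {v.values.size for v in vectors}
    if len(lengths) != 1:
        raise ValueError("paradigm edge vectors differ in length")
    if any(v.subject_id != subject for v in vectors):
        raise ValueError("edge vectors belong to different subjects")
    x = np.stack([v.values for v in vectors])
    if center:
        x = x - x.mean(axis=0, keepdims=True)
    if not np.any(x):
        raise ValueError("all-zero paradigm stack; no component to extract")
    _, s, vt = np.linalg.svd(x, full_matrices=False)
    loadings = vt[0]
    var_explained = s**2 / np.sum(s**2)
    scores = x @ loadings
    total = scores.sum()
    if total < 0 or (total == 0 and loadings[np.argmax(np.abs(loadings))] < 0):
        loadings = -loadings
        scores = -scores
    return CpcResult(
        subject_id=subject,
        loadings=loadings,
        variance_explained=var_explained,
        paradigm_scores=scores,
        paradigm_ids=tuple(v.paradigm_id for v in vectors),
        n_nodes=n_nodes,
    )


def network_score(cpc: CpcResult, mask: EdgeMask, reduction: str = "mean",
                  weights: np.ndarray | None = None) -> float:
    """Scalar network phenotype: reduce the CPC loadings over masked edges.

    ``mean`` (default) is scale-stable across mask sizes; ``sum`` and
    ``wmean`` (weighted mean, weights per masked edge in canonical order)
    are available alternatives.
    """
    if len(mask) == 0:
        raise ValueError("empty edge mask")
    idx = mask.edge_indices(cpc.n_nodes)
    vals = cpc.loadings[idx]
    if reduction == "mean":
        return float(vals.mean())
    if reduction == "sum":
        return float(vals.sum())
    if reduction == "wmean":
        if weights is None or len(weights) != len(idx):
            raise ValueError("wmean needs one weight per masked edge")
        w = np.asarray(weights, dtype=float)
        return float((vals * w).sum() / w.sum())
    raise ValueError(f"unknown reduction {reduction!r}")
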