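"""Cross-dataset integration: CCA with scalable query extension,
mutual-nearest-neighbour anchors, Seurat-v3-style anchor scoring, anchor-based
alignment to a reference embedding, and Leiden joint clustering.

The CCA between two z-scored cell-by-feature matrices X and Y is solved by an
SVD of their dot product, U S V^T = X Y^T.  Fitting on full datasets is
memory-bound in the number of cells, so a seeded reference subsample fits the
model and the remaining (query) cells are extended exactly:

    U_qry = X_qry (Y_ref^T V_ref) / S
    V_qry = Y_qry (X_ref^T U_ref) / S

When the query equals the reference this reproduces the fitted canonical
vectors, which is asserted in the test suite.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .transfer import distance_to_weight

logger = logging.getLogger(__name__)

__all__ = [
    "CcaModel",
    "AnchorSet",
    "cca_fit",
    "cca_extend",
    "l2_normalize_rows",
    "find_mutual_anchors",
    "score_anchors",
    "integrate_embeddings",
    "joint_cluster",
]


@dataclass
class CcaModel:
    """Fitted canonical vectors plus the scaled inputs needed for extension."""

    u_ref: np.ndarray          # ref cells of X, pre row-normalization
    v_ref: np.ndarray          # ref cells of Y
    singular_values: np.ndarray
    x_ref: np.ndarray
    y_ref: np.ndarray

    @property
    def n_components(self) -> int:
        return self.u_ref.shape[1]


@dataclass
class AnchorSet:
    """Scored mutual-nearest-neighbour cell pairs linking two datasets."""

    pairs: np.ndarray          # n x 2 (ref index, query index)
    raw_scores: np.ndarray | None = None
    scores: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.pairs)

    def frame(self) -> pd.DataFrame:
        d = {"ref_idx": self.pairs[:, 0], "qry_idx": self.pairs[:, 1]}
        if self.raw_scores is not None:
            d["raw"] = self.raw_scores
        if self.scores is not None:
            d["score"] = self.scores
        return pd.DataFrame(d)


def cca_fit(x_ref: np.ndarray, y_ref: np.ndarray, n_components: int) -> CcaModel:
    """SVD of X Y^T, truncated; inputs must share feature columns and be
    z-scored across cells within each dataset."""
    x_ref = np.asarray(x_ref, dtype=float)
    y_ref = np.asarray(y_ref, dtype=float)
    if x_ref.shape[1] != y_ref.shape[1]:
        raise ValueError("X and Y must share feature columns")
    k = min(n_components, x_ref.shape[0], y_ref.shape[0])
    if k < n_components:
        warnings.warn(f"truncating to {k} components (fewer cells than requested)")
    u, s, vt = np.linalg.svd(x_ref @ y_ref.T, full_matrices=False)
    return CcaModel(
        u_ref=u[:, :k],
        v_ref=vt[:k].T,
        singular_values=s[:k],
        x_ref=x_ref,
        y_ref=y_ref,
    )


def cca_extend(
    model: CcaModel,
    x_qry: np.ndarray | None = None,
    y_qry: np.ndarray | None = None,
) -> tuple[np.ndarray | None, np.ndarray | None]:
    """Project query cells onto the fitted canonical space (exact formulas)."""
    s = model.singular_values
    keep = s > s[0] * 1e-12 if s.size else np.array([], dtype=bool)
    if not keep.all():
        warnings.warn("dropping near-zero singular components during extension")
    u_qry = v_qry = None
    if x_qry is not None:
        u_qry = (np.asarray(x_qry, float) @ (model.y_ref.T @ model.v_ref[:, keep])) / s[keep]
    if y_qry is not None:
        v_qry = (np.asarray(y_qry, float) @ (model.x_ref.T @ model.u_ref[:, keep])) / s[keep]
    return u_qry, v_qry


def l2_normalize_rows(m: np.ndarray) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    norms = np.linalg.norm(m, axis=1, keepdims=True)
    return m / np.where(norms == 0, 1.0, norms)


def _knn_indices(query: np.ndarray, target: np.ndarray, k: int) -> np.ndarray:
    nn = NearestNeighbors(n_neighbors=k).fit(target)
    return nn.kneighbors(query, return_distance=False)


def find_mutual_anchors(
    emb_a: np.ndarray,
    emb_b: np.ndarray,
    k: int = 5,
    emb_a_alt: np.ndarray | None = None,
    emb_b_alt: np.ndarray | None = None,
) -> AnchorSet:
    """Mutual k-nearest-neighbour pairs between two datasets.

    Pair (i, j) is an anchor iff j is among the k nearest B-cells of i and i
    among the k nearest A-cells of j.  In reciprocal-reduction mode the
    search direction a->b uses (emb_a, emb_b) and b->a uses
    (emb_a_alt, emb_b_alt) — each dataset projected into the other's
    reduction.  Ties are broken by cell index order (sklearn's stable
    ordering), for determinism.
    """
    emb_a = np.asarray(emb_a, float)
    emb_b = np.asarray(emb_b, float)
    if k >= min(emb_a.shape[0], emb_b.shape[0]):
        raise ValueError("k must be smaller than both dataset sizes")
    ab = _knn_indices(emb_a, emb_b, k)  # for each a: its k nearest b
    if emb_a_alt is not None or emb_b_alt is not None:
        if emb_a_alt is None or emb_b_alt is None:
            raise ValueError("reciprocal mode needs both alternate embeddings")
        ba = _knn_indices(np.asarray(emb_b_alt, float), np.asarray(emb_a_alt, float), k)
    else:
        ba = _knn_indices(emb_b, emb_a, k)

    b_of_a = {(i, j) for i in range(ab.shape[0]) for j in ab[i]}
    pairs = sorted(
        (i, j)
        for j in range(ba.shape[0])
        for i in ba[j]
        if (i, j) in b_of_a
    )
    return AnchorSet(pairs=np.array(pairs, dtype=int).reshape(-1, 2))


def score_anchors(
    anchors: AnchorSet,
    emb_a: np.ndarray,
    emb_b: np.ndarray,
    neighborhood: int = 30,
) -> AnchorSet:
    """Shared-neighbourhood anchor scores, rescaled as in Seurat v3.

    The raw score of anchor (i, j) is the overlap between the two cells'
    ``neighborhood``-sized neighbourhoods in the combined dataset; raw scores
    are rescaled linearly between their 1st and 90th percentiles and clipped
    to [0, 1].
    """
    if len(anchors) == 0:
        raise ValueError("anchors must be nonempty")
    emb_a = np.asarray(emb_a, float)
    emb_b = np.asarray(emb_b, float)
    combined = np.vstack([emb_a, emb_b])
    n_a = emb_a.shape[0]
    k = min(neighborhood, combined.shape[0])
    nn = NearestNeighbors(n_neighbors=k).fit(combined)
    hoods = nn.kneighbors(combined, return_distance=False)
    raw = np.array(
        [
            len(set(hoods[i]) & set(hoods[n_a + j]))
            for i, j in anchors.pairs
        ],
        dtype=float,
    )
    lo, hi = np.quantile(raw, [0.01, 0.90])
    if hi > lo:
        scores = np.clip((raw - lo) / (hi - lo), 0.0, 1.0)
    else:
        scores = np.ones_like(raw)
    return AnchorSet(pairs=anchors.pairs, raw_scores=raw, scores=scores)


def integrate_embeddings(
    reference: np.ndarray,
    query: np.ndarray,
    anchors: AnchorSet,
    k_weight: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Align query coordinates to the reference through scored anchors.

    Each query cell subtracts a weighted average of anchor difference vectors
    (query coordinate minus reference coordinate at each anchor).  Weights come
    from the label-transfer distance transform over the cell's ``k_weight``
    nearest anchors (distance measured to the anchors' query cells),
    multiplied by the anchor scores and renormalized.  Reference coordinates
    are returned unchanged.
    """
    reference = np.asarray(reference, float)
    query = np.asarray(query, float)
    if len(anchors) == 0:
        raise ValueError("cannot integrate with zero anchors")
    scores = anchors.scores if anchors.scores is not None else np.ones(len(anchors))
    if np.all(scores == 0):
        raise ValueError("all anchor scores are zero; correction undefined")

    anchor_q = query[anchors.pairs[:, 1]]
    diff = anchor_q - reference[anchors.pairs[:, 0]]

    k = min(k_weight, len(anchors))
    nn = NearestNeighbors(n_neighbors=k).fit(anchor_q)
    dist, idx = nn.kneighbors(query)
    w = distance_to_weight(dist) * scores[idx]
    totals = w.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        raise ValueError(
            "some query cells have only zero-score anchors in range; "
            "correction undefined"
        )
    w = w / totals
    correction = np.einsum("qk,qkd->qd", w, diff[idx])
    return reference, query - correction


def joint_cluster(
    coords: np.ndarray,
    k: int = 25,
    resolution: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Leiden partition of the Euclidean kNN graph of the integrated space.

    Labels are contiguous integers ordered by decreasing cluster size.
    """
    coords = np.asarray(coords, float)
    n = coords.shape[0]
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} cells, got {n}")
    knn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    idx = knn.kneighbors(coords, return_distance=False)[:, 1:]
    edges = {(min(i, j), max(i, j)) for i in range(n) for j in idx[i]}
    graph = ig.Graph(n=n, edges=sorted(edges))
    if not graph.is_connected():
        logger.info("kNN graph is disconnected; clustering proceeds per component")
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    labels = np.asarray(part.membership)
    # relabel by size, ties by original label for determinism
    order = sorted(
        np.unique(labels), key=lambda c: (-(labels == c).sum(), c)
    )
    remap = {old: new for new, old in enumerate(order)}
    return np.array([remap[c] for c in labels], dtype=int)
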