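"""Weighted k-nearest-neighbour label transfer and the workflows built on it.

Given two datasets in a co-embedding — A labelled, B unlabelled — each query
cell in B finds its k nearest neighbours in A (Euclidean), and the distance
vector d is transformed to weights:

    d'  = 1 - d / max(d)
    d'' = 1 - exp(-d' / 2)
    w   = d'' / sum(d'')

so closer neighbours weigh more, the farthest neighbour gets weight 0, and the
weights sum to 1.  Categorical labels are one-hot encoded and averaged with w,
giving per-category probabilities L_qry = w L_ref; the argmax is the
assignment.  Continuous per-cell values (e.g. embedding coordinates) are
averaged the same way.

The transform is undefined when all distances are equal (d' = 0 everywhere);
the uniform 1/k fallback is the limit of intent and is used with a warning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .methylome import MethylCountMatrix, posterior_methylation, reduce_dimensions

logger = logging.getLogger(__name__)

__all__ = [
    "TransferWeights",
    "LabelProbabilities",
    "distance_to_weight",
    "knn_transfer_weights",
    "transfer_labels",
    "remove_doublets",
    "hierarchical_classify",
]


@dataclass
class TransferWeights:
    """Per-query neighbour indices, distances and normalized weights."""

    neighbor_idx: np.ndarray   # query x k, row indices into the labelled dataset
    distances: np.ndarray      # query x k
    weights: np.ndarray        # query x k, rows sum to 1

    @property
    def k(self) -> int:
        return self.neighbor_idx.shape[1]


@dataclass
class LabelProbabilities:
    """Query-by-category probabilities; assignment is the row argmax."""

    categories: np.ndarray
    probabilities: np.ndarray

    @property
    def assignments(self) -> np.ndarray:
        # ties broken by category order (first maximum)
        return self.categories[self.probabilities.argmax(axis=1)]

    def frame(self, index=None) -> pd.DataFrame:
        return pd.DataFrame(self.probabilities, columns=self.categories, index=index)


def distance_to_weight(d: np.ndarray) -> np.ndarray:
    """Apply the d -> d' -> d'' -> w chain row-wise.

    Rows where max(d) == 0 or all entries are equal fall back to uniform 1/k.
    """
    d = np.atleast_2d(np.asarray(d, dtype=float))
    n, k = d.shape
    if k == 1:
        return np.ones((n, 1))
    dmax = d.max(axis=1, keepdims=True)
    degenerate = (dmax[:, 0] == 0) | (d.min(axis=1) == d.max(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        dprime = 1.0 - d / dmax
    ddbl = 1.0 - np.exp(-dprime / 2.0)
    total = ddbl.sum(axis=1, keepdims=True)
    w = np.where(degenerate[:, None], 1.0 / k, ddbl / np.where(total == 0, 1.0, total))
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} query rows had degenerate distances; "
            "uniform weights used"
        )
    return w


def knn_transfer_weights(
    query_coords: np.ndarray, labelled_coords: np.ndarray, k: int = 25
) -> TransferWeights:
    """Find k nearest labelled cells per query cell and compute transfer weights."""
    labelled_coords = np.asarray(labelled_coords, dtype=float)
    query_coords = np.asarray(query_coords, dtype=float)
    if k > labelled_coords.shape[0]:
        raise ValueError(f"k={k} exceeds labelled dataset size {labelled_coords.shape[0]}")
    nn = NearestNeighbors(n_neighbors=k).fit(labelled_coords)
    dist, idx = nn.kneighbors(query_coords)
    w = distance_to_weight(dist)
    return TransferWeights(neighbor_idx=idx, distances=dist, weights=w)


def transfer_labels(
    weights: TransferWeights,
    labels: np.ndarray,
    continuous: bool = False,
) -> LabelProbabilities | np.ndarray:
    """Average neighbour labels (one-hot) or values with the transfer weights.

    Categorical mode returns :class:`LabelProbabilities` (rows sum to 1);
    continuous mode returns the weighted average of neighbour value vectors.
    """
    labels = np.asarray(labels)
    if continuous:
        vals = labels[weights.neighbor_idx]            # q x k (x dims)
        if vals.ndim == 2:
            return (weights.weights * vals).sum(axis=1)
        return np.einsum("qk,qkd->qd", weights.weights, vals)
    if pd.isnull(labels).any():
        raise ValueError("every neighbour must carry a label")
    categories, encoded = np.unique(labels, return_inverse=True)
    onehot = np.eye(len(categories))[encoded]          # labelled x c
    lref = onehot[weights.neighbor_idx]                # q x k x c
    probs = np.einsum("qk,qkc->qc", weights.weights, lref)
    probs = probs / probs.sum(axis=1, keepdims=True)
    return LabelProbabilities(categories=categories, probabilities=probs)


def _classify(
    query_levels: np.ndarray,
    ref_levels: np.ndarray,
    ref_labels: np.ndarray,
    k: int,
    n_components: int,
) -> np.ndarray:
    """Fit a reduction on the reference, transform the query, transfer labels.

    Classification uses the unnormalized principal projections (coordinates
    multiplied back by the singular values): kNN voting needs the original
    distance geometry, where signal components outweigh noise components.
    """
    n_components = min(n_components, ref_levels.shape[0] - 1, ref_levels.shape[1])
    model = reduce_dimensions(ref_levels, n_components, mode="fit")
    ref_coords = model.coords * model.singular_values
    qry_coords = model.transform(query_levels) * model.singular_values
    k = min(k, ref_levels.shape[0])
    w = knn_transfer_weights(qry_coords, ref_coords, k=k)
    return transfer_labels(w, ref_labels).assignments


def remove_doublets(
    query_levels: np.ndarray,
    ref_levels: np.ndarray,
    ref_l1_labels: np.ndarray,
    ref_doublet_mask: np.ndarray,
    k: int = 25,
    n_components: int = 20,
    doublet_label: str = "doublet",
) -> tuple[np.ndarray, np.ndarray]:
    """Two-round doublet flagging against a reference carrying doublet clusters.

    Round 1 classifies every query cell against all reference level-1 clusters
    plus the reference's predicted-doublet cells, using a reduction fit on the
    whole reference.  Round 2 repeats the classification within each assigned
    L1 cluster, with all reference doublet cells re-injected, using a reduction
    refit on that cluster's reference cells (plus doublets).  A query cell
    assigned to the doublet class in either round is flagged.

    Returns (assigned L1 labels, doublet flags); flagged cells keep their
    round-1 L1 assignment for reporting but should be removed downstream.
    """
    ref_doublet_mask = np.asarray(ref_doublet_mask, dtype=bool)
    if not ref_doublet_mask.any():
        raise ValueError("reference carries no doublet-cluster labels")
    labels_r1 = np.asarray(ref_l1_labels).astype(object).copy()
    labels_r1[ref_doublet_mask] = doublet_label

    assign1 = _classify(query_levels, ref_levels, labels_r1, k, n_components)
    flags = assign1 == doublet_label
    final = assign1.copy()

    for cluster in np.unique(assign1[~flags]):
        q_mask = assign1 == cluster
        r_mask = (labels_r1 == cluster) | ref_doublet_mask
        if (labels_r1 == cluster).sum() == 0:
            logger.warning("L1 cluster %s has no reference cells; skipped", cluster)
            continue
        sub_labels = labels_r1[r_mask]
        if len(np.unique(sub_labels)) < 2:
            continue
        assign2 = _classify(
            query_levels[q_mask], ref_levels[r_mask], sub_labels, k, n_components
        )
        flags[q_mask] |= assign2 == doublet_label
    return final, flags


def hierarchical_classify(
    query_levels: np.ndarray,
    ref_levels: np.ndarray,
    ref_labels: pd.DataFrame,
    k: int = 25,
    n_components: int = 20,
) -> pd.DataFrame:
    """Assign query cells one cluster per hierarchy level (columns of
    ``ref_labels``, e.g. L1..L4, nested).

    The level-n assignment restricts level-(n+1) candidates to the reference
    cells of the assigned cluster.  Branches without deeper labels (NaN) stop
    at the deepest available level.
    """
    levels = list(ref_labels.columns)
    n_query = query_levels.shape[0]
    out = pd.DataFrame(index=range(n_query), columns=levels, dtype=object)

    # level 1 over the full reference
    lab0 = ref_labels[levels[0]].to_numpy()
    out[levels[0]] = _classify(query_levels, ref_levels, lab0, k, n_components)

    for li in range(1, len(levels)):
        parent, child = levels[li - 1], levels[li]
        for cluster in pd.unique(out[parent].dropna()):
            q_mask = (out[parent] == cluster).to_numpy()
            r_mask = (ref_labels[parent] == cluster).to_numpy()
            child_labels = ref_labels.loc[r_mask, child]
            if child_labels.isna().all():
                continue  # branch ends here; deeper levels stay NaN
            r_mask &= ref_labels[child].notna().to_numpy()
            labs = ref_labels.loc[r_mask, child].to_numpy()
            if len(np.unique(labs)) == 1:
                out.loc[q_mask, child] = labs[0]
                continue
            out.loc[q_mask, child] = _classify(
                query_levels[q_mask], ref_levels[r_mask], labs, k, n_components
            )
    return out
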