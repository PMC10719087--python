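"""Spatially smoothed label transfer for in-situ (MERFISH-style) data.

Initial label transfer from a dissociated reference to in-situ cells is noisy.
Smoothing combines two neighbourhoods: for in-situ cell i, its k_spatial
nearest cells on the same slice (distances Ds) and, for each spatial neighbour
j, that neighbour's k_ref nearest reference cells in the integrated embedding
(distances Dr).  Both distance vectors pass through the unnormalized second
stage of the transfer transform (d'' = 1 - exp(-d'/2)); the weight of the kth
reference neighbour of the jth spatial neighbour is the product
Ds''_{i,j} * Dr''_{Ns_{i,j},k}.  The combined weight row (k_spatial x k_ref
entries) is normalized once at the end and used for label transfer, so each
in-situ cell votes over up to k_spatial*k_ref reference cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .transfer import LabelProbabilities, TransferWeights, transfer_labels

__all__ = ["SpatialSlice", "smooth_spatial_labels", "map_clusters_to_slices"]


@dataclass
class SpatialSlice:
    """Cells of one tissue slice: coordinates (µm), slice id, labels."""

    cell_ids: np.ndarray
    x: np.ndarray
    y: np.ndarray
    slice_id: str
    initial_labels: np.ndarray | None = None
    smoothed_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("coordinates must be finite")
        if len(self.x) != len(self.cell_ids) or len(self.y) != len(self.cell_ids):
            raise ValueError("coordinate / cell id length mismatch")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def coords(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def frame(self) -> pd.DataFrame:
        d = {"cell_id": self.cell_ids, "x": self.x, "y": self.y, "slice": self.slice_id}
        if self.initial_labels is not None:
            d["initial_label"] = self.initial_labels
        if self.smoothed_labels is not None:
            d["smoothed_label"] = self.smoothed_labels
        return pd.DataFrame(d)


def _unnormalized_ddbl(d: np.ndarray) -> np.ndarray:
    """Second-stage transform d'' = 1 - exp(-d'/2) without the final
    normalization; degenerate rows (all-equal distances) become uniform 1s."""
    d = np.asarray(d, dtype=float)
    dmax = d.max(axis=1, keepdims=True)
    degenerate = (dmax[:, 0] == 0) | (d.min(axis=1) == d.max(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        dprime = 1.0 - d / dmax
    ddbl = 1.0 - np.exp(-dprime / 2.0)
    ddbl[degenerate] = 1.0
    return ddbl


def combine_product_weights(
    ds_dbl: np.ndarray, dr_dbl_rows: np.ndarray
) -> np.ndarray:
    """Combined weights for one query cell.

    ``ds_dbl``: (k_spatial,) unnormalized d'' to the spatial neighbours;
    ``dr_dbl_rows``: (k_spatial, k_ref) unnormalized d'' of each spatial
    neighbour to its reference neighbours.  Returns the row-normalized
    flattened product, length k_spatial * k_ref.
    """
    combined = (np.asarray(ds_dbl)[:, None] * np.asarray(dr_dbl_rows)).ravel()
    total = combined.sum()
    if total == 0:
        return np.full(combined.size, 1.0 / combined.size)
    return combined / total


def smooth_spatial_labels(
    slice_: SpatialSlice,
    ref_embedding: np.ndarray,
    ref_labels: np.ndarray,
    query_embedding: np.ndarray,
    k_spatial: int = 25,
    k_ref: int = 25,
) -> LabelProbabilities:
    """Transfer labels to one slice through product-weighted two-stage
    neighbourhoods.

    ``query_embedding`` holds the slice's cells in the integrated space shared
    with ``ref_embedding`` (the labelled reference).  Spatial neighbour search
    is restricted to the slice; cells on other slices never enter.
    """
    n = slice_.n_cells
    ref_embedding = np.asarray(ref_embedding, dtype=float)
    query_embedding = np.asarray(query_embedding, dtype=float)
    if query_embedding.shape[0] != n:
        raise ValueError("query_embedding must align with the slice's cells")

    ks = k_spatial
    if n - 1 < ks:
        warnings.warn(
            f"slice {slice_.slice_id}: only {n - 1} same-slice neighbours "
            f"available (< k_spatial={k_spatial})"
        )
        ks = max(n - 1, 1)
    # spatial neighbours on the same slice, excluding the cell itself
    nn_sp = NearestNeighbors(n_neighbors=ks + 1).fit(slice_.coords)
    ds, ns = nn_sp.kneighbors(slice_.coords)
    ds, ns = ds[:, 1:], ns[:, 1:]

    kr = min(k_ref, ref_embedding.shape[0])
    nn_ref = NearestNeighbors(n_neighbors=kr).fit(ref_embedding)
    dr, nr = nn_ref.kneighbors(query_embedding)

    ds_dbl = _unnormalized_ddbl(ds)
    dr_dbl = _unnormalized_ddbl(dr)

    combined_idx = np.empty((n, ks * kr), dtype=int)
    combined_w = np.empty((n, ks * kr))
    for i in range(n):
        neigh = ns[i]
        combined_idx[i] = nr[neigh].ravel()
        combined_w[i] = combine_product_weights(ds_dbl[i], dr_dbl[neigh])

    weights = TransferWeights(
        neighbor_idx=combined_idx, distances=np.zeros_like(combined_w), weights=combined_w
    )
    return transfer_labels(weights, np.asarray(ref_labels))


def map_clusters_to_slices(
    slices: list[SpatialSlice],
    labels_per_slice: list[np.ndarray],
    enriched_clusters: list,
) -> pd.DataFrame:
    """Per-slice occupancy of the given clusters: counts, centroid, bounding box.

    Clusters absent from a slice get a zero-count row with NaN geometry.
    """
    rows = []
    for sl, labels in zip(slices, labels_per_slice):
        labels = np.asarray(labels)
        for cluster in enriched_clusters:
            mask = labels == cluster
            if mask.any():
                rows.append(
                    dict(
                        slice=sl.slice_id,
                        cluster=cluster,
                        n_cells=int(mask.sum()),
                        centroid_x=float(sl.x[mask].mean()),
                        centroid_y=float(sl.y[mask].mean()),
                        min_x=float(sl.x[mask].min()),
                        max_x=float(sl.x[mask].max()),
                        min_y=float(sl.y[mask].min()),
                        max_y=float(sl.y[mask].max()),
                    )
                )
            else:
                rows.append(
                    dict(
                        slice=sl.slice_id,
                        cluster=cluster,
                        n_cells=0,
                        centroid_x=np.nan,
                        centroid_y=np.nan,
                        min_x=np.nan,
                        max_x=np.nan,
                        min_y=np.nan,
                        max_y=np.nan,
                    )
                )
    cols = [
        "slice", "cluster", "n_cells",
        "centroid_x", "centroid_y", "min_x", "max_x", "min_y", "max_y",
    ]
    return pd.DataFrame(rows, columns=cols)
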