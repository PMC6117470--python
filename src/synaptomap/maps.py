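"""Voxel and region synaptome maps, diversity, similarity, dendrograms.

Punctum parameters are averaged per mapping voxel (19.2 um x 19.2 um in
the section plane, one optical slice deep), producing parameter maps and
per-subtype density maps.  Derived products: the normalized-Shannon-entropy
diversity map (entropy of the per-voxel subtype composition divided by
log2 of the subtype count), the dominant-subtype map (argmax density),
per-region parameter signatures, Gaussian-kernel similarity matrices over
standardized region signatures, and UPGMA dendrograms of the similarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform
from skbio import TreeNode

from .io import RegionAtlas

log = logging.getLogger(__name__)

__all__ = [
    "VoxelMap",
    "voxelize",
    "region_stats",
    "diversity_map",
    "dominant_subtype_map",
    "similarity_matrix",
    "upgma_dendrogram",
    "gradient_profile",
]

PARAM_COLS = ("intensity", "size_um2", "skewness", "kurtosis", "circularity",
              "aspect_ratio")


@dataclass
class VoxelMap:
    """Per-voxel synaptome summary on a regular grid.

    ``counts`` is (ny, nx); ``param_means`` maps parameter name to a
    (ny, nx) array of per-voxel means (NaN where empty); ``subtype_counts``
    is (n_subtypes, ny, nx).  Voxel bins are half-open
    ``[k*v, (k+1)*v)`` from ``origin_nm``; puncta falling outside the grid
    are tallied in ``overflow``.
    """

    origin_nm: tuple[float, float]
    voxel_size_um: float
    counts: np.ndarray
    param_means: dict[str, np.ndarray]
    subtype_counts: np.ndarray | None = None
    subtype_ids: np.ndarray | None = None
    channel_counts: dict[int, np.ndarray] | None = None
    overflow: int = 0

    @property
    def voxel_area_um2(self) -> float:
        return self.voxel_size_um**2

    def density_per_100um2(self) -> np.ndarray:
        return self.counts / self.voxel_area_um2 * 100.0

    def subtype_densities(self) -> np.ndarray:
        """(n_subtypes, ny, nx) puncta per voxel area."""
        if self.subtype_counts is None:
            raise ValueError("map was built without subtype labels")
        return self.subtype_counts / self.voxel_area_um2


def voxelize(table: pd.DataFrame, voxel_size_um: float = 19.2,
             origin_nm: tuple[float, float] = (0.0, 0.0),
             shape: tuple[int, int] | None = None,
             param_cols=PARAM_COLS) -> VoxelMap:
    """Bin puncta into the mapping grid by centroid and average parameters.

    The grid extent defaults to the smallest grid covering all puncta from
    ``origin_nm``.  Binning is half-open, so voxel counts sum to the table
    size minus the logged overflow.
    """
    v_nm = voxel_size_um * 1000.0
    x = table["x_nm"].to_numpy(float) - origin_nm[1]
    y = table["y_nm"].to_numpy(float) - origin_nm[0]
    ij = np.floor(np.column_stack([y, x]) / v_nm).astype(int)
    if shape is None:
        ny = int(ij[:, 0].max()) + 1 if len(ij) else 1
        nx = int(ij[:, 1].max()) + 1 if len(ij) else 1
        shape = (max(ny, 1), max(nx, 1))
    inside = ((ij[:, 0] >= 0) & (ij[:, 0] < shape[0]) &
              (ij[:, 1] >= 0) & (ij[:, 1] < shape[1]))
    overflow = int((~inside).sum())
    if overflow:
        log.warning("%d puncta outside the voxel grid (overflow bin)", overflow)
    ij = ij[inside]
    flat = ij[:, 0] * shape[1] + ij[:, 1]
    counts = np.bincount(flat, minlength=shape[0] * shape[1]).reshape(shape)

    param_means: dict[str, np.ndarray] = {}
    for col in param_cols:
        if col not in table.columns:
            continue
        vals = table[col].to_numpy(float)[inside]
        ok = np.isfinite(vals)
        s = np.bincount(flat[ok], weights=vals[ok], minlength=shape[0] * shape[1])
        c = np.bincount(flat[ok], minlength=shape[0] * shape[1])
        with np.errstate(invalid="ignore"):
            param_means[col] = (s / c).reshape(shape)

    subtype_counts = subtype_ids = None
    if "subtype" in table.columns:
        sub = table["subtype"].to_numpy(int)[inside]
        subtype_ids = np.unique(sub)
        subtype_counts = np.stack([
            np.bincount(flat[sub == s], minlength=shape[0] * shape[1]).reshape(shape)
            for s in subtype_ids])

    channel_counts = None
    if "channel" in table.columns:
        ch = table["channel"].to_numpy(int)[inside]
        channel_counts = {
            int(c): np.bincount(flat[ch == c],
                                minlength=shape[0] * shape[1]).reshape(shape)
            for c in np.unique(ch)}

    return VoxelMap(origin_nm=origin_nm, voxel_size_um=voxel_size_um,
                    counts=counts, param_means=param_means,
                    subtype_counts=subtype_counts, subtype_ids=subtype_ids,
                    channel_counts=channel_counts, overflow=overflow)


def region_stats(table: pd.DataFrame, atlas: RegionAtlas,
                 aggregator: str = "median",
                 param_cols=PARAM_COLS) -> pd.DataFrame:
    """Per-region signatures: density (puncta per 100 um^2) and the
    aggregated punctum parameters.

    Puncta are assigned to regions by the atlas label under their centroid;
    density is punctum count over region pixel area.  Regions with no
    puncta get density 0 and null parameter fields.
    """
    if atlas.pixel_size_nm is None:
        raise ValueError("atlas needs a pixel size to normalize densities")
    py, px = atlas.pixel_size_nm
    iy = np.clip((table["y_nm"].to_numpy(float) / py).astype(int),
                 0, atlas.labels.shape[0] - 1)
    ix = np.clip((table["x_nm"].to_numpy(float) / px).astype(int),
                 0, atlas.labels.shape[1] - 1)
    region_of = atlas.labels[iy, ix]
    agg = {"median": np.nanmedian, "mean": np.nanmean}[aggregator]
    rows = []
    for rid in atlas.region_ids:
        sel = region_of == rid
        area_um2 = atlas.region_area_px(int(rid)) * (py * 1e-3) * (px * 1e-3)
        row = dict(region=int(rid), n=int(sel.sum()),
                   density=float(sel.sum() / area_um2 * 100.0),
                   aggregator=aggregator)
        for col in param_cols:
            if col in table.columns:
                vals = table.loc[sel, col].to_numpy(float)
                row[col] = float(agg(vals)) if sel.any() and np.isfinite(vals).any() else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def diversity_map(subtype_densities: np.ndarray, n_subtypes: int = 37) -> np.ndarray:
    """Normalized Shannon entropy of the subtype composition per voxel.

    With p_i the per-voxel density fractions, returns
    ``-sum p_i log2 p_i / log2(n_subtypes)`` in [0, 1]; empty voxels are
    NaN.  The default normalization divides by log2 37, the full subtype
    catalog size.
    """
    dens = np.asarray(subtype_densities, float)
    if (dens < 0).any():
        raise ValueError("subtype densities must be nonnegative")
    total = dens.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = dens / total
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    h = -plogp.sum(axis=0) / np.log2(n_subtypes)
    return np.where(total > 0, h, np.nan)


def dominant_subtype_map(subtype_densities: np.ndarray,
                         subtype_ids: np.ndarray | None = None) -> np.ndarray:
    """Subtype with the largest density per voxel; ties go to the lowest
    index, empty voxels to 0."""
    dens = np.asarray(subtype_densities, float)
    if (dens < 0).any():
        raise ValueError("subtype densities must be nonnegative")
    ids = np.arange(1, dens.shape[0] + 1) if subtype_ids is None else np.asarray(subtype_ids)
    order = np.argsort(ids)
    dens = dens[order]
    ids = ids[order]
    win = ids[np.argmax(dens, axis=0)]   # argmax returns the first (lowest-id) tie
    return np.where(dens.sum(axis=0) > 0, win, 0)


def similarity_matrix(signatures: pd.DataFrame, method: str = "parameter",
                      bandwidth: float | None = None,
                      feature_cols=None) -> tuple[np.ndarray, list, dict]:
    """Region x region similarity in [0, 1].

    ``parameter``: z-score the signature columns across regions, take
    Euclidean distances d_ij and apply a Gaussian kernel
    ``exp(-d^2 / (2 sigma^2))`` with sigma the median pairwise distance
    unless ``bandwidth`` is given.  Constant columns are dropped with a
    warning (their z-score is undefined).

    ``subtype_pearson``: Pearson correlation of the per-region subtype
    density vectors, rescaled ``(r+1)/2`` into [0, 1] (raw r in the info
    dict).
    """
    ids = list(signatures["region"]) if "region" in signatures.columns else list(signatures.index)
    if feature_cols is None:
        feature_cols = [c for c in signatures.columns
                        if c not in ("region", "n", "aggregator")
                        and signatures[c].dtype.kind == "f"]
    F = signatures[list(feature_cols)].to_numpy(float)
    if len(F) < 2:
        raise ValueError("need at least two regions")
    if np.isnan(F).any():
        raise ValueError("null fields in the similarity feature columns")
    info: dict = {"method": method, "features": list(feature_cols)}
    if method == "parameter":
        sd = F.std(axis=0)
        if (sd == 0).any():
            dropped = [c for c, s in zip(feature_cols, sd) if s == 0]
            log.warning("dropping constant signature columns: %s", dropped)
            info["dropped"] = dropped
            F = F[:, sd > 0]
            sd = sd[sd > 0]
        Z = (F - F.mean(axis=0)) / sd
        d = squareform(pdist(Z))
        if bandwidth is None:
            bandwidth = float(np.median(d[np.triu_indices_from(d, k=1)]))
        info["bandwidth"] = bandwidth
        S = np.exp(-(d**2) / (2 * bandwidth**2))
    elif method == "subtype_pearson":
        r = np.corrcoef(F)
        info["raw_pearson"] = r
        S = (r + 1.0) / 2.0
    else:
        raise ValueError(f"unknown similarity method {method!r}")
    np.fill_diagonal(S, 1.0)
    return S, ids, info


def upgma_dendrogram(similarity: np.ndarray, ids: list) -> tuple[TreeNode, np.ndarray]:
    """UPGMA (unweighted average linkage) tree on distance 1 - similarity.

    Returns a tree whose leaves are the region ids (serialize with
    ``str(tree)`` for newick) plus the scipy linkage matrix.
    """
    S = np.asarray(similarity, float)
    dist = 1.0 - S
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    tree = TreeNode.from_linkage_matrix(Z, [str(i) for i in ids])
    return tree, Z


def gradient_profile(table: pd.DataFrame, axis: str = "x_nm", n_bins: int = 20,
                     lo: float | None = None, hi: float | None = None,
                     aggregator: str = "median",
                     param_cols=PARAM_COLS) -> pd.DataFrame:
    """1D spatial profile: region_stats along ordered bins of one axis.

    Used to quantify tangential/radial parameter gradients; bins are
    half-open and equal width over [lo, hi).
    """
    coord = table[axis].to_numpy(float)
    lo = coord.min() if lo is None else lo
    hi = coord.max() + 1e-9 if hi is None else hi
    edges = np.linspace(lo, hi, n_bins + 1)
    which = np.clip(np.searchsorted(edges, coord, side="right") - 1, 0, n_bins - 1)
    agg = {"median": np.nanmedian, "mean": np.nanmean}[aggregator]
    rows = []
    for b in range(n_bins):
        sel = which == b
        row = dict(bin=b, center=0.5 * (edges[b] + edges[b + 1]), n=int(sel.sum()))
        for col in param_cols:
            if col in table.columns:
                vals = table.loc[sel, col].to_numpy(float)
                row[col] = float(agg(vals)) if sel.any() and np.isfinite(vals).any() else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
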