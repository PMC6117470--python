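"""Synapse typing and subtype discovery by weighted ensemble clustering (WEC).

Puncta are first assigned one of three major types from two-channel
colocalization: type 1 expresses only the PSD95-like marker, type 2 only
the SAP102-like marker, type 3 both (a colocalized pair counts as one
type-3 synapse).  Within each type, subtypes are discovered without
supervision by a consensus over many base clusterings: eight clustering
methods are each run over a range of cluster counts, every labeling is
scored by eleven cluster-validity indices (min-max normalized over the
pool, orientation harmonized so higher is better), and the mean normalized
validity becomes the labeling's weight.  The weighted co-association matrix

    M_ij = sum_pool w * 1[i, j same cluster] / sum_pool w

is cut by average-linkage hierarchical clustering at the cluster count
whose pool entries carry the highest aggregated validity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.linalg import eigh
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import Birch, KMeans, MiniBatchKMeans
from sklearn.metrics import adjusted_rand_score, silhouette_score
from sklearn.mixture import GaussianMixture

from .puncta import PairingResult

log = logging.getLogger(__name__)

__all__ = [
    "WECConfig",
    "WECResult",
    "assign_types",
    "typed_table",
    "base_clusterings",
    "validity_indices",
    "INDEX_NAMES",
    "wec_cluster",
    "assign_subtypes",
]

BASE_METHODS = ("kmeans", "minibatch_kmeans", "gmm", "ward", "average",
                "complete", "spectral", "birch")

INDEX_NAMES = ("silhouette", "calinski_harabasz", "davies_bouldin_inv", "dunn",
               "xie_beni_inv", "gap", "wss_bss_inv", "pbm", "c_index_inv",
               "point_biserial", "stability")


# ---------------------------------------------------------------- typing

def assign_types(pairing: PairingResult) -> tuple[np.ndarray, np.ndarray]:
    """Per-punctum major types for the two channels.

    Channel-A puncta are type 3 if colocalized else type 1; channel-B
    puncta are type 3 if colocalized else type 2.  Totals are conserved:
    ``|type1| + |pairs| == n_a`` and ``|type2| + |pairs| == n_b``.
    """
    ids_a = pairing.pairs["id_a"].to_numpy(int)
    ids_b = pairing.pairs["id_b"].to_numpy(int)
    if len(ids_a) and (ids_a.max() >= pairing.n_a or ids_b.max() >= pairing.n_b):
        raise ValueError("pairing refers to puncta missing from the tables")
    types_a = np.ones(pairing.n_a, dtype=int)
    types_b = np.full(pairing.n_b, 2, dtype=int)
    types_a[ids_a] = 3
    types_b[ids_b] = 3
    return types_a, types_b


def typed_table(table_a: pd.DataFrame, table_b: pd.DataFrame,
                pairing: PairingResult,
                param_cols: tuple[str, ...] = ("intensity", "size_um2", "skewness",
                                               "kurtosis", "circularity",
                                               "aspect_ratio")) -> pd.DataFrame:
    """One row per synapse with its type and clustering features.

    Type-3 rows (colocalized pairs) carry both puncta's parameters: the
    channel-A columns plus ``partner_``-prefixed channel-B columns, which
    are null for types 1 and 2.
    """
    types_a, types_b = assign_types(pairing)
    a = table_a.reset_index(drop=True).copy()
    b = table_b.reset_index(drop=True).copy()
    a["type"] = types_a
    b["type"] = types_b
    rows = [a[a["type"] == 1], b[b["type"] == 2]]
    if len(pairing.pairs):
        pa = a.loc[pairing.pairs["id_a"].to_numpy(int)].reset_index(drop=True)
        pb = b.loc[pairing.pairs["id_b"].to_numpy(int)].reset_index(drop=True)
        merged = pa.copy()
        merged["type"] = 3
        for c in param_cols:
            if c in pb.columns:
                merged[f"partner_{c}"] = pb[c].to_numpy()
        rows.append(merged)
    out = pd.concat(rows, ignore_index=True)
    out["synapse_id"] = np.arange(len(out))
    return out


# ------------------------------------------------------- base clusterings

@dataclass
class PoolEntry:
    method: str
    k: int
    labels: np.ndarray          # 0-based, length n
    weight: float = np.nan
    indices: dict[str, float] = field(default_factory=dict)


def _spectral_embedding(X: np.ndarray, n_components: int, D: np.ndarray) -> np.ndarray:
    """Normalized-Laplacian embedding with an rbf affinity at the median
    pairwise distance (computed once, reused for every k)."""
    sigma = np.median(D[np.triu_indices_from(D, k=1)])
    sigma = sigma if sigma > 0 else 1.0
    W = np.exp(-(D**2) / (2 * sigma**2))
    np.fill_diagonal(W, 0.0)
    deg = W.sum(axis=1)
    deg[deg == 0] = 1.0
    d_isqrt = 1.0 / np.sqrt(deg)
    L = np.eye(len(X)) - d_isqrt[:, None] * W * d_isqrt[None, :]
    n_components = min(n_components, len(X) - 1)
    _, vec = eigh(L, subset_by_index=[0, n_components - 1])
    return vec


def base_clusterings(X: np.ndarray, methods=BASE_METHODS,
                     k_range=range(1, 31), seed: int = 0,
                     D: np.ndarray | None = None) -> list[PoolEntry]:
    """One labeling per (method, k) pair; pool size = |methods| x |k_range|.

    Entries with k > n, or where a base fit fails to converge on the data,
    are skipped with a log record.  Everything is seed-deterministic.
    ``X`` is expected standardized (z-scored per column).
    """
    X = np.asarray(X, float)
    n = len(X)
    ks = [k for k in k_range]
    pool: list[PoolEntry] = []

    link = {}
    for m in ("ward", "average", "complete"):
        if m in methods:
            link[m] = linkage(X, method=m)
    if "spectral" in methods:
        if D is None:
            D = squareform(pdist(X))
        emb = _spectral_embedding(X, max(2, min(max(ks), n - 1)), D)

    for k in ks:
        if k > n:
            log.info("skipping k=%d > n=%d", k, n)
            continue
        for m in methods:
            try:
                if k == 1:
                    labels = np.zeros(n, dtype=int)
                elif m == "kmeans":
                    labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(X)
                elif m == "minibatch_kmeans":
                    labels = MiniBatchKMeans(n_clusters=k, n_init=3,
                                             random_state=seed).fit_predict(X)
                elif m == "gmm":
                    labels = GaussianMixture(n_components=k, covariance_type="diag",
                                             n_init=1, random_state=seed).fit_predict(X)
                elif m in ("ward", "average", "complete"):
                    labels = fcluster(link[m], k, criterion="maxclust") - 1
                elif m == "spectral":
                    e = emb[:, :max(2, k)]
                    norms = np.linalg.norm(e, axis=1, keepdims=True)
                    e = e / np.where(norms > 0, norms, 1.0)
                    labels = KMeans(n_clusters=k, n_init=3, random_state=seed).fit_predict(e)
                elif m == "birch":
                    labels = Birch(n_clusters=k, threshold=0.5).fit_predict(X)
                else:
                    raise ValueError(f"unknown base method {m!r}")
            except Exception as exc:  # noqa: BLE001 - skip failed base fits
                log.info("base clustering %s k=%d failed: %s", m, k, exc)
                continue
            pool.append(PoolEntry(method=m, k=k, labels=np.asarray(labels, int)))
    return pool


# ------------------------------------------------------- validity indices

def _within_dispersion(X, labels):
    """Sum over clusters of within-cluster sum of squared distances to the
    cluster mean (the k-means objective)."""
    W = 0.0
    for c in np.unique(labels):
        pts = X[labels == c]
        W += ((pts - pts.mean(axis=0)) ** 2).sum()
    return W


def gap_reference_logw(X: np.ndarray, ks, seed: int = 0, n_ref: int = 3) -> dict[int, float]:
    """Expected log within-dispersion of k-means on uniform reference draws
    over the bounding box of X (shared across the pool)."""
    rng = np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)
    out = {}
    refs = [rng.uniform(lo, hi, size=X.shape) for _ in range(n_ref)]
    for k in sorted(set(ks)):
        if k > len(X):
            continue
        vals = []
        for R in refs:
            if k == 1:
                vals.append(np.log(_within_dispersion(R, np.zeros(len(R), int)) + 1e-300))
            else:
                lab = KMeans(n_clusters=k, n_init=1,
                             random_state=seed).fit_predict(R)
                vals.append(np.log(_within_dispersion(R, lab) + 1e-300))
        out[k] = float(np.mean(vals))
    return out


def validity_indices(X: np.ndarray, labels: np.ndarray,
                     D: np.ndarray | None = None,
                     ref_logw: dict[int, float] | None = None,
                     seed: int = 0) -> dict[str, float]:
    """Raw values of the 11 validity indices, orientation harmonized.

    Indices whose natural orientation is lower-is-better (Davies-Bouldin,
    Xie-Beni, WSS/BSS, C-index) are negated.  Indices undefined at k = 1
    are returned as NaN; the pool normalization maps NaN to the pool
    minimum, so only the gap statistic (defined at every k) can argue for
    k = 1.  Min-max normalization to [0, 1] happens across the pool, not
    here.
    """
    X = np.asarray(X, float)
    labels = np.asarray(labels, int)
    n = len(X)
    uniq = np.unique(labels)
    k = len(uniq)
    if D is None:
        D = squareform(pdist(X))
    out = {name: np.nan for name in INDEX_NAMES}

    Wk = _within_dispersion(X, labels)
    if ref_logw is not None and k in ref_logw:
        out["gap"] = ref_logw[k] - np.log(Wk + 1e-300)

    if k == 1 or k >= n:
        return out

    centroids = np.array([X[labels == c].mean(axis=0) for c in uniq])
    sizes = np.array([(labels == c).sum() for c in uniq])
    grand = X.mean(axis=0)
    total_ss = ((X - grand) ** 2).sum()
    bss = total_ss - Wk

    try:
        out["silhouette"] = silhouette_score(D, labels, metric="precomputed")
    except ValueError:
        pass
    if Wk > 0 and bss > 0:
        out["calinski_harabasz"] = (bss / (k - 1)) / (Wk / (n - k))
        out["wss_bss_inv"] = -(Wk / bss)

    # Davies-Bouldin: mean over clusters of max (s_i + s_j)/d_ij
    disp = np.array([
        np.mean(np.linalg.norm(X[labels == c] - centroids[i], axis=1))
        for i, c in enumerate(uniq)])
    cd = squareform(pdist(centroids))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (disp[:, None] + disp[None, :]) / cd
    np.fill_diagonal(ratio, -np.inf)
    out["davies_bouldin_inv"] = -float(np.mean(np.max(ratio, axis=1)))

    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(n, k=1)
    d_flat = D[iu]
    same_flat = same[iu]
    inter = d_flat[~same_flat]
    intra = d_flat[same_flat]
    if len(inter) and len(intra) and intra.max() > 0:
        out["dunn"] = float(inter.min() / intra.max())

    min_cd2 = cd[np.triu_indices(k, k=1)].min() ** 2
    if min_cd2 > 0:
        out["xie_beni_inv"] = -float(Wk / (n * min_cd2))

    # PBM: ((1/k) * (E1/Ek) * Dk)^2 with distances to centroids
    e1 = np.linalg.norm(X - grand, axis=1).sum()
    ek = sum(np.linalg.norm(X[labels == c] - centroids[i], axis=1).sum()
             for i, c in enumerate(uniq))
    dk = cd.max()
    if ek > 0:
        out["pbm"] = float(((e1 * dk) / (k * ek)) ** 2)

    # C-index: (S - Smin) / (Smax - Smin) over within-cluster pair distances
    nw = len(intra)
    if nw and len(d_flat) > nw:
        ds = np.sort(d_flat)
        smin = ds[:nw].sum()
        smax = ds[-nw:].sum()
        if smax > smin:
            out["c_index_inv"] = -float((intra.sum() - smin) / (smax - smin))

    # point-biserial: corr(distance, different-cluster indicator)
    if len(inter) and len(intra):
        ind = (~same_flat).astype(float)
        sd = d_flat.std()
        if sd > 0:
            out["point_biserial"] = float(np.corrcoef(d_flat, ind)[0, 1])

    # stability: ARI between the labeling and its 1-NN transfer from a
    # seeded bootstrap resample
    rng = np.random.default_rng(seed + 7 * k)
    boot = rng.integers(0, n, n)
    nn = boot[np.argmin(D[:, boot], axis=1)]
    out["stability"] = float(adjusted_rand_score(labels, labels[nn]))
    return out


# ----------------------------------------------------------------- WEC

@dataclass
class WECConfig:
    methods: tuple[str, ...] = BASE_METHODS
    k_range: tuple[int, int] = (1, 30)          # inclusive bounds
    max_consensus_n: int = 1000                  # subsample size for the pool
    n_gap_refs: int = 3
    param_cols: tuple[str, ...] | None = None

    @property
    def ks(self) -> range:
        return range(self.k_range[0], self.k_range[1] + 1)


@dataclass
class WECResult:
    """Consensus clustering output.

    ``labels`` are 0-based consensus labels for every input row;
    ``chosen_k`` the selected cluster count; ``index_table`` the per-pool
    normalized validity indices and weights; ``coassoc`` the weighted
    co-association matrix over the (sub)sampled rows ``sample_idx``.
    """

    labels: np.ndarray
    chosen_k: int
    index_table: pd.DataFrame
    coassoc: np.ndarray
    sample_idx: np.ndarray

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))


def _zscore(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    return (X[:, keep] - mu[keep]) / sd[keep]


def wec_cluster(data: pd.DataFrame | np.ndarray, config: WECConfig | None = None,
                seed: int = 0) -> WECResult:
    """Weighted ensemble clustering of one type's punctum parameters.

    Columns are z-scored; the base pool and co-association consensus run on
    a seeded subsample of at most ``max_consensus_n`` rows (the pool's
    pairwise machinery is quadratic), and remaining rows are assigned to
    the nearest consensus-cluster centroid in the standardized space.
    """
    config = config or WECConfig()
    if isinstance(data, pd.DataFrame):
        cols = list(config.param_cols) if config.param_cols else [
            c for c in data.columns
            if data[c].dtype.kind == "f" and data[c].notna().all()]
        X_full = data[cols].to_numpy(float)
    else:
        X_full = np.asarray(data, float)
    n = len(X_full)
    if n < 2:
        raise ValueError("need at least two rows to cluster")
    Xz_full = _zscore(X_full)
    if Xz_full.shape[1] == 0 or len(np.unique(Xz_full, axis=0)) == 1:
        # degenerate: all rows identical
        return WECResult(np.zeros(n, int), 1, pd.DataFrame(), np.ones((1, 1)),
                         np.arange(min(n, 1)))

    rng = np.random.default_rng(seed)
    if n > config.max_consensus_n:
        sample_idx = np.sort(rng.choice(n, config.max_consensus_n, replace=False))
    else:
        sample_idx = np.arange(n)
    X = Xz_full[sample_idx]
    D = squareform(pdist(X))

    pool = base_clusterings(X, methods=config.methods, k_range=config.ks,
                            seed=seed, D=D)
    ref_logw = gap_reference_logw(X, [e.k for e in pool], seed=seed,
                                  n_ref=config.n_gap_refs)
    raw = np.full((len(pool), len(INDEX_NAMES)), np.nan)
    for i, e in enumerate(pool):
        vals = validity_indices(X, e.labels, D=D, ref_logw=ref_logw, seed=seed)
        e.indices = vals
        raw[i] = [vals[name] for name in INDEX_NAMES]

    # min-max normalize each index over the pool; NaN -> pool minimum (0)
    norm = np.zeros_like(raw)
    for j in range(raw.shape[1]):
        col = raw[:, j]
        finite = np.isfinite(col)
        if finite.sum() >= 2 and np.ptp(col[finite]) > 0:
            lo, hi = col[finite].min(), col[finite].max()
            norm[finite, j] = (col[finite] - lo) / (hi - lo)
    weights = norm.mean(axis=1)
    for e, w in zip(pool, weights):
        e.weight = float(w)

    # the cluster count comes from the highest-validity pool results: each
    # k is scored by the best weight any base method achieved at that k
    ks = np.array([e.k for e in pool])
    k_scores = {k: weights[ks == k].max() for k in np.unique(ks)}
    chosen_k = int(max(k_scores, key=lambda k: (k_scores[k], -k)))

    # weighted co-association over the sample
    m = len(X)
    M = np.zeros((m, m))
    wsum = 0.0
    for e, w in zip(pool, weights):
        if w <= 0:
            continue
        M += w * (e.labels[:, None] == e.labels[None, :])
        wsum += w
    M /= max(wsum, 1e-300)
    np.fill_diagonal(M, 1.0)

    cons_link = linkage(squareform(1.0 - M, checks=False), method="average")
    sample_labels = fcluster(cons_link, chosen_k, criterion="maxclust") - 1

    labels = np.empty(n, dtype=int)
    labels[sample_idx] = sample_labels
    rest = np.setdiff1d(np.arange(n), sample_idx)
    if len(rest):
        cents = np.array([X[sample_labels == c].mean(axis=0)
                          for c in np.unique(sample_labels)])
        d = ((Xz_full[rest, None, :] - cents[None, :, :]) ** 2).sum(axis=2)
        labels[rest] = np.unique(sample_labels)[np.argmin(d, axis=1)]

    index_table = pd.DataFrame(norm, columns=list(INDEX_NAMES))
    index_table.insert(0, "method", [e.method for e in pool])
    index_table.insert(1, "k", ks)
    index_table["weight"] = weights
    return WECResult(labels=labels, chosen_k=chosen_k, index_table=index_table,
                     coassoc=M, sample_idx=sample_idx)


def assign_subtypes(wec_by_type: dict[int, WECResult | np.ndarray]) -> dict[int, np.ndarray]:
    """Global subtype indices 1..K from per-type consensus labels.

    Blocks are ordered type 1, then 2, then 3; within a type, subtypes are
    numbered by descending population.  Returns per-type arrays of global
    subtype indices aligned with each type's rows.
    """
    out: dict[int, np.ndarray] = {}
    offset = 0
    for t in sorted(wec_by_type):
        res = wec_by_type[t]
        labels = res.labels if isinstance(res, WECResult) else np.asarray(res, int)
        uniq, counts = np.unique(labels, return_counts=True)
        order = uniq[np.argsort(-counts, kind="stable")]
        remap = {c: offset + r + 1 for r, c in enumerate(order)}
        out[t] = np.array([remap[c] for c in labels])
        offset += len(uniq)
    return out
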