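"""tSNE embedding, elbow-based k selection, and k-means partitioning.

The evaluated feature table (features only — metadata never reaches the
embedding) is mapped to 2-D with tSNE, the within-cluster sum of squares
(WSS) is measured for a range of k, an exponential decay a·exp(−k/τ)+c is
fit to the WSS curve, and the cluster count is taken at 4τ — the point
where the decay has plateaued ("elbow").  k-means at that k partitions the
embedding, and composition tables cross the clusters with rearing
condition and cortical region; a (condition, cluster) pair with enough
members forms a subcluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE

from .expression_io import PhenoplastError
from .features import FeatureTable


@dataclass
class Embedding:
    coords: np.ndarray  # n x 2
    perplexity: float
    max_iter: int
    seed: int
    sample_keys: pd.DataFrame | None = None
    backend: str = "sklearn.manifold.TSNE"


@dataclass
class WSSCurve:
    k_values: np.ndarray  # ascending ints, starting at 1
    wss: np.ndarray


@dataclass
class ElbowFit:
    a: float
    c: float
    tau: float
    k_star: int
    rss: float


@dataclass
class ClusterAssignment:
    sample_keys: pd.DataFrame
    labels: np.ndarray  # cluster ids 1..k
    k: int
    seed: int
    subcluster: pd.Series | None = None


def embed_tsne(
    features: FeatureTable,
    perplexity: float = 25.0,
    max_iter: int = 5000,
    seed: int = 0,
) -> Embedding:
    """2-D tSNE of the feature columns only; deterministic given the seed."""
    X = features.feature_matrix()
    if np.isnan(X).any():
        raise PhenoplastError("feature table has missing values; tSNE needs complete rows")
    n = X.shape[0]
    if n <= 3 * perplexity:
        raise PhenoplastError(
            f"perplexity {perplexity} too large for n={n}; need n > 3*perplexity"
        )
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        max_iter=max_iter,
        random_state=seed,
        init="pca",
    )
    coords = tsne.fit_transform(X)
    return Embedding(
        coords=np.asarray(coords, dtype=float),
        perplexity=perplexity,
        max_iter=max_iter,
        seed=seed,
        sample_keys=features.data[features.metadata_fields].copy(),
    )


def _total_ss(coords: np.ndarray) -> float:
    """Total centered sum of squares, the k=1 WSS ((n−1)·Σ column variances)."""
    centered = coords - coords.mean(axis=0)
    return float((centered**2).sum())


def wss_curve(
    embedding: Embedding,
    k_min: int = 2,
    k_max: int = 15,
    seed: int = 0,
    n_restarts: int = 25,
) -> WSSCurve:
    """Within-cluster sum of squares for k = 1 and k_min..k_max.

    The k=1 entry is the total centered sum of squares in closed form; each
    other k runs k-means with ``n_restarts`` k-means++ restarts and records
    the best inertia.
    """
    coords = embedding.coords
    if k_max >= coords.shape[0]:
        raise PhenoplastError("k_max must be below the sample count")
    ks = [1] + list(range(k_min, k_max + 1))
    wss = [_total_ss(coords)]
    for k in range(k_min, k_max + 1):
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(coords)
        wss.append(float(km.inertia_))
    return WSSCurve(k_values=np.asarray(ks), wss=np.asarray(wss))


def elbow_k(curve: WSSCurve, k_min: int | None = None, k_max: int | None = None) -> ElbowFit:
    """Fit WSS(k) ≈ a·exp(−k/τ) + c and return k* = round(4τ), clamped.

    Rounding is half-away-from-zero; the clamp range defaults to the
    searched k range.  A non-decaying curve (fit failure or τ at its bound
    with a ≤ 0) raises, recommending a manual k.
    """
    ks = np.asarray(curve.k_values, dtype=float)
    wss = np.asarray(curve.wss, dtype=float)
    if len(ks) < 4:
        raise PhenoplastError("elbow fit needs at least 4 curve points")
    lo = int(k_min if k_min is not None else ks.min())
    hi = int(k_max if k_max is not None else ks.max())

    def model(k, a, c, tau):
        return a * np.exp(-k / tau) + c

    drop = float(wss[0] - wss.min())
    if drop <= 1e-12 * max(abs(wss).max(), 1.0):
        raise PhenoplastError("WSS curve does not decay; supply k manually")
    c0 = float(wss.min())
    a0 = max(float(wss[0] - c0), 1e-9)
    tau0 = max((hi - lo) / 4.0, 0.5)
    try:
        popt, _ = curve_fit(
            model, ks, wss,
            p0=[a0, c0, tau0],
            bounds=([0.0, -np.inf, 1e-6], [np.inf, np.inf, float(hi)]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise PhenoplastError(
            f"exponential-decay fit failed ({exc}); supply k manually"
        ) from None
    a, c, tau = (float(v) for v in popt)
    if a <= 0:
        raise PhenoplastError("WSS curve does not decay; supply k manually")
    rss = float(np.sum((model(ks, a, c, tau) - wss) ** 2))
    k_star = int(np.floor(4 * tau + 0.5))  # half-away-from-zero for positive tau
    k_star = int(np.clip(k_star, lo, hi))
    return ElbowFit(a=a, c=c, tau=tau, k_star=k_star, rss=rss)


def kmeans_partition(
    embedding: Embedding,
    k: int,
    seed: int = 0,
    n_restarts: int = 25,
    max_retries: int = 5,
) -> ClusterAssignment:
    """k-means on the embedding, best of ``n_restarts`` k-means++ starts.

    Empty clusters after convergence trigger a reseeded retry, up to
    ``max_retries`` times.
    """
    coords = embedding.coords
    n = coords.shape[0]
    if not (1 < k < n):
        raise PhenoplastError(f"k must satisfy 1 < k < n={n}, got {k}")
    for attempt in range(max_retries):
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed + attempt).fit(coords)
        labels = km.labels_ + 1
        if len(np.unique(labels)) == k:
            keys = embedding.sample_keys
            if keys is None:
                keys = pd.DataFrame(index=range(n))
            return ClusterAssignment(
                sample_keys=keys.reset_index(drop=True),
                labels=labels,
                k=k,
                seed=seed + attempt,
            )
    raise PhenoplastError(f"k-means left an empty cluster after {max_retries} retries")


def compose_clusters(
    assignment: ClusterAssignment,
    condition_field: str = "condition",
    region_field: str = "region",
    min_size: int = 2,
) -> dict[str, pd.DataFrame]:
    """Cluster composition tables and subcluster labels.

    Returns counts per (cluster × condition) and (cluster × region), plus a
    per-sample table whose ``subcluster`` column labels each sample's
    (condition, cluster) pair when that pair has at least ``min_size``
    members (smaller pairs get no subcluster).
    """
    keys = assignment.sample_keys.copy()
    keys["cluster"] = assignment.labels
    out: dict[str, pd.DataFrame] = {}
    for name, fld in (("condition", condition_field), ("region", region_field)):
        if fld in keys.columns:
            out[f"by_{name}"] = (
                keys.groupby(["cluster", fld]).size().unstack(fill_value=0)
            )
    if condition_field in keys.columns:
        pair = keys[condition_field].astype(str) + " | cluster " + keys["cluster"].astype(str)
        sizes = pair.value_counts()
        keys["subcluster"] = pair.where(pair.map(sizes) >= min_size)
        assignment.subcluster = keys["subcluster"]
    out["samples"] = keys
    return out
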