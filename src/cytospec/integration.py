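"""Batch-effect assessment and correction for merged multi-sample data.

The stage mirrors the standard single-cell integration recipe applied to
cytometry channel data: per-channel scaling to a symmetric [-1, 1] range,
PCA to a small number of components (default 20), an optional soft-k-means
batch corrector in PC space, a 2-D UMAP embedding, and the local inverse
Simpson index (LISI) as the mixing metric.

LISI measures the effective number of batches in each cell's embedding
neighborhood: a Gaussian kernel over the cell's k nearest neighbors is tuned
so its entropy matches log(perplexity); the kernel mass per batch gives
probabilities p_b, and LISI = 1 / sum_b p_b^2, ranging from 1 (the cell sits
in a single-batch region) to B, the number of batches (perfect mixing).

The decision rule: cells with LISI above a threshold (2 for three batches,
1.667 for two) are "high-LISI" (well-integrated); if the fraction of
high-LISI cells is small (< 20%), the embedding is batch-dominated and
correction is warranted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .fcs_io import EventMatrix, append_parameters

__all__ = [
    "IntegrationConfig",
    "Embedding",
    "LISIResult",
    "scale_channels",
    "pca_embed",
    "batch_correct",
    "embed_umap",
    "compute_lisi",
    "recommend_correction",
]

#: High-LISI thresholds stated for two- and three-batch analyses.  Other
#: batch counts require an explicit threshold.
HIGH_LISI_THRESHOLDS = {2: 1.667, 3: 2.0}


@dataclass(frozen=True)
class IntegrationConfig:
    """Tunable parameters of the integration stage."""

    n_components: int = 20
    perplexity: float = 30.0
    neighbors_k: Optional[int] = None          # default 3 x perplexity
    high_lisi_threshold: Optional[float] = None  # default from batch count
    recommend_below_fraction: float = 0.20
    backend: str = "reference"                 # or "external" (harmonypy)
    n_clusters: int = 20
    temperature: float = 1.0
    max_iterations: int = 10
    lisi_gain_tol: float = 0.01
    umap_neighbors: int = 15
    umap_min_dist: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_components < 2:
            raise ValueError("n_components must be >= 2")
        if not 0 < self.recommend_below_fraction < 1:
            raise ValueError("recommend_below_fraction must lie in (0, 1)")

    @property
    def k(self) -> int:
        return self.neighbors_k if self.neighbors_k is not None else int(3 * self.perplexity)

    def threshold_for(self, n_batches: int) -> float:
        if self.high_lisi_threshold is not None:
            return self.high_lisi_threshold
        try:
            return HIGH_LISI_THRESHOLDS[n_batches]
        except KeyError:
            raise ValueError(
                f"no default high-LISI threshold for {n_batches} batches; "
                "set IntegrationConfig.high_lisi_threshold explicitly"
            ) from None


@dataclass
class Embedding:
    """Events x d coordinate matrix with a space tag ('pca', 'corrected', 'umap')."""

    coordinates: np.ndarray
    space: str

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2:
            raise ValueError("coordinates must be 2-D")

    @property
    def n_events(self) -> int:
        return self.coordinates.shape[0]


@dataclass
class LISIResult:
    """Per-cell LISI scores with the high-LISI summary and recommendation."""

    lisi: np.ndarray
    n_batches: int
    threshold: Optional[float] = None
    high_fraction: Optional[float] = None
    per_batch_high_fraction: dict[str, float] = field(default_factory=dict)
    recommendation: Optional[str] = None       # "correct" | "no-correction"


def scale_channels(events: EventMatrix, channels: Optional[Sequence[str]] = None) -> EventMatrix:
    """Scale each channel to be centered around 0 with a range from -1 to 1.

    Min-max mapping ``x -> -1 + 2 (x - min) / (max - min)``: the channel's
    range becomes exactly [-1, 1], centered on 0.  Constant channels map to
    all-zero with a warning.  Requires >= 2 events.
    """
    if events.n_events < 2:
        raise ValueError("need >= 2 events to scale")
    values = events.values.copy()
    idx = (
        [events.index_of(c) for c in channels]
        if channels is not None
        else list(range(events.n_channels))
    )
    constant = []
    for i in idx:
        col = values[:, i]
        lo, hi = col.min(), col.max()
        if hi == lo:
            constant.append(events.channel_names[i])
            values[:, i] = 0.0
        else:
            values[:, i] = -1.0 + 2.0 * (col - lo) / (hi - lo)
    if constant:
        warnings.warn(f"constant channel(s) scaled to zero: {constant}", stacklevel=2)
    return replace(events, values=values)


def pca_embed(scaled: EventMatrix, cfg: IntegrationConfig = IntegrationConfig()) -> Embedding:
    """Top-n principal-component scores of the scaled channel matrix.

    Deterministic: uses a full SVD and fixes each component's sign so that
    its largest-magnitude loading is positive.
    """
    from sklearn.decomposition import PCA

    n = min(cfg.n_components, scaled.n_channels)
    if cfg.n_components > scaled.n_channels:
        raise ValueError(
            f"n_components={cfg.n_components} exceeds channel count {scaled.n_channels}"
        )
    pca = PCA(n_components=n, svd_solver="full")
    scores = pca.fit_transform(scaled.values)
    # sign convention: largest-|loading| positive
    for j in range(n):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] = -scores[:, j]
    return Embedding(coordinates=scores, space="pca")


def _soft_kmeans_correct(
    Z: np.ndarray, batch_idx: np.ndarray, n_batches: int, cfg: IntegrationConfig,
    n_clusters: int,
) -> np.ndarray:
    """One corrector pass: soft k-means, then subtract per-cluster batch offsets.

    With ``n_clusters=1`` this reduces to global per-batch mean centering,
    which is the corrector's first pass: when batches are fully segregated,
    k-means clusters are batch-pure and per-cluster offsets vanish, so the
    global pass is what brings the batches into contact before the
    cluster-resolved passes refine per-cell-type offsets.
    """
    from sklearn.cluster import KMeans

    k = min(n_clusters, max(1, Z.shape[0] // 10))
    if k == 1:
        R = np.ones((Z.shape[0], 1))
    else:
        km = KMeans(n_clusters=k, n_init=3, random_state=cfg.seed)
        km.fit(Z)
        d2 = ((Z[:, None, :] - km.cluster_centers_[None, :, :]) ** 2).sum(axis=2)
        d2 = d2 - d2.min(axis=1, keepdims=True)
        R = np.exp(-d2 / max(cfg.temperature, 1e-9))
        R = R / R.sum(axis=1, keepdims=True)
    k = R.shape[1]

    correction = np.zeros_like(Z)
    for c in range(k):
        w = R[:, c]
        tot = w.sum()
        if tot < 1e-9:
            continue
        centroid = (w[:, None] * Z).sum(axis=0) / tot
        for b in range(n_batches):
            sel = batch_idx == b
            wb = w[sel]
            tb = wb.sum()
            if tb < 1e-9:
                continue
            offset = (wb[:, None] * Z[sel]).sum(axis=0) / tb - centroid
            correction[sel] += w[sel, None] * offset[None, :]
    return Z - correction


def batch_correct(
    pcs: Embedding, batches: Sequence[str], cfg: IntegrationConfig = IntegrationConfig()
) -> Embedding:
    """Remove per-batch displacement in PC space.

    ``backend="reference"`` runs the built-in corrector: iterate soft k-means
    assignment, per-cluster per-batch centroid offsets, and
    assignment-weighted subtraction until the mean-LISI gain drops below
    ``lisi_gain_tol`` or ``max_iterations`` is reached.  A single batch is
    returned unchanged.  ``backend="external"`` delegates to harmonypy when
    installed.
    """
    batches = np.asarray(batches)
    if batches.shape[0] != pcs.n_events:
        raise ValueError("one batch label per event required")
    uniq, batch_idx = np.unique(batches, return_inverse=True)
    n_batches = len(uniq)
    if n_batches == 1:
        return Embedding(pcs.coordinates.copy(), space="corrected")
    counts = np.bincount(batch_idx)
    small = [str(uniq[i]) for i in np.flatnonzero(counts < pcs.coordinates.shape[1])]
    if small:
        raise ValueError(f"batch(es) smaller than the embedding dimension: {small}")

    if cfg.backend == "external":
        try:
            import harmonypy
        except ImportError as exc:
            raise RuntimeError(
                "backend='external' requires the harmonypy package; install it "
                "or use backend='reference'"
            ) from exc
        import pandas as pd

        meta = pd.DataFrame({"batch": batches})
        ho = harmonypy.run_harmony(pcs.coordinates, meta, ["batch"], random_state=cfg.seed)
        return Embedding(ho.Z_corr.T, space="corrected")

    if cfg.backend != "reference":
        raise ValueError(f"unknown backend {cfg.backend!r}")

    Z = pcs.coordinates.copy()
    mean_lisi = compute_lisi(Embedding(Z, "pca"), batches, cfg).lisi.mean()
    for it in range(cfg.max_iterations):
        k = 1 if it == 0 else cfg.n_clusters
        Z_new = _soft_kmeans_correct(Z, batch_idx, n_batches, cfg, n_clusters=k)
        new_mean = compute_lisi(Embedding(Z_new, "pca"), batches, cfg).lisi.mean()
        if new_mean < mean_lisi:   # never accept a mixing regression
            break
        Z = Z_new
        if it > 0 and new_mean - mean_lisi < cfg.lisi_gain_tol:
            mean_lisi = new_mean
            break
        mean_lisi = new_mean
    return Embedding(Z, space="corrected")


def embed_umap(
    pcs: Embedding, cfg: IntegrationConfig = IntegrationConfig(),
    events: Optional[EventMatrix] = None,
) -> Embedding | tuple[Embedding, EventMatrix]:
    """2-D UMAP of the (corrected) PC scores, deterministic per seed.

    When ``events`` is given, the coordinates are also appended to it as
    derived channels ``UMAP_1`` / ``UMAP_2`` and the widened matrix returned
    alongside the embedding.
    """
    import umap

    if pcs.n_events < 10:
        raise ValueError("need >= 10 events for a UMAP embedding")
    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=min(cfg.umap_neighbors, pcs.n_events - 1),
        min_dist=cfg.umap_min_dist,
        random_state=cfg.seed,
    )
    coords = np.asarray(reducer.fit_transform(pcs.coordinates), dtype=float)
    emb = Embedding(coords, space="umap")
    if events is not None:
        widened = append_parameters(events, coords, ["UMAP_1", "UMAP_2"])
        return emb, widened
    return emb


def _tuned_kernel(dist: np.ndarray, perplexity: float, tol: float = 1e-5) -> np.ndarray:
    """Row-wise Gaussian kernel with bandwidth tuned to entropy log(perplexity)."""
    n, k = dist.shape
    target = np.log(min(perplexity, k))
    P = np.empty_like(dist)
    d2 = dist**2
    for i in range(n):
        row = d2[i]
        if row.max() - row.min() < 1e-12:
            P[i] = 1.0 / k
            continue
        beta_lo, beta_hi, beta = 0.0, np.inf, 1.0 / (row.mean() + 1e-12)
        for _ in range(64):
            w = np.exp(-beta * (row - row.min()))
            s = w.sum()
            p = w / s
            h = -(p * np.log(np.clip(p, 1e-300, None))).sum()
            if abs(h - target) < tol:
                break
            if h > target:      # kernel too flat -> sharpen
                beta_lo = beta
                beta = beta * 2 if not np.isfinite(beta_hi) else 0.5 * (beta_lo + beta_hi)
            else:
                beta_hi = beta
                beta = 0.5 * (beta_lo + beta_hi)
        P[i] = w / s
    return P


def compute_lisi(
    embedding: Embedding, batches: Sequence[str],
    cfg: IntegrationConfig = IntegrationConfig(),
) -> LISIResult:
    """Per-cell local inverse Simpson index over batch labels.

    For each cell, a perplexity-tuned Gaussian kernel over its k nearest
    neighbors (k = 3 x perplexity) yields batch probabilities
    p_b; LISI = 1 / sum p_b^2 lies in [1, B].  A cell whose neighborhood is
    uniformly mixed across B batches scores B; a cell in a single-batch
    region scores 1.
    """
    from sklearn.neighbors import NearestNeighbors

    batches = np.asarray(batches)
    if batches.shape[0] != embedding.n_events:
        raise ValueError("one batch label per event required")
    uniq, batch_idx = np.unique(batches, return_inverse=True)
    B = len(uniq)
    n = embedding.n_events
    if B == 1:
        return LISIResult(lisi=np.ones(n), n_batches=1)

    k = cfg.k
    if k >= n:
        warnings.warn(f"k={k} >= n={n}; reducing to {n - 1}", stacklevel=2)
        k = n - 1
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding.coordinates)
    dist, idx = nn.kneighbors(embedding.coordinates)
    dist, idx = dist[:, 1:], idx[:, 1:]     # drop self

    P = _tuned_kernel(dist, cfg.perplexity)
    onehot = np.eye(B)[batch_idx[idx]]      # n x k x B
    p_batch = np.einsum("nk,nkb->nb", P, onehot)
    p_batch = p_batch / p_batch.sum(axis=1, keepdims=True)
    lisi = 1.0 / np.square(p_batch).sum(axis=1)
    lisi = np.clip(lisi, 1.0, float(B))
    return LISIResult(lisi=lisi, n_batches=B)


def recommend_correction(
    lisi: LISIResult, batches: Sequence[str],
    cfg: IntegrationConfig = IntegrationConfig(),
) -> LISIResult:
    """Apply the high-LISI decision rule to a pre-correction embedding's scores.

    high_fraction = fraction of cells whose LISI exceeds the batch-count
    threshold (>2 for three batches, >1.667 for two); correction is
    recommended iff high_fraction < ``recommend_below_fraction`` (default
    20%) — i.e. when few cells are well-integrated, the embedding is
    batch-dominated and correcting it is worthwhile.
    """
    batches = np.asarray(batches)
    thr = cfg.threshold_for(lisi.n_batches)
    high = lisi.lisi > thr
    frac = float(high.mean()) if high.size else 0.0
    per_batch = {
        str(b): float(high[batches == b].mean()) if np.any(batches == b) else 0.0
        for b in np.unique(batches)
    }
    return LISIResult(
        lisi=lisi.lisi,
        n_batches=lisi.n_batches,
        threshold=thr,
        high_fraction=frac,
        per_batch_high_fraction=per_batch,
        recommendation="correct" if frac < cfg.recommend_below_fraction else "no-correction",
    )
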