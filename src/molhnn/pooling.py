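"""Interest-point pooling: fixed-size readout for variable-size hypergraphs.

After message passing, the vertex and hyperedge representations of a
conformation are flattened (vertex rows in index order, then hyperedge
rows in the canonical kind/lexicographic order) into one vector ``x``.
A set of *points of interest* — K-means centroids of flattened training
representations — provides fixed reference vectors ``p_i``.  Because
``x`` and ``p_i`` may have different lengths (different molecules!),
similarity is computed with a cosine sliding window whose size equals
the shorter of the two vectors, moving with step 1 along the longer
one.  Per point of interest the window similarities are reduced to
(min, mean, max), giving a 3k-vector fed to a linear + sigmoid head
that outputs the probability of the low free-energy class.

Windows (or a shorter vector) of zero norm get similarity 0 by
convention, keeping every entry in [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve
from sklearn.cluster import KMeans

from .autodiff import Tensor
from .hmpnn import LayerState, LinearMap, _sigmoid, _is_tensor

__all__ = [
    "PointOfInterestSet", "flatten_representation", "flatten_batch",
    "select_points_of_interest", "sliding_similarity", "pool", "pool_batch",
    "classify", "refresh_points_of_interest", "equal_length_pooled",
]


@dataclass
class PointOfInterestSet:
    """K-means centroids of flattened reference representations."""

    P: np.ndarray   # (k, L)

    @property
    def k(self) -> int:
        return self.P.shape[0]

    def __iter__(self):
        return iter(self.P)


def flatten_representation(state: LayerState) -> np.ndarray:
    """Concatenate all vertex then hyperedge features into one vector.

    Accepts a batched state ((B, V, d) / (B, E, d)) and then returns a
    (B, V*d + E*d) matrix; the canonical hyperedge order of the
    representation module makes the layout deterministic.
    """
    X = state.X.data if _is_tensor(state.X) else np.asarray(state.X)
    W = state.W.data if _is_tensor(state.W) else np.asarray(state.W)
    if X.ndim == 2:
        return np.concatenate([X.ravel(), W.ravel()])
    return flatten_batch(X, W)


def flatten_batch(X: np.ndarray, W: np.ndarray) -> np.ndarray:
    b = X.shape[0]
    return np.concatenate(
        [X.reshape(b, -1), W.reshape(b, -1)], axis=1
    )


def select_points_of_interest(reps: np.ndarray, k: int,
                              seed: int = 0) -> PointOfInterestSet:
    """K-means centroids of the (n, L) representation matrix.

    Deterministic for a given seed; requires at least k distinct rows.
    """
    reps = np.asarray(reps, dtype=np.float64)
    if reps.ndim != 2:
        raise ValueError("reps must be a 2-D (n, L) matrix")
    # deduplicate with multiplicity weights: repeated conformations then
    # provably cannot move the centroids
    uniq, counts = np.unique(reps, axis=0, return_counts=True)
    if k < 1 or k > uniq.shape[0]:
        raise ValueError(
            f"k must be in [1, {uniq.shape[0]}] (distinct representations), "
            f"got {k}"
        )
    km = KMeans(n_clusters=k, n_init=4, max_iter=300,
                random_state=seed).fit(uniq, sample_weight=counts)
    return PointOfInterestSet(P=km.cluster_centers_.astype(np.float64))


def _window_norms(long: np.ndarray, s: int) -> np.ndarray:
    """Euclidean norms of all step-1 windows of size s (via cumulative sums)."""
    sq = np.concatenate([[0.0], np.cumsum(long * long)])
    return np.sqrt(np.maximum(sq[s:] - sq[:-s], 0.0))


def sliding_similarity(x: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Cosine similarity of the shorter vector against every step-1 window
    of the longer one; zero-norm windows contribute 0."""
    x = np.asarray(x, dtype=np.float64).ravel()
    p = np.asarray(p, dtype=np.float64).ravel()
    if x.size == 0 or p.size == 0:
        raise ValueError("sliding_similarity needs non-empty vectors")
    short, long = (x, p) if x.size <= p.size else (p, x)
    dots = np.correlate(long, short, mode="valid")
    denom = _window_norms(long, short.size) * np.linalg.norm(short)
    out = np.zeros_like(dots)
    ok = denom > 0
    out[ok] = dots[ok] / denom[ok]
    return np.clip(out, -1.0, 1.0)


def pool(x: np.ndarray, P: PointOfInterestSet | np.ndarray) -> np.ndarray:
    """(min, mean, max) of the window similarities per point of interest.

    Returns the length-3k pooled vector l with l[3i] <= l[3i+1] <= l[3i+2].
    """
    points = P.P if isinstance(P, PointOfInterestSet) else np.asarray(P)
    if points.ndim == 1:
        points = points[None, :]
    if points.shape[0] == 0:
        raise ValueError("pooling needs at least one point of interest")
    out = np.empty(3 * points.shape[0])
    for i, p in enumerate(points):
        v = sliding_similarity(x, p)
        out[3 * i: 3 * i + 3] = (v.min(), v.mean(), v.max())
    return out


def pool_batch(reps: np.ndarray, P: PointOfInterestSet | np.ndarray) -> np.ndarray:
    """Pooled vectors for many flattened representations of one system.

    All points of interest share one sliding-window matrix per input, so
    each conformation costs a single (n_windows x s) @ (s x k) product.
    """
    points = P.P if isinstance(P, PointOfInterestSet) else np.asarray(P)
    reps = np.asarray(reps, dtype=np.float64)
    n, L = reps.shape
    k, Lp = points.shape
    out = np.empty((n, 3 * k))
    if L == Lp:
        # degenerate single-window case: plain cosine similarity
        dots = reps @ points.T
        denom = np.linalg.norm(reps, axis=1)[:, None] * \
            np.linalg.norm(points, axis=1)[None, :]
        cos = np.zeros_like(dots)
        np.divide(dots, denom, out=cos, where=denom > 0)
        cos = np.clip(cos, -1.0, 1.0)
        out[:, 0::3] = cos
        out[:, 1::3] = cos
        out[:, 2::3] = cos
        return out
    if L > Lp:
        # FFT correlation: one batched convolution per conformation covers
        # all points of interest (~1e-13 relative error on the cosines)
        pnorm = np.linalg.norm(points, axis=1)
        prev = points[:, ::-1]
        for i in range(n):
            dots = fftconvolve(reps[i][None, :], prev, mode="valid",
                               axes=1).T                # (n_win, k)
            wnorms = _window_norms(reps[i], Lp)
            denom = wnorms[:, None] * pnorm[None, :]
            cos = np.zeros_like(dots)
            np.divide(dots, denom, out=cos, where=denom > 0)
            cos = np.clip(cos, -1.0, 1.0)
            out[i, 0::3] = cos.min(axis=0)
            out[i, 1::3] = cos.mean(axis=0)
            out[i, 2::3] = cos.max(axis=0)
        return out
    for i in range(n):                                   # |x| < |p|: roles swap
        out[i] = pool(reps[i], points)
    return out


def classify(l, head: LinearMap):
    """Probability of the low free-energy class from the pooled vector."""
    if head.d_in != np.shape(l)[-1]:
        raise ValueError(
            f"head expects {head.d_in} pooled features, got {np.shape(l)[-1]}"
        )
    logit = head(l)
    p = _sigmoid(logit)
    if _is_tensor(p):
        return p
    return np.asarray(p)[..., 0] if np.ndim(p) else float(p)


def equal_length_pooled(reps: Tensor, points: np.ndarray) -> Tensor:
    """Differentiable pooled features when |x| == |p| (training system).

    With equal lengths the sliding window is the whole vector, so
    min = mean = max = cosine(x, p_i); the 3k layout is kept so the same
    head applies unchanged to cross-size inputs at prediction time.
    """
    k = points.shape[0]
    dots = reps @ points.T                               # (B, k)
    rnorm = ((reps * reps).sum(axis=-1, keepdims=True)) ** 0.5
    pnorm = np.linalg.norm(points, axis=1)[None, :]
    cos = dots / (rnorm * pnorm)
    expand = np.zeros((k, 3 * k))
    for i in range(k):
        expand[i, 3 * i: 3 * i + 3] = 1.0
    return cos @ expand


def refresh_points_of_interest(reps: np.ndarray, k: int,
                               seed: int = 0) -> PointOfInterestSet:
    """Recompute centroids from current-parameter representations.

    Called on a schedule during training (the layer parameters move, so
    the reference representations drift); reuses the same K-means seed,
    making the refresh deterministic.
    """
    return select_points_of_interest(reps, k, seed)
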