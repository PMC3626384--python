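"""Fuzzy C-means refinement of the initial ventilation mask.

Pixel intensities inside the initial (noise-subtracted) mask are partitioned
into four ventilation classes — negligible, low, intermediate, high — by
fuzzy C-means (FCM) on the 1-D intensity axis.  Memberships follow the
Bezdek update

    u_ik = 1 / sum_j (D_ik / D_jk)^(2/(m-1)),      D_ik = |x_k - c_i|,

centres are the fuzzy-weighted means c_i = sum_k u_ik^m x_k / sum_k u_ik^m,
and the iteration alternates the two until the largest membership change
drops below ``epsilon``.  The recorded objective is

    J_m = sum_i sum_k u_ik^m D_ik^2,

the quantity the alternating updates monotonically decrease.  After
convergence, centres are sorted ascending and named negligible < low <
intermediate < high; pixels whose hardened (argmax) class is *negligible*
are returned to the background, refining the mask.

A K-means backend (hard assignments, same cost function) is selectable and
coincides with hardened FCM on well-separated data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .image_io import ImageStack, MaskStack

CLASS_NAMES = ("negligible", "low", "intermediate", "high")

# label-map codes: 0 background, 1..4 = negligible..high
BACKGROUND = 0

__all__ = [
    "ClusterModel",
    "fcm_cluster",
    "kmeans_cluster",
    "exact_membership",
    "refine_mask",
    "cluster_stack",
    "CLASS_NAMES",
]


@dataclass(frozen=True)
class ClusterModel:
    """Fitted intensity-clustering model over N masked pixels.

    ``centers`` are sorted ascending (index 0 = negligible ventilation);
    ``memberships`` is the C x N membership matrix in the same (sorted)
    order; ``labels`` holds each pixel's argmax class index 0..C-1.
    """

    n_clusters: int
    fuzziness: float
    centers: np.ndarray
    memberships: np.ndarray
    labels: np.ndarray
    objective_trace: np.ndarray
    n_iter: int
    converged: bool

    @property
    def class_names(self) -> tuple[str, ...]:
        if self.n_clusters == len(CLASS_NAMES):
            return CLASS_NAMES
        return tuple(f"class_{i}" for i in range(self.n_clusters))

    def objective(self, values: np.ndarray) -> float:
        """Re-evaluate J_m = sum u^m D^2 at the stored (u, c)."""
        d2 = (np.asarray(values)[np.newaxis, :] - self.centers[:, np.newaxis]) ** 2
        return float(np.sum(self.memberships**self.fuzziness * d2))


def exact_membership(x: float, centers: np.ndarray, m: float = 2.0) -> np.ndarray:
    """Closed-form membership of a single intensity in each cluster.

    If ``x`` coincides with one or more centres, membership is split among
    the coincident centres (singleton rule; 1 for a unique match).
    """
    centers = np.asarray(centers, dtype=float)
    d = np.abs(x - centers)
    if np.any(d == 0):
        u = (d == 0).astype(float)
        return u / u.sum()
    ratio = (d[:, np.newaxis] / d[np.newaxis, :]) ** (2.0 / (m - 1.0))
    return 1.0 / ratio.sum(axis=1)


def _memberships(values: np.ndarray, centers: np.ndarray, m: float) -> np.ndarray:
    """Vectorised Bezdek memberships, C x N, with the zero-distance rule."""
    d = np.abs(values[np.newaxis, :] - centers[:, np.newaxis])  # C x N
    zero = d == 0
    hit = zero.any(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = d ** (-2.0 / (m - 1.0))
        u = inv / inv.sum(axis=0)
    if hit.any():
        u[:, hit] = zero[:, hit] / zero[:, hit].sum(axis=0)
    return u


def _objective(values: np.ndarray, centers: np.ndarray, u: np.ndarray, m: float) -> float:
    d2 = (values[np.newaxis, :] - centers[:, np.newaxis]) ** 2
    return float(np.sum(u**m * d2))


def fcm_cluster(
    values: np.ndarray,
    n_clusters: int = 4,
    fuzziness: float = 2.0,
    epsilon: float = 1e-5,
    max_iter: int = 100,
    seed: int = 0,
    init_centers: np.ndarray | None = None,
    n_init: int = 5,
) -> ClusterModel:
    """Fuzzy C-means on a 1-D intensity vector.

    Centres are initialised uniformly at random over the observed intensity
    range (reproducible via ``seed``) unless ``init_centers`` is given.
    Iteration stops when max |u^(t) - u^(t-1)| < epsilon or after
    ``max_iter`` sweeps.  A centre that collapses onto another is
    re-initialised (at most 5 times) with a warning.

    Random initialisation can land in a poor local minimum of J_m (e.g. two
    centres splitting one intensity mode); ``n_init`` independent restarts
    are run and the solution with the lowest final objective is returned,
    deterministically given ``seed``.
    """
    if init_centers is not None or n_init <= 1:
        return _fcm_single(values, n_clusters, fuzziness, epsilon, max_iter, seed, init_centers)
    best: ClusterModel | None = None
    for i in range(n_init):
        model = _fcm_single(
            values, n_clusters, fuzziness, epsilon, max_iter, [seed, i], None
        )
        if best is None or model.objective_trace[-1] < best.objective_trace[-1]:
            best = model
    return best


def _fcm_single(
    values: np.ndarray,
    n_clusters: int,
    fuzziness: float,
    epsilon: float,
    max_iter: int,
    seed,
    init_centers: np.ndarray | None,
) -> ClusterModel:
    values = np.asarray(values, dtype=float).ravel()
    N = values.size
    C = int(n_clusters)
    if N < C:
        raise ValueError(f"need at least {C} pixels to form {C} clusters, got {N}")
    if fuzziness <= 1:
        raise ValueError("fuzziness m must be > 1")
    if not (0 < epsilon < 1):
        raise ValueError("epsilon must lie in (0, 1)")

    rng = np.random.default_rng(seed)
    lo, hi = float(values.min()), float(values.max())
    if init_centers is not None:
        centers = np.asarray(init_centers, dtype=float).copy()
    else:
        centers = rng.uniform(lo, hi, size=C) if hi > lo else lo + np.arange(C, dtype=float)

    reinits = 0
    u_prev = None
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # guard collapsed (duplicate) centres before the membership update
        while True:
            order_ok = np.unique(np.round(centers, 12)).size == C
            if order_ok:
                break
            reinits += 1
            if reinits > 5:
                raise RuntimeError("cluster centres collapsed 5 times; aborting")
            warnings.warn("duplicate cluster centres; re-initialising", stacklevel=2)
            centers = rng.uniform(lo, hi, size=C) if hi > lo else lo + np.arange(C, dtype=float)
        u = _memberships(values, centers, fuzziness)
        um = u**fuzziness
        centers = (um @ values) / um.sum(axis=1)
        trace.append(_objective(values, centers, u, fuzziness))
        if u_prev is not None and np.max(np.abs(u - u_prev)) < epsilon:
            converged = True
            u_prev = u
            break
        u_prev = u

    # sort centres ascending and permute memberships to match
    order = np.argsort(centers)
    centers = centers[order]
    u = u_prev[order]
    labels = np.argmax(u, axis=0)
    return ClusterModel(
        n_clusters=C,
        fuzziness=fuzziness,
        centers=centers,
        memberships=u,
        labels=labels,
        objective_trace=np.asarray(trace),
        n_iter=it,
        converged=converged,
    )


def kmeans_cluster(
    values: np.ndarray,
    n_clusters: int = 4,
    epsilon: float = 1e-5,
    max_iter: int = 100,
    seed: int = 0,
    init_centers: np.ndarray | None = None,
    n_init: int = 5,
) -> ClusterModel:
    """Hard-assignment (K-means) backend minimising the same cost function.

    Memberships are one-hot; the trace records sum of squared distances to
    the assigned centre.  Interface, restarts and ordering match
    :func:`fcm_cluster`.
    """
    if init_centers is None and n_init > 1:
        best: ClusterModel | None = None
        for i in range(n_init):
            model = kmeans_cluster(
                values, n_clusters, epsilon, max_iter, [seed, i], None, n_init=1
            )
            if best is None or model.objective_trace[-1] < best.objective_trace[-1]:
                best = model
        return best
    values = np.asarray(values, dtype=float).ravel()
    N = values.size
    C = int(n_clusters)
    if N < C:
        raise ValueError(f"need at least {C} pixels to form {C} clusters, got {N}")
    rng = np.random.default_rng(seed)
    lo, hi = float(values.min()), float(values.max())
    if init_centers is not None:
        centers = np.asarray(init_centers, dtype=float).copy()
    else:
        centers = rng.uniform(lo, hi, size=C) if hi > lo else lo + np.arange(C, dtype=float)

    labels_prev = None
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        d2 = (values[np.newaxis, :] - centers[:, np.newaxis]) ** 2
        labels = np.argmin(d2, axis=0)
        for i in range(C):  # empty cluster -> re-seed at a random point
            if not np.any(labels == i):
                centers[i] = rng.uniform(lo, hi) if hi > lo else lo
        labels = np.argmin((values[np.newaxis, :] - centers[:, np.newaxis]) ** 2, axis=0)
        centers = np.array(
            [values[labels == i].mean() if np.any(labels == i) else centers[i] for i in range(C)]
        )
        trace.append(float(np.sum((values - centers[labels]) ** 2)))
        if labels_prev is not None and np.array_equal(labels, labels_prev):
            converged = True
            break
        labels_prev = labels

    order = np.argsort(centers)
    centers = centers[order]
    rank = np.empty(C, dtype=int)
    rank[order] = np.arange(C)
    labels = rank[labels]
    u = np.zeros((C, N))
    u[labels, np.arange(N)] = 1.0
    return ClusterModel(
        n_clusters=C,
        fuzziness=1.0 + 1e-9,
        centers=centers,
        memberships=u,
        labels=labels,
        objective_trace=np.asarray(trace),
        n_iter=it,
        converged=converged,
    )


def cluster_stack(
    stack: ImageStack,
    initial: MaskStack,
    n_clusters: int = 4,
    fuzziness: float = 2.0,
    epsilon: float = 1e-5,
    max_iter: int = 100,
    seed: int = 0,
    backend: str = "fcm",
    whole_image: bool = False,
) -> ClusterModel:
    """Fit the clustering model over the whole volume.

    By default clustering runs on the pixels inside the union of the
    per-slice initial masks (making the negligible class meaningful);
    ``whole_image=True`` clusters every pixel instead.
    """
    if whole_image:
        values = stack.slices.ravel()
    else:
        values = stack.slices[initial.slices.astype(bool)]
    if backend == "fcm":
        return fcm_cluster(values, n_clusters, fuzziness, epsilon, max_iter, seed)
    if backend == "kmeans":
        return kmeans_cluster(values, n_clusters, epsilon, max_iter, seed)
    raise ValueError(f"unknown backend {backend!r}")


def refine_mask(
    stack: ImageStack, initial: MaskStack, model: ClusterModel
) -> tuple[MaskStack, np.ndarray]:
    """Drop negligible-class pixels from the initial mask.

    Returns the refined mask (a subset of ``initial``) and an int label map
    of the stack's shape: 0 = background, 1..C = ventilation class of each
    surviving or discarded masked pixel (1 = negligible).
    """
    inside = initial.slices.astype(bool)
    n_masked = int(inside.sum())
    if model.labels.size != n_masked:
        raise ValueError(
            f"model was fitted on {model.labels.size} pixels but the mask has {n_masked}"
        )
    label_map = np.zeros(stack.slices.shape, dtype=np.int16)
    label_map[inside] = model.labels + 1
    refined = (label_map > 1).astype(np.uint8)
    return MaskStack.like(initial, refined), label_map
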