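"""K-means clustering and gap-statistic selection of the cluster count.

Feature vectors (Zernike shape magnitudes, fuzzy texture histograms) are
grouped with Lloyd's algorithm, seeded by drawing initial centroids from
the data rows.  Point-to-centroid assignment supports Euclidean distance
(shape features) or Manhattan distance (histogram features); centroids
are coordinate-wise means by default.

The number of clusters is chosen with the gap statistic: the log
within-cluster dispersion ``log W_k`` is compared against its expectation
under B reference datasets drawn uniformly over each feature's observed
range, and the smallest k with ``Gap(k) >= Gap(k+1) - s_{k+1}`` wins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "KMeansResult",
    "GapCurve",
    "kmeans",
    "within_cluster_dispersion",
    "gap_statistic",
    "optimal_k",
    "stability_trials",
]

DEFAULT_MAX_K = 20
DEFAULT_N_REF = 10
_METRICS = {"euclidean": "euclidean", "manhattan": "cityblock"}
_LOG_FLOOR = 1e-300  # guards log of an exactly-zero dispersion


@dataclass
class KMeansResult:
    labels: np.ndarray
    centroids: np.ndarray
    inertia: float
    n_iter: int
    converged: bool
    objective_history: list[float] = field(default_factory=list)


@dataclass
class GapCurve:
    """Gap statistic per candidate k = 1..N."""

    ks: np.ndarray
    w: np.ndarray
    log_w: np.ndarray
    ref_log_w_mean: np.ndarray
    gap: np.ndarray
    sd: np.ndarray
    s: np.ndarray
    n_ref: int
    k_opt: int = 0

    def as_dict(self) -> dict:
        return {
            "k": self.ks.tolist(),
            "W_k": self.w.tolist(),
            "log_W_k": self.log_w.tolist(),
            "ref_log_W_mean": self.ref_log_w_mean.tolist(),
            "gap": self.gap.tolist(),
            "sd_k": self.sd.tolist(),
            "s_k": self.s.tolist(),
            "B": self.n_ref,
            "k_opt": self.k_opt,
        }


def _check_features(features: np.ndarray) -> np.ndarray:
    x = np.asarray(features, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("feature matrix must be 2D (rows = lesions)")
    if not np.isfinite(x).all():
        raise ValueError("feature matrix contains missing or non-finite values")
    return x


def _assign(x: np.ndarray, centroids: np.ndarray, metric: str) -> tuple[np.ndarray, np.ndarray]:
    d = cdist(x, centroids, metric=_METRICS[metric])
    # argmin breaks ties toward the lowest centroid index
    return d.argmin(axis=1), d


def _objective(d: np.ndarray, labels: np.ndarray, metric: str) -> float:
    assigned = d[np.arange(d.shape[0]), labels]
    return float((assigned**2).sum()) if metric == "euclidean" else float(assigned.sum())


def _update_centroids(
    x: np.ndarray, labels: np.ndarray, k: int, update: str
) -> tuple[np.ndarray, list[int]]:
    centroids = np.empty((k, x.shape[1]))
    empty = []
    for r in range(k):
        members = x[labels == r]
        if members.shape[0] == 0:
            empty.append(r)
        elif update == "median":
            centroids[r] = np.median(members, axis=0)
        else:
            centroids[r] = members.mean(axis=0)
    return centroids, empty


def _lloyd(
    x: np.ndarray,
    k: int,
    rng: np.random.Generator,
    metric: str,
    max_iter: int,
    centroid_update: str,
) -> KMeansResult:
    init_idx = rng.choice(x.shape[0], size=k, replace=False)
    centroids = x[init_idx].copy()
    labels = np.full(x.shape[0], -1, dtype=np.intp)
    history: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        new_labels, d = _assign(x, centroids, metric)
        # an emptied cluster is re-seeded from the farthest point
        for _ in range(k):
            _, empty = _update_centroids(x, new_labels, k, centroid_update)
            if not empty:
                break
            assigned_d = d[np.arange(x.shape[0]), new_labels]
            for r in empty:
                far = int(np.argmax(assigned_d))
                centroids[r] = x[far]
                assigned_d[far] = -np.inf
            new_labels, d = _assign(x, centroids, metric)
        history.append(_objective(d, new_labels, metric))
        if np.array_equal(new_labels, labels):
            converged = True
            labels = new_labels
            break
        labels = new_labels
        centroids, _ = _update_centroids(x, labels, k, centroid_update)
    final_labels, d = _assign(x, centroids, metric)
    return KMeansResult(
        labels=final_labels,
        centroids=centroids,
        inertia=_objective(d, final_labels, metric),
        n_iter=n_iter,
        converged=converged,
        objective_history=history,
    )


def kmeans(
    features,
    k: int,
    seed: int | np.random.Generator | None = None,
    metric: str = "euclidean",
    max_iter: int = 100,
    n_init: int = 1,
    centroid_update: str = "mean",
) -> KMeansResult:
    """Lloyd's K-means with initial centroids drawn from the data rows.

    Parameters
    ----------
    features : array (rows, dims)
    k : number of clusters, ``1 <= k <= rows``.
    seed : int or Generator fixing the initial centroid draw.
    metric : "euclidean" or "manhattan" point-to-centroid assignment.
    n_init : independent restarts; the solution with the lowest objective wins.
    centroid_update : "mean" (default, as in classical K-means even under
        Manhattan assignment) or "median" (k-medians style).
    """
    x = _check_features(features)
    if not 1 <= k <= x.shape[0]:
        raise ValueError(f"k must be in [1, {x.shape[0]}], got {k}")
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {sorted(_METRICS)}")
    if centroid_update not in ("mean", "median"):
        raise ValueError("centroid_update must be 'mean' or 'median'")
    rng = np.random.default_rng(seed)
    best: KMeansResult | None = None
    for _ in range(max(1, n_init)):
        res = _lloyd(x, k, rng, metric, max_iter, centroid_update)
        if best is None or res.inertia < best.inertia:
            best = res
    return best


def within_cluster_dispersion(features, labels) -> float:
    """Sum over clusters of squared Euclidean deviations from the cluster mean.

    ``W_k = sum_r sum_{x_i in C_r} ||x_i - xbar_r||^2`` — squared deviations
    regardless of the assignment metric used during clustering.
    """
    x = _check_features(features)
    labels = np.asarray(labels)
    if labels.shape[0] != x.shape[0]:
        raise ValueError("every row must carry a cluster label")
    total = 0.0
    for r in np.unique(labels):
        members = x[labels == r]
        total += float(((members - members.mean(axis=0)) ** 2).sum())
    return total


def _reference_datasets(
    x: np.ndarray, n_ref: int, rng: np.random.Generator
) -> list[np.ndarray]:
    lo = x.min(axis=0)
    hi = x.max(axis=0)
    return [rng.uniform(lo, hi, size=x.shape) for _ in range(n_ref)]


def gap_statistic(
    features,
    n_max: int = DEFAULT_MAX_K,
    n_ref: int = DEFAULT_N_REF,
    seed: int | None = None,
    metric: str = "euclidean",
    n_init: int = 10,
    centroid_update: str = "mean",
) -> GapCurve:
    """Gap statistic over k = 1..N with B uniform reference datasets.

    Reference rows are sampled uniformly and independently over each
    feature's observed [min, max] (a degenerate constant column stays
    constant).  The same K-means procedure is applied to the data and to
    every reference dataset; ``Gap(k)`` is the mean reference ``log W_kb``
    minus the data ``log W_k``, and ``s_k = sd_k * sqrt(1 + 1/B)``.
    """
    x = _check_features(features)
    if n_max < 2:
        raise ValueError("n_max must be >= 2")
    if n_ref < 2:
        raise ValueError("n_ref must be >= 2")
    n_max = min(n_max, x.shape[0])
    rng = np.random.default_rng(seed)
    refs = _reference_datasets(x, n_ref, rng)

    ks = np.arange(1, n_max + 1)
    log_w = np.empty(n_max)
    w = np.empty(n_max)
    ref_mean = np.empty(n_max)
    sd = np.empty(n_max)
    for i, k in enumerate(ks):
        res = kmeans(x, int(k), seed=rng, metric=metric, n_init=n_init,
                     centroid_update=centroid_update)
        w[i] = within_cluster_dispersion(x, res.labels)
        log_w[i] = np.log(max(w[i], _LOG_FLOOR))
        ref_log = np.empty(n_ref)
        for b, xb in enumerate(refs):
            res_b = kmeans(xb, int(k), seed=rng, metric=metric, n_init=n_init,
                           centroid_update=centroid_update)
            ref_log[b] = np.log(max(within_cluster_dispersion(xb, res_b.labels), _LOG_FLOOR))
        ref_mean[i] = ref_log.mean()
        sd[i] = float(np.sqrt(((ref_log - ref_mean[i]) ** 2).mean()))
    gap = ref_mean - log_w
    s = sd * np.sqrt(1.0 + 1.0 / n_ref)
    curve = GapCurve(
        ks=ks, w=w, log_w=log_w, ref_log_w_mean=ref_mean, gap=gap, sd=sd, s=s, n_ref=n_ref
    )
    curve.k_opt = optimal_k(curve)
    return curve


def optimal_k(curve: GapCurve) -> int:
    """Smallest k with ``Gap(k) >= Gap(k+1) - s_{k+1}``; falls back to N."""
    n = len(curve.ks)
    for i in range(n - 1):
        if curve.gap[i] >= curve.gap[i + 1] - curve.s[i + 1]:
            return int(curve.ks[i])
    warnings.warn(
        "gap rule not satisfied for any k < N; returning N (consider raising n_max)",
        stacklevel=2,
    )
    return int(curve.ks[-1])


def trial_seeds(master_seed: int | None, trials: int) -> np.ndarray:
    """Deterministic per-trial seed stream derived from a master seed."""
    rng = np.random.default_rng(master_seed)
    return rng.integers(0, 2**31 - 1, size=trials)


def stability_trials(
    features,
    k: int,
    trials: int = 1000,
    seed: int | None = None,
    metric: str = "euclidean",
    centroid_update: str = "mean",
) -> np.ndarray:
    """Repeated K-means with randomly drawn initial seeds.

    Returns an array of shape (trials, rows) of per-trial cluster labels,
    for downstream stability/ANOVA analysis.  Trial t is exactly
    ``kmeans(features, k, seed=trial_seeds(seed, trials)[t])``.
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    x = _check_features(features)
    seeds = trial_seeds(seed, trials)
    out = np.empty((trials, x.shape[0]), dtype=np.intp)
    for t in range(trials):
        out[t] = kmeans(x, k, seed=int(seeds[t]), metric=metric,
                        centroid_update=centroid_update).labels
    return out
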