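"""Pairwise-RMSD hierarchical clustering of trajectory frames.

Frames are clustered on their pairwise mass-weighted RMSD (each pair
independently superposed), merged agglomeratively, and the cluster count is
chosen from three quality metrics evaluated over a candidate range: the
Davies-Bouldin index (local minimum wanted), the pseudo F-statistic
(Calinski-Harabasz; local maximum wanted) and the explained-variance ratio
SSR/SST (plateau wanted).

The variance decomposition behind the metrics (SST = SSR + SSE) is only
exact in a fixed coordinate frame, so the metric computation aligns all
frames once to their common mean and works in coordinates scaled by
sqrt(m_a / M); Euclidean distance in that space equals the mass-weighted
RMSD between the aligned frames.  The pairwise-RMSD matrix is still what is
merged and what defines the medoid centroids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .geometry import _selection_weights, align_frames
from .io import Selection, Trajectory

__all__ = [
    "DistanceMatrix",
    "ClusteringResult",
    "rmsd_matrix",
    "hierarchical_cluster",
    "cluster_metrics",
    "select_cluster_count",
    "extract_centroids",
    "cluster_trajectory",
]

_LINKAGES = {"average", "complete", "centroid", "single"}


@dataclass
class DistanceMatrix:
    """Condensed pairwise frame-to-frame RMSD values (Å).

    ``condensed`` follows scipy's ordering for ``n`` strided frames;
    ``frame_indices`` maps strided positions back to original frame indices.
    """

    condensed: np.ndarray
    n: int
    stride: int
    frame_indices: np.ndarray

    def __post_init__(self) -> None:
        expected = self.n * (self.n - 1) // 2
        if len(self.condensed) != expected:
            raise ValueError(
                f"condensed length {len(self.condensed)} != n(n-1)/2 = {expected}"
            )

    def square(self) -> np.ndarray:
        return squareform(self.condensed)


@dataclass
class ClusteringResult:
    labels_by_k: dict[int, np.ndarray]
    metrics_by_k: dict[int, dict[str, float]]
    chosen_k: int
    centroids: np.ndarray
    populations: np.ndarray
    frame_indices: np.ndarray
    linkage_method: str = "average"


def rmsd_matrix(
    traj: Trajectory,
    selection: Selection,
    stride: int = 1,
    mass_weighted: bool = True,
    chunk: int = 200_000,
) -> DistanceMatrix:
    """All-pairs superposition-minimised mass-weighted RMSD, condensed.

    Each pair of strided frames is independently superposed (weighted
    Kabsch) before the RMSD is taken, so the result is symmetric with a
    zero diagonal but is not guaranteed to satisfy the triangle inequality.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    frame_indices = np.arange(0, traj.n_frames, stride)
    n = len(frame_indices)
    if n < 2:
        raise ValueError("need at least two strided frames")
    idx = selection.indices
    w = _selection_weights(traj.topology, selection, mass_weighted)
    coords = traj.frames[frame_indices][:, idx, :]
    # center once; Kabsch reduces to an SVD of the cross-covariance, and the
    # rmsd follows from the trace formula (a relative clamp removes the
    # sqrt-amplified rounding for identical frames)
    cent = (coords * w[None, :, None]).sum(axis=1, keepdims=True)
    a = coords - cent
    aw = a * w[None, :, None]
    t = np.einsum("pni,pni->p", aw, a)
    ii, jj = np.triu_indices(n, k=1)
    condensed = np.empty(len(ii))
    for lo in range(0, len(ii), chunk):
        hi = min(lo + chunk, len(ii))
        ci, cj = ii[lo:hi], jj[lo:hi]
        h = np.einsum("pni,pnj->pij", aw[ci], a[cj])
        s = np.linalg.svd(h, compute_uv=False)
        sign = np.where(np.linalg.det(h) < 0, -1.0, 1.0)
        trace = s[:, 0] + s[:, 1] + sign * s[:, 2]
        e0 = t[ci] + t[cj]
        msd = e0 - 2.0 * trace
        msd[msd < 1e-12 * e0] = 0.0
        condensed[lo:hi] = np.sqrt(np.maximum(msd, 0.0))
    return DistanceMatrix(
        condensed=condensed, n=n, stride=stride, frame_indices=frame_indices
    )


def _canonical_labels(raw: np.ndarray) -> np.ndarray:
    """Relabel clusters 0..K-1 in order of first appearance."""
    out = np.empty_like(raw)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(raw):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def hierarchical_cluster(
    matrix: DistanceMatrix,
    linkage_method: str = "average",
    k_range: range | list[int] | None = None,
) -> dict[int, np.ndarray]:
    """Cut one agglomerative merge tree at each candidate cluster count.

    Returns ``{K: labels}`` with labels in 0..K-1, renumbered by order of
    first appearance so the output is deterministic.
    """
    if linkage_method not in _LINKAGES:
        raise ValueError(
            f"linkage must be one of {sorted(_LINKAGES)}, got {linkage_method!r}"
        )
    if k_range is None:
        k_range = range(1, min(matrix.n, 10) + 1)
    ks = sorted(set(int(k) for k in k_range))
    if any(k < 1 or k > matrix.n for k in ks):
        raise ValueError(f"cluster counts must lie in [1, {matrix.n}]")
    z = linkage(matrix.condensed, method=linkage_method)
    labels_by_k: dict[int, np.ndarray] = {}
    for k in ks:
        raw = fcluster(z, t=k, criterion="maxclust")
        labels_by_k[k] = _canonical_labels(raw)
    return labels_by_k


def _aligned_features(
    traj: Trajectory,
    selection: Selection,
    frame_indices: np.ndarray,
    mass_weighted: bool,
) -> np.ndarray:
    """Strided frames aligned to their common mean, flattened and scaled so
    Euclidean distance equals mass-weighted RMSD."""
    sub = Trajectory(
        frames=traj.frames[frame_indices],
        times=traj.times[frame_indices],
        topology=traj.topology,
    )
    aligned = align_frames(sub, selection, mass_weighted)[:, selection.indices, :]
    w = _selection_weights(traj.topology, selection, mass_weighted)
    scaled = aligned * np.sqrt(w)[None, :, None]
    return scaled.reshape(len(frame_indices), -1)


def cluster_metrics(
    traj: Trajectory,
    labels: np.ndarray,
    selection: Selection,
    frame_indices: np.ndarray | None = None,
    mass_weighted: bool = True,
    features: np.ndarray | None = None,
) -> dict[str, float]:
    """DBI, pseudo-F and SSR/SST for one frame labelling.

    Computed in the globally aligned, mass-scaled coordinate space (see
    module docstring): SST is the total squared deviation from the grand
    mean structure, SSE the within-cluster part, SSR = SST - SSE.  DBI uses
    S_i = mean member distance to the cluster mean and M_ij = distance
    between cluster means.  K = 1 yields ssr_sst = 0 with DBI/pSF undefined
    (NaN); SSE = 0 yields pSF = +inf.
    """
    labels = np.asarray(labels, dtype=int)
    if features is None:
        if frame_indices is None:
            frame_indices = np.arange(traj.n_frames)
        features = _aligned_features(traj, selection, frame_indices, mass_weighted)
    x = features
    if len(labels) != len(x):
        raise ValueError("labels length must match frame count")
    uniq = np.unique(labels)
    k = len(uniq)
    counts = np.array([(labels == u).sum() for u in uniq])
    if np.any(counts == 0):
        raise ValueError("empty cluster")
    f = len(x)
    grand = x.mean(axis=0)
    sst = float(((x - grand) ** 2).sum())
    means = np.stack([x[labels == u].mean(axis=0) for u in uniq])
    sse = 0.0
    scatters = np.empty(k)
    for c, u in enumerate(uniq):
        dev = x[labels == u] - means[c]
        sse += float((dev**2).sum())
        scatters[c] = float(np.sqrt((dev**2).sum(axis=1)).mean())
    ssr = max(sst - sse, 0.0)
    ssr_sst = ssr / sst if sst > 0 else 0.0
    if k == 1:
        return {"dbi": float("nan"), "psf": float("nan"), "ssr_sst": ssr_sst}
    if sse <= 1e-300:
        psf = float("inf")
    else:
        psf = (ssr / (k - 1)) / (sse / (f - k))
    sep = np.sqrt(((means[:, None, :] - means[None, :, :]) ** 2).sum(axis=2))
    ratio = np.zeros((k, k))
    with np.errstate(divide="ignore", invalid="ignore"):
        for i in range(k):
            for j in range(k):
                if i != j:
                    ratio[i, j] = (
                        (scatters[i] + scatters[j]) / sep[i, j]
                        if sep[i, j] > 0
                        else float("inf")
                    )
    dbi = float(np.mean(ratio.max(axis=1)))
    return {"dbi": dbi, "psf": psf, "ssr_sst": ssr_sst}


def select_cluster_count(
    metrics_by_k: dict[int, dict[str, float]],
    plateau_tol: float = 0.05,
) -> int:
    """Choose the cluster count from the three quality curves.

    A candidate K must sit at a local DBI minimum and have a relative
    SSR/SST gain to K+1 below ``plateau_tol`` (the plateau criterion); ties
    are broken by the largest pseudo-F.  If no K satisfies both, the DBI
    arg-min is returned with a warning.
    """
    ks = sorted(k for k in metrics_by_k if np.isfinite(metrics_by_k[k]["dbi"]))
    if len(ks) < 3:
        raise ValueError("need metrics for at least 3 contiguous cluster counts")
    dbi = {k: metrics_by_k[k]["dbi"] for k in ks}
    psf = {k: metrics_by_k[k]["psf"] for k in ks}
    ssr = {
        k: metrics_by_k[k]["ssr_sst"]
        for k in metrics_by_k
        if "ssr_sst" in metrics_by_k[k]
    }
    candidates = []
    for i, k in enumerate(ks):
        left_ok = i == 0 or dbi[k] <= dbi[ks[i - 1]]
        right_ok = i == len(ks) - 1 or dbi[k] <= dbi[ks[i + 1]]
        if not (left_ok and right_ok):
            continue
        if k + 1 not in ssr:
            continue  # cannot verify the plateau at the range edge
        gain = (ssr[k + 1] - ssr[k]) / max(ssr[k], 1e-12)
        if gain < plateau_tol:
            candidates.append(k)
    if candidates:
        return max(candidates, key=lambda k: (psf[k], -k))
    best = min(ks, key=lambda k: dbi[k])
    warnings.warn(
        "no cluster count satisfies both the DBI-minimum and SSR/SST-plateau "
        f"criteria; falling back to the DBI arg-min K={best}",
        stacklevel=2,
    )
    return best


def extract_centroids(
    matrix: DistanceMatrix, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Medoid frame per cluster and cluster populations.

    The centroid of a cluster is the member with the smallest summed RMSD
    to all other members; populations are member fractions of the strided
    frames.  Returned centroid values are original trajectory frame
    indices.
    """
    labels = np.asarray(labels, dtype=int)
    if len(labels) != matrix.n:
        raise ValueError("labels length must match matrix size")
    d = matrix.square()
    uniq = np.unique(labels)
    centroids = np.empty(len(uniq), dtype=int)
    populations = np.empty(len(uniq))
    for c, u in enumerate(uniq):
        members = np.flatnonzero(labels == u)
        if members.size == 0:
            raise ValueError(f"cluster {u} is empty")
        sums = d[np.ix_(members, members)].sum(axis=1)
        centroids[c] = matrix.frame_indices[members[np.argmin(sums)]]
        populations[c] = members.size / matrix.n
    return centroids, populations


def cluster_trajectory(
    traj: Trajectory,
    selection: Selection,
    stride: int = 1,
    linkage_method: str = "average",
    k_range: range | list[int] | None = None,
    plateau_tol: float = 0.05,
    mass_weighted: bool = True,
) -> ClusteringResult:
    """Full clustering stage: matrix, merge tree, metrics, K selection,
    centroids and populations (ordered by decreasing population)."""
    matrix = rmsd_matrix(traj, selection, stride, mass_weighted)
    if k_range is None:
        k_range = range(1, min(matrix.n, 10) + 1)
    labels_by_k = hierarchical_cluster(matrix, linkage_method, k_range)
    features = _aligned_features(
        traj, selection, matrix.frame_indices, mass_weighted
    )
    metrics_by_k = {
        k: cluster_metrics(traj, labels, selection, features=features)
        for k, labels in labels_by_k.items()
    }
    chosen = select_cluster_count(metrics_by_k, plateau_tol)
    centroids, populations = extract_centroids(matrix, labels_by_k[chosen])
    order = np.argsort(populations)[::-1]
    return ClusteringResult(
        labels_by_k=labels_by_k,
        metrics_by_k=metrics_by_k,
        chosen_k=chosen,
        centroids=centroids[order],
        populations=populations[order],
        frame_indices=matrix.frame_indices,
        linkage_method=linkage_method,
    )
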