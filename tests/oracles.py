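"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (grids, exhaustive enumeration, plain
Python loops) and shares no code with the package implementation it checks.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.spatial.transform import Rotation


def weighted_rmsd_after(rotations: np.ndarray, mobile: np.ndarray,
                        reference: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted RMSD of mobile under each rotation, with optimal translation."""
    w = weights / weights.sum()
    cm = (mobile * w[:, None]).sum(axis=0)
    cr = (reference * w[:, None]).sum(axis=0)
    a = mobile - cm
    b = reference - cr
    moved = np.einsum("rij,nj->rni", rotations, a)
    diff = moved - b[None]
    return np.sqrt(np.einsum("rni,rni->r", diff * w[None, :, None], diff))


def grid_min_rmsd(mobile: np.ndarray, reference: np.ndarray,
                  weights: np.ndarray, coarse: int = 24,
                  refine_rounds: int = 7) -> float:
    """Minimum weighted RMSD over a refined grid of rotations.

    Shrinking the search box by 3x per round keeps the surviving box well
    inside the previous grid spacing, so the minimum cannot escape during
    refinement; the final angular resolution is ~pi * 3^-7 / 12 rad.
    """
    best_angles = np.zeros(3)
    span = np.pi
    best = np.inf
    for _ in range(refine_rounds + 1):
        axes = [np.linspace(c - span, c + span, coarse) for c in best_angles]
        grid = np.array(list(itertools.product(*axes)))
        rots = Rotation.from_euler("zyx", grid).as_matrix()
        vals = weighted_rmsd_after(rots, mobile, reference, weights)
        k = int(np.argmin(vals))
        if vals[k] < best:
            best = float(vals[k])
            best_angles = grid[k]
        span /= 3.0
    return best


def brute_average_linkage_labels(square: np.ndarray, k: int) -> np.ndarray:
    """Exhaustive average-linkage agglomeration down to k clusters."""
    n = square.shape[0]
    clusters: list[list[int]] = [[i] for i in range(n)]
    while len(clusters) > k:
        best = (np.inf, None)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = np.mean([square[a, b] for a in clusters[i] for b in clusters[j]])
                if d < best[0]:
                    best = (d, (i, j))
        i, j = best[1]
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    labels = np.empty(n, dtype=int)
    for c, members in enumerate(clusters):
        labels[members] = c
    return labels


def canonical_relabel(labels: np.ndarray) -> np.ndarray:
    out = np.empty_like(labels)
    mapping: dict[int, int] = {}
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out[i] = mapping[lab]
    return out


def brute_cluster_metrics(x: np.ndarray, labels: np.ndarray) -> dict[str, float]:
    """DBI, pseudo-F and SSR/SST by direct loops over the definition."""
    uniq = sorted(set(labels.tolist()))
    f = len(x)
    k = len(uniq)
    grand = x.mean(axis=0)
    sst = sum(float(((row - grand) ** 2).sum()) for row in x)
    means = {u: x[labels == u].mean(axis=0) for u in uniq}
    sse = 0.0
    scatter = {}
    for u in uniq:
        members = x[labels == u]
        sse += float(((members - means[u]) ** 2).sum())
        scatter[u] = float(
            np.mean([np.linalg.norm(row - means[u]) for row in members])
        )
    ssr = sst - sse
    out = {"ssr_sst": ssr / sst if sst > 0 else 0.0}
    if k == 1:
        out["dbi"] = float("nan")
        out["psf"] = float("nan")
        return out
    out["psf"] = (
        float("inf") if sse == 0 else (ssr / (k - 1)) / (sse / (f - k))
    )
    worst = []
    for u in uniq:
        ratios = [
            (scatter[u] + scatter[v]) / np.linalg.norm(means[u] - means[v])
            for v in uniq
            if v != u
        ]
        worst.append(max(ratios))
    out["dbi"] = float(np.mean(worst))
    return out


def brute_medoid(square: np.ndarray, members: np.ndarray) -> int:
    best, best_sum = None, np.inf
    for m in members:
        s = sum(square[m, o] for o in members if o != m)
        if s < best_sum:
            best, best_sum = m, s
    return int(best)


def brute_equilibration(values: np.ndarray, window: int, tol: float) -> int:
    """Direct scan mirroring the documented plateau rule."""
    f = len(values)
    means = [values[t : t + window].mean() for t in range(f - window + 1)]
    final = means[-1]
    first = None
    for t in range(len(means)):
        if all(abs(m - final) <= tol for m in means[t:]):
            first = t
            break
    if first is None or first > f - 2 * window:
        return f - 1
    return first


def select_k_by_rule(metrics_by_k: dict, plateau_tol: float) -> int:
    """Hand evaluation of the cluster-count rule for cross-checking."""
    ks = sorted(k for k in metrics_by_k if np.isfinite(metrics_by_k[k]["dbi"]))
    cands = []
    for i, k in enumerate(ks):
        dbi = metrics_by_k[k]["dbi"]
        if i > 0 and dbi > metrics_by_k[ks[i - 1]]["dbi"]:
            continue
        if i < len(ks) - 1 and dbi > metrics_by_k[ks[i + 1]]["dbi"]:
            continue
        if k + 1 not in metrics_by_k:
            continue
        gain = (
            metrics_by_k[k + 1]["ssr_sst"] - metrics_by_k[k]["ssr_sst"]
        ) / max(metrics_by_k[k]["ssr_sst"], 1e-12)
        if gain < plateau_tol:
            cands.append(k)
    if cands:
        return max(cands, key=lambda k: (metrics_by_k[k]["psf"], -k))
    return min(ks, key=lambda k: metrics_by_k[k]["dbi"])
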