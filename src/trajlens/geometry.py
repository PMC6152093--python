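"""Mass-weighted superposition, RMSD series, RMSF profiles, equilibration.

The workhorse is a weighted Kabsch fit implemented with (optionally batched)
3x3 SVDs, so that per-frame series and all-pairs RMSD matrices share one
code path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import Selection, Structure, Trajectory

__all__ = [
    "SuperpositionResult",
    "RmsdSeries",
    "RmsfProfile",
    "superpose",
    "rmsd_series",
    "rmsf_per_residue",
    "detect_equilibration",
    "align_frames",
]


@dataclass
class SuperpositionResult:
    """Optimal rigid transform mapping mobile onto reference.

    ``x' = rotation @ (x - mobile_centroid) + reference_centroid`` minimises
    the weighted squared deviation; ``rmsd`` is the weighted minimum in Å.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    mobile_centroid: np.ndarray
    reference_centroid: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Apply the fitted transform to an (M, 3) coordinate array."""
        return (coords - self.mobile_centroid) @ self.rotation.T + self.reference_centroid


@dataclass
class RmsdSeries:
    values: np.ndarray
    times: np.ndarray
    reference_label: str = ""
    selection_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < -1e-12):
            raise ValueError("RMSD values must be non-negative")


@dataclass
class RmsfProfile:
    residue_ids: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.residue_ids) != len(self.values):
            raise ValueError("residue_ids and values must share length")
        if np.any(self.values < -1e-12):
            raise ValueError("RMSF values must be non-negative")


def _norm_weights(weights: np.ndarray | None, n: int) -> np.ndarray:
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if len(w) != n:
            raise ValueError(f"weights have length {len(w)}, expected {n}")
        if np.any(w <= 0):
            raise ValueError("weights must be strictly positive")
    return w / w.sum()


def _kabsch_batch(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray,
    want_rotations: bool = True,
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray, np.ndarray]:
    """Weighted Kabsch for stacked pairs.

    mobile, reference: (B, N, 3) already paired; weights: (N,) normalised to
    sum 1.  Returns (rmsd (B,), rotations (B, 3, 3) or None,
    mobile_centroids, reference_centroids).
    """
    w = weights[None, :, None]
    cm = (mobile * w).sum(axis=1)
    cr = (reference * w).sum(axis=1)
    a = mobile - cm[:, None, :]
    b = reference - cr[:, None, :]
    # weighted cross-covariance H = a^T W b per pair
    h = np.einsum("pni,pnj->pij", a * w, b)
    u, s, vt = np.linalg.svd(h)
    det = np.linalg.det(np.einsum("pij,pjk->pik", u, vt))
    sign = np.where(det < 0, -1.0, 1.0)
    d = np.ones_like(s)
    d[:, 2] = sign
    # rotation maps mobile -> reference: R = V diag(1,1,sign) U^T
    rotations = np.einsum("pji,pj,pkj->pik", vt, d, u)
    # rmsd from the explicitly rotated coordinates: backward-stable near 0,
    # unlike the trace formula which amplifies rounding by sqrt
    diff = np.einsum("pij,pnj->pni", rotations, a) - b
    rmsd = np.sqrt(np.einsum("pni,pni->p", diff * w, diff))
    if not want_rotations:
        rotations = None
    return rmsd, rotations, cm, cr


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> SuperpositionResult:
    """Weighted Kabsch superposition of ``mobile`` onto ``reference``.

    Both arguments are (N, 3) with N >= 3; weights default to uniform (pass
    masses for the mass-weighted fit).  Raises on fewer than three atoms or
    on (near-)collinear point sets, for which the rotation is not unique.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError("mobile and reference must have identical shapes")
    if mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("coordinates must be (N, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("superposition requires at least 3 atoms")
    w = _norm_weights(weights, n)
    for name, pts in (("mobile", mobile), ("reference", reference)):
        c = (pts * w[:, None]).sum(axis=0)
        cov = ((pts - c) * w[:, None]).T @ (pts - c)
        sv = np.linalg.svd(cov, compute_uv=False)
        if sv[1] <= 1e-12 * max(sv[0], 1.0):
            raise ValueError(
                f"ill-conditioned superposition: {name} points are collinear"
            )
    rmsd, rot, cm, cr = _kabsch_batch(
        mobile[None], reference[None], w, want_rotations=True
    )
    return SuperpositionResult(
        rotation=rot[0],
        translation=cr[0] - rot[0] @ cm[0],
        rmsd=float(rmsd[0]),
        mobile_centroid=cm[0],
        reference_centroid=cr[0],
    )


def _selection_weights(
    topology: Structure, selection: Selection, mass_weighted: bool
) -> np.ndarray:
    if mass_weighted:
        return _norm_weights(topology.masses[selection.indices], len(selection))
    return _norm_weights(None, len(selection))


def rmsd_series(
    traj: Trajectory,
    reference: Structure,
    fit_selection: Selection,
    report_selection: Selection | None = None,
    mass_weighted: bool = True,
) -> RmsdSeries:
    """Per-frame RMSD to a reference after per-frame superposition.

    Each frame is superposed on ``fit_selection`` (mass-weighted by default)
    and the RMSD is reported over ``report_selection`` (defaults to the fit
    selection), mirroring the fit-on-backbone / report-on-backbone protocol.
    """
    if report_selection is None:
        report_selection = fit_selection
    fit_idx = fit_selection.indices
    rep_idx = report_selection.indices
    if fit_idx.max() >= traj.n_atoms or rep_idx.max() >= traj.n_atoms:
        raise ValueError("selection exceeds trajectory atom count")
    w_fit = _selection_weights(traj.topology, fit_selection, mass_weighted)
    w_rep = _selection_weights(traj.topology, report_selection, mass_weighted)
    mob_fit = traj.frames[:, fit_idx, :]
    ref_fit = np.broadcast_to(
        reference.coordinates[fit_idx], mob_fit.shape
    )
    same = np.array_equal(fit_idx, rep_idx)
    rmsd_fit, rot, cm, cr = _kabsch_batch(
        mob_fit, ref_fit, w_fit, want_rotations=not same
    )
    if same:
        values = rmsd_fit
    else:
        mob_rep = traj.frames[:, rep_idx, :]
        moved = (
            np.einsum("pij,pnj->pni", rot, mob_rep - cm[:, None, :])
            + cr[:, None, :]
        )
        diff = moved - reference.coordinates[rep_idx]
        values = np.sqrt(
            np.einsum("pni,pni->p", diff * w_rep[None, :, None], diff)
        )
    return RmsdSeries(
        values=values,
        times=traj.times,
        reference_label="reference",
        selection_label=report_selection.label,
    )


def align_frames(
    traj: Trajectory,
    selection: Selection,
    mass_weighted: bool = True,
    align_to: str = "mean-structure",
    n_iter: int = 2,
) -> np.ndarray:
    """Rigid-fit every frame on ``selection``; returns transformed (F, N, 3).

    ``align_to``: ``"mean-structure"`` iteratively fits to the running mean
    of the aligned coordinates (started from frame 0); ``"first-frame"``
    fits to frame 0 only; ``"none"`` returns the frames untouched (for
    trajectories already expressed in a common frame).
    """
    if align_to == "none":
        return traj.frames.copy()
    if align_to not in ("mean-structure", "first-frame"):
        raise ValueError(f"unknown align_to {align_to!r}")
    idx = selection.indices
    w = _selection_weights(traj.topology, selection, mass_weighted)
    frames = traj.frames
    target = frames[0, idx, :]
    iterations = 1 if align_to == "first-frame" else max(1, n_iter)
    out = frames
    for _ in range(iterations):
        mob = out[:, idx, :]
        ref = np.broadcast_to(target, mob.shape)
        _, rot, cm, cr = _kabsch_batch(mob, ref, w, want_rotations=True)
        out = (
            np.einsum("pij,pnj->pni", rot, out - cm[:, None, :])
            + cr[:, None, :]
        )
        if align_to == "first-frame":
            break
        target = (out[:, idx, :]).mean(axis=0)
    return out


def rmsf_per_residue(
    traj: Trajectory,
    selection: Selection,
    align_to: str = "mean-structure",
    mass_weighted: bool = True,
) -> RmsfProfile:
    """Per-residue RMSF of the selected atoms about their time-mean.

    Frames are first rigid-fit on the selection (``align_to`` as in
    :func:`align_frames`); the per-atom RMSF is the root time-mean squared
    deviation from the time-mean position, and residues average their
    selected atoms' RMSF values with mass weights.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF is undefined for a single frame")
    idx = selection.indices
    aligned = align_frames(traj, selection, mass_weighted, align_to)[:, idx, :]
    mean = aligned.mean(axis=0)
    dev = aligned - mean
    per_atom = np.sqrt(np.einsum("pni,pni->n", dev, dev) / traj.n_frames)
    resids = traj.topology.residue_ids[idx]
    masses = (
        traj.topology.masses[idx]
        if mass_weighted
        else np.ones(len(idx))
    )
    unique = np.unique(resids)
    values = np.empty(len(unique))
    for k, rid in enumerate(unique):
        mask = resids == rid
        values[k] = np.average(per_atom[mask], weights=masses[mask])
    return RmsfProfile(residue_ids=unique, values=values)


def detect_equilibration(
    series: RmsdSeries,
    window: int | None = None,
    tolerance: float = 0.3,
) -> int:
    """First frame from which the RMSD has plateaued.

    Sliding means over ``window`` frames (default 5% of the series length,
    at least 2 frames) are compared with the final-window mean; the detector
    returns the first start index from which every subsequent window mean
    stays within ``tolerance`` Å of the final one.  If the series never
    settles the last frame index is returned with a warning.
    """
    values = series.values
    f = len(values)
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if window is None:
        window = max(2, int(round(0.05 * f)))
    if window >= f:
        raise ValueError(f"window ({window}) must be smaller than F ({f})")
    kernel = np.ones(window) / window
    window_means = np.convolve(values, kernel, mode="valid")  # start index t
    final_mean = window_means[-1]
    ok = np.abs(window_means - final_mean) <= tolerance
    # first t such that ok[t:] is all True
    bad = np.flatnonzero(~ok)
    if bad.size == 0:
        return 0
    first = int(bad[-1]) + 1
    # the final window matches itself trivially; demand the plateau span at
    # least one further full window to count as settled
    if first > f - 2 * window:
        warnings.warn(
            "RMSD series never plateaus within tolerance; returning the "
            "last frame",
            stacklevel=2,
        )
        return f - 1
    return first
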