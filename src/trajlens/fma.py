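"""Positional PCA and functional mode analysis (FMA).

FMA regresses a scalar functional quantity (here typically the RMSD of a
flexible loop) on the projections of the trajectory onto its leading PCA
modes.  The regression coefficients define a single collective mode — the
maximally correlated motion (MCM) — and its ensemble-weighted variant
(ewMCM), in which each mode's contribution is additionally weighted by its
eigenvalue so that motions actually sampled by the ensemble dominate.  The
trajectory filtered on the ewMCM isolates the collective motion coupled to
the functional quantity, and its RMSF profile reads off which residues
participate.

PCA operates on mass-weighted coordinates q = sqrt(m) * x after rigid-body
alignment, so eigenvalues carry units of Å²·amu and eigenvectors are unit
vectors in weighted coordinate space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import RmsfProfile, align_frames, rmsd_series, rmsf_per_residue
from .io import Selection, Structure, Trajectory

__all__ = [
    "PCAModel",
    "FunctionalSeries",
    "FMAResult",
    "fit_pca",
    "project",
    "functional_rmsd",
    "fit_fma",
    "filter_on_mode",
    "mode_rmsf",
    "mode_to_cartesian",
]


@dataclass
class PCAModel:
    """PCA of positional fluctuations over a selection.

    ``eigenvectors`` has shape (n_modes, 3n) with rows orthonormal in the
    weighted coordinate space and sorted by descending ``eigenvalues``
    (Å²·amu when mass-weighted).  ``mean_structure`` is (n, 3) in Å.
    """

    mean_structure: np.ndarray
    eigenvectors: np.ndarray
    eigenvalues: np.ndarray
    mass_weights: np.ndarray
    selection: Selection
    mass_weighted: bool = True

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)

    def n_components_for_variance(self, fraction: float = 0.9) -> int:
        """Smallest mode count explaining ``fraction`` of total variance."""
        total = self.eigenvalues.sum()
        if total <= 0:
            raise ValueError("model has no variance")
        cum = np.cumsum(self.eigenvalues) / total
        return int(np.searchsorted(cum, fraction) + 1)


@dataclass
class FunctionalSeries:
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("functional series must be finite")


@dataclass
class FMAResult:
    """MCM/ewMCM vectors with training and cross-validated correlations.

    ``mcm`` and ``ewmcm`` are unit 3n-vectors in the PCA's weighted
    coordinate space; ``betas`` are the OLS coefficients of the retained
    modes (intercept excluded).
    """

    betas: np.ndarray
    intercept: float
    mcm: np.ndarray
    ewmcm: np.ndarray
    r_train: float
    r_cv: float
    n_components: int


def _weight_scale(model_masses: np.ndarray, mass_weighted: bool) -> np.ndarray:
    return np.sqrt(model_masses) if mass_weighted else np.ones_like(model_masses)


def fit_pca(
    traj: Trajectory,
    selection: Selection,
    mass_weighted: bool = True,
    align: bool = True,
) -> PCAModel:
    """Diagonalise the covariance of (mass-weighted) positional fluctuations.

    Frames are rigid-fit on the selection to their iterated mean (skipped
    with ``align=False`` for trajectories already in a common frame).
    """
    if traj.n_frames < 2:
        raise ValueError("PCA needs at least 2 frames")
    idx = selection.indices
    coords = (
        align_frames(traj, selection, mass_weighted)[:, idx, :]
        if align
        else traj.frames[:, idx, :]
    )
    masses = traj.topology.masses[idx]
    scale = _weight_scale(masses, mass_weighted)
    mean = coords.mean(axis=0)
    q = ((coords - mean) * scale[None, :, None]).reshape(traj.n_frames, -1)
    cov = q.T @ q / (traj.n_frames - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order].T  # rows
    return PCAModel(
        mean_structure=mean,
        eigenvectors=evecs,
        eigenvalues=evals,
        mass_weights=masses,
        selection=selection,
        mass_weighted=mass_weighted,
    )


def project(
    traj: Trajectory,
    model: PCAModel,
    modes: np.ndarray | None = None,
    align: bool = True,
) -> np.ndarray:
    """Project frames onto PCA modes; returns (F, len(modes)).

    Frames are fit onto the model's mean structure over the model's
    selection before projection, matching the fit used by :func:`fit_pca`.
    """
    if modes is None:
        modes = np.arange(model.n_modes)
    modes = np.asarray(modes, dtype=int)
    if modes.size and (modes.min() < 0 or modes.max() >= model.n_modes):
        raise IndexError(
            f"mode index out of range [0, {model.n_modes})"
        )
    idx = model.selection.indices
    scale = _weight_scale(model.mass_weights, model.mass_weighted)
    coords = traj.frames[:, idx, :]
    if align:
        coords = _fit_to_reference(
            traj.subset_atoms(idx),
            Selection(np.arange(len(idx)), model.selection.label),
            model.mean_structure,
            model.mass_weighted,
        )
    q = ((coords - model.mean_structure) * scale[None, :, None]).reshape(
        traj.n_frames, -1
    )
    return q @ model.eigenvectors[modes].T


def _fit_to_reference(
    traj: Trajectory,
    selection: Selection,
    reference_coords: np.ndarray,
    mass_weighted: bool,
) -> np.ndarray:
    """Rigid-fit every frame's selection onto fixed reference coordinates."""
    from .geometry import _kabsch_batch, _selection_weights

    idx = selection.indices
    w = _selection_weights(traj.topology, selection, mass_weighted)
    mob = traj.frames[:, idx, :]
    ref = np.broadcast_to(reference_coords, mob.shape)
    _, rot, cm, cr = _kabsch_batch(mob, ref, w, want_rotations=True)
    return (
        np.einsum("pij,pnj->pni", rot, mob - cm[:, None, :]) + cr[:, None, :]
    )


def functional_rmsd(
    traj: Trajectory,
    subselection: Selection,
    reference: Structure,
    fit_selection: Selection,
    mass_weighted: bool = True,
) -> FunctionalSeries:
    """Per-frame RMSD of a sub-region after whole-selection superposition.

    This is the scalar functional quantity regressed in FMA (e.g., the RMSD
    of loop L3, residues 239-251, after fitting the whole backbone).
    """
    series = rmsd_series(
        traj, reference, fit_selection, subselection, mass_weighted
    )
    return FunctionalSeries(values=series.values, label=series.selection_label)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    denom = np.sqrt((x * x).sum() * (y * y).sum())
    if denom == 0:
        return 0.0
    return float((x * y).sum() / denom)


def fit_fma(
    model: PCAModel,
    projections: np.ndarray,
    f: FunctionalSeries,
    n_components: int | None = None,
    split: str | float = "halves",
) -> FMAResult:
    """Least-squares fit of the functional quantity on PCA projections.

    The functional series is regressed (with intercept) on the projections
    of the first ``n_components`` modes over the training split; maximising
    the Pearson correlation of a linear model and ordinary least squares
    coincide.  The MCM is the normalised coefficient-weighted sum of
    eigenvectors, the ewMCM additionally weights each mode by its
    eigenvalue.  ``r_cv`` evaluates the frozen coefficients on the held-out
    split.

    ``split``: ``"halves"`` trains on the first half, or a float in (0, 1)
    giving the training fraction.
    """
    proj = np.asarray(projections, dtype=float)
    y = f.values
    if proj.shape[0] != len(y):
        raise ValueError("projections and functional series length mismatch")
    n_nonzero = int(np.sum(model.eigenvalues > 1e-12 * max(model.eigenvalues.max(), 1e-30)))
    if n_components is None:
        n_components = min(model.n_components_for_variance(0.9), proj.shape[1])
    if n_components > proj.shape[1] or n_components > n_nonzero:
        raise ValueError(
            f"n_components={n_components} exceeds available non-zero modes "
            f"({min(proj.shape[1], n_nonzero)})"
        )
    frac = 0.5 if split == "halves" else float(split)
    if not 0 < frac < 1:
        raise ValueError("training fraction must lie in (0, 1)")
    n_train = int(round(frac * len(y)))
    if n_train < n_components + 2 or n_train >= len(y):
        raise ValueError("training split is degenerate")
    y_train, y_test = y[:n_train], y[n_train:]
    if np.var(y_train) == 0:
        raise ValueError("functional quantity has zero variance on the training split")
    x_train = proj[:n_train, :n_components]
    x_test = proj[n_train:, :n_components]
    design = np.column_stack([np.ones(n_train), x_train])
    coef, *_ = np.linalg.lstsq(design, y_train, rcond=None)
    intercept, betas = float(coef[0]), coef[1:]
    pred_train = design @ coef
    pred_test = intercept + x_test @ betas
    r_train = _pearson(y_train, pred_train)
    r_cv = _pearson(y_test, pred_test)
    vecs = model.eigenvectors[:n_components]
    mcm = betas @ vecs
    ew = (betas * model.eigenvalues[:n_components]) @ vecs
    for name, v in (("mcm", mcm), ("ewmcm", ew)):
        norm = np.linalg.norm(v)
        if norm == 0:
            raise ValueError(f"{name} vector is zero; regression degenerate")
    mcm = mcm / np.linalg.norm(mcm)
    ew = ew / np.linalg.norm(ew)
    return FMAResult(
        betas=betas,
        intercept=intercept,
        mcm=mcm,
        ewmcm=ew,
        r_train=r_train,
        r_cv=r_cv,
        n_components=n_components,
    )


def filter_on_mode(
    traj: Trajectory, model: PCAModel, mode: np.ndarray, align: bool = True
) -> Trajectory:
    """Trajectory retaining only the motion along one collective mode.

    Each output frame is the model's mean structure displaced along the
    (unit, weighted-space) mode by that frame's projection; all orthogonal
    variance is removed.  The output trajectory contains the model's
    selection atoms only.  ``align=False`` skips the rigid fit for frames
    already expressed in the model's frame.
    """
    mode = np.asarray(mode, dtype=float)
    if abs(np.linalg.norm(mode) - 1.0) > 1e-9:
        raise ValueError("mode must be a unit vector")
    idx = model.selection.indices
    scale = _weight_scale(model.mass_weights, model.mass_weighted)
    if align:
        coords = _fit_to_reference(
            traj.subset_atoms(idx),
            Selection(np.arange(len(idx)), model.selection.label),
            model.mean_structure,
            model.mass_weighted,
        )
    else:
        coords = traj.frames[:, idx, :]
    q = ((coords - model.mean_structure) * scale[None, :, None]).reshape(
        traj.n_frames, -1
    )
    p = q @ mode
    back = (mode.reshape(-1, 3) / scale[:, None])[None, :, :]
    frames = model.mean_structure[None, :, :] + p[:, None, None] * back
    return Trajectory(
        frames=frames,
        times=traj.times,
        topology=traj.topology.subset(idx).with_coordinates(
            model.mean_structure
        ),
    )


def mode_rmsf(
    filtered: Trajectory, selection: Selection | None = None
) -> RmsfProfile:
    """Per-residue RMSF of a mode-filtered trajectory.

    Filtered frames already share the model's common frame, so no further
    superposition is applied; residues moved by the mode show non-zero
    RMSF, all others exactly zero.
    """
    if selection is None:
        selection = Selection(np.arange(filtered.n_atoms), "all")
    return rmsf_per_residue(filtered, selection, align_to="none")


def mode_to_cartesian(model: PCAModel, mode: np.ndarray, normalize: bool = True) -> np.ndarray:
    """Back-transform a weighted-space mode to (n, 3) Cartesian displacements."""
    scale = _weight_scale(model.mass_weights, model.mass_weighted)
    v = np.asarray(mode, dtype=float).reshape(-1, 3) / scale[:, None]
    if normalize:
        v = v / np.linalg.norm(v)
    return v
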