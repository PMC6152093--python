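"""Synthetic trajectories, ensembles and toy complexes with planted truth.

Every analysis stage in this package is exercised on data whose answer is
known by construction: Gaussian fluctuation about a reference with a
planted low-dimensional collective mode (for PCA/FMA), multi-state
ensembles with stated occupancies (for clustering), and small charged
receptor-ligand complexes whose energy terms have closed forms (for
MM/GBSA).  Noise is isotropic Gaussian in Cartesian space; all generators
are seed-deterministic and their outputs are valid inputs to the io module
without modification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import EnergyParameters, Structure, Trajectory

__all__ = [
    "PlantedModeSpec",
    "MultiStateSpec",
    "ToyComplexSpec",
    "build_chain",
    "make_localized_mode",
    "make_states",
    "generate_planted_mode_trajectory",
    "generate_multistate_trajectory",
    "generate_toy_complex",
]

_BACKBONE_TEMPLATE = [
    # name, element mass (amu), offset within residue (Å)
    ("N", 14.007, np.array([0.0, 0.0, 0.0])),
    ("CA", 12.011, np.array([1.46, 0.30, 0.25])),
    ("C", 12.011, np.array([2.30, 1.40, -0.20])),
    ("O", 15.999, np.array([2.10, 2.60, -0.10])),
]


def build_chain(
    n_residues: int, chain_id: str = "A", first_resid: int = 1
) -> Structure:
    """Procedurally built backbone-only poly-alanine-like chain.

    Residues (N, CA, C, O atoms each) are laid along a gentle helix so
    coordinates are never collinear and ``backbone`` selections work
    naturally.  Deterministic; no randomness involved.
    """
    if n_residues < 1:
        raise ValueError("need at least one residue")
    names, resids, resnames, chains, coords, masses = [], [], [], [], [], []
    for i in range(n_residues):
        theta = 0.6 * i
        base = np.array(
            [3.2 * np.cos(theta), 3.2 * np.sin(theta), 1.5 * i]
        )
        for name, mass, offset in _BACKBONE_TEMPLATE:
            names.append(name)
            resids.append(first_resid + i)
            resnames.append("ALA")
            chains.append(chain_id)
            coords.append(base + offset)
            masses.append(mass)
    return Structure(
        atom_names=np.array(names, dtype=object),
        residue_ids=np.array(resids),
        residue_names=np.array(resnames, dtype=object),
        chain_ids=np.array(chains, dtype=object),
        coordinates=np.array(coords),
        masses=np.array(masses),
    )


@dataclass
class PlantedModeSpec:
    """A single planted collective mode in Cartesian space.

    ``mode`` is a unit (N, 3) displacement pattern; frame t displaces the
    reference by a_t ~ Normal(amplitude_mean, amplitude_sd²) along it, plus
    isotropic per-coordinate Gaussian noise of width ``noise_sd``.  A
    non-zero ``amplitude_mean`` keeps the displacement one-signed so that
    an RMSD-based functional quantity depends (near-)linearly on a_t.
    """

    mode: np.ndarray
    amplitude_sd: float = 1.0
    amplitude_mean: float = 0.0
    noise_sd: float = 0.1
    n_frames: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        self.mode = np.asarray(self.mode, dtype=float)
        norm = np.linalg.norm(self.mode)
        if abs(norm - 1.0) > 1e-9:
            raise ValueError("mode must be a unit vector")
        if self.amplitude_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


def remove_rigid_components(
    mode: np.ndarray, structure: Structure
) -> np.ndarray:
    """Project the rigid-body subspace out of a displacement field.

    A mass-weighted superposition removes any net (mass-weighted)
    translation and infinitesimal rotation from a displacement, so a
    planted mode must be orthogonal to those six rigid modes to survive
    alignment intact.  Orthogonality is taken in the mass-weighted inner
    product the superposition minimises.
    """
    m = structure.masses
    sqm = np.sqrt(m)[:, None]
    com = (structure.coordinates * m[:, None]).sum(axis=0) / m.sum()
    rel = structure.coordinates - com
    rigid = []
    for ax in np.eye(3):
        rigid.append(np.tile(ax, (structure.n_atoms, 1)))  # translation
    for ax in np.eye(3):
        rigid.append(np.cross(np.tile(ax, (structure.n_atoms, 1)), rel))
    q = np.asarray(mode, dtype=float) * sqm
    basis = np.stack([(r * sqm).ravel() for r in rigid])
    # orthonormalise the rigid basis, then deflate
    u, s, _ = np.linalg.svd(basis.T, full_matrices=False)
    keep = s > 1e-10 * s.max()
    qf = q.ravel() - u[:, keep] @ (u[:, keep].T @ q.ravel())
    out = (qf.reshape(-1, 3) / sqm)
    norm = np.linalg.norm(out)
    if norm < 1e-12:
        raise ValueError("mode lies entirely in the rigid-body subspace")
    return out / norm


def make_localized_mode(
    structure: Structure,
    resid_lo: int,
    resid_hi: int,
    seed: int = 0,
    remove_rigid: bool = True,
) -> np.ndarray:
    """Unit (N, 3) collective mode localised on a residue range.

    Atoms in [resid_lo, resid_hi] move along a common random direction with
    smoothly varying per-atom weights; all other atoms are (nearly) fixed.
    With ``remove_rigid`` (default) the rigid-body component is projected
    out so the mode survives trajectory superposition; this spreads a small
    compensating displacement over the remaining atoms.
    """
    rng = np.random.default_rng(seed)
    mask = (structure.residue_ids >= resid_lo) & (structure.residue_ids <= resid_hi)
    if not mask.any():
        raise ValueError("residue range selects no atoms")
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    mode = np.zeros((structure.n_atoms, 3))
    local = np.flatnonzero(mask)
    weights = np.sin(np.linspace(0.3, np.pi - 0.3, len(local)))
    mode[local] = weights[:, None] * direction
    if remove_rigid:
        return remove_rigid_components(mode, structure)
    return mode / np.linalg.norm(mode)


def generate_planted_mode_trajectory(
    reference: Structure, spec: PlantedModeSpec, dt: float = 1.0
) -> tuple[Trajectory, np.ndarray]:
    """Trajectory with one planted collective mode; returns (traj, a_t)."""
    if spec.mode.shape != (reference.n_atoms, 3):
        raise ValueError(
            f"mode shape {spec.mode.shape} does not match reference "
            f"({reference.n_atoms}, 3)"
        )
    rng = np.random.default_rng(spec.seed)
    a = rng.normal(spec.amplitude_mean, spec.amplitude_sd, spec.n_frames)
    noise = rng.normal(0.0, spec.noise_sd, (spec.n_frames, reference.n_atoms, 3))
    frames = (
        reference.coordinates[None]
        + a[:, None, None] * spec.mode[None]
        + noise
    )
    traj = Trajectory(
        frames=frames,
        times=np.arange(spec.n_frames) * dt,
        topology=reference,
    )
    return traj, a


@dataclass
class MultiStateSpec:
    """Mixture of >= 2 conformational states with stated occupancies."""

    states: list[Structure]
    occupancies: np.ndarray
    within_state_sd: float = 0.1
    n_frames: int = 1200
    seed: int = 0

    def __post_init__(self) -> None:
        self.occupancies = np.asarray(self.occupancies, dtype=float)
        if len(self.states) < 2:
            raise ValueError("need at least 2 states")
        if len(self.occupancies) != len(self.states):
            raise ValueError("one occupancy per state required")
        if np.any(self.occupancies < 0) or abs(self.occupancies.sum() - 1) > 1e-9:
            raise ValueError("occupancies must be non-negative and sum to 1")
        if self.within_state_sd < 0:
            raise ValueError("within_state_sd must be non-negative")
        n0 = self.states[0].n_atoms
        for s in self.states[1:]:
            if s.n_atoms != n0 or not np.array_equal(
                s.residue_ids, self.states[0].residue_ids
            ):
                raise ValueError("states must share one topology")


def make_states(
    reference: Structure,
    n_states: int,
    separation: float,
    seed: int = 0,
) -> list[Structure]:
    """Distinct conformational states displaced from a common reference.

    Each state adds an independent smooth Gaussian displacement field
    scaled so the expected pairwise RMSD between states is about
    ``separation`` Å.
    """
    rng = np.random.default_rng(seed)
    per_coord = separation / np.sqrt(6.0)  # two independent N(0, s²) fields
    states = []
    for _ in range(n_states):
        disp = rng.normal(0.0, per_coord, (reference.n_atoms, 3))
        states.append(reference.with_coordinates(reference.coordinates + disp))
    return states


def generate_multistate_trajectory(
    spec: MultiStateSpec, dt: float = 1.0
) -> tuple[Trajectory, np.ndarray]:
    """Frames drawn per-state by occupancy, jittered; returns (traj, labels)."""
    rng = np.random.default_rng(spec.seed)
    labels = rng.choice(len(spec.states), size=spec.n_frames, p=spec.occupancies)
    coords = np.stack([s.coordinates for s in spec.states])
    frames = coords[labels] + rng.normal(
        0.0, spec.within_state_sd, (spec.n_frames, spec.states[0].n_atoms, 3)
    )
    traj = Trajectory(
        frames=frames,
        times=np.arange(spec.n_frames) * dt,
        topology=spec.states[0],
    )
    return traj, labels


@dataclass
class ToyComplexSpec:
    """Desk-scale receptor-ligand complex with closed-form-checkable cases.

    geometry: ``"two-ion"`` (one +1e receptor atom, one -1e ligand atom at
    ``separation`` Å, the fully hand-checkable case), ``"helix-pair"`` (two
    short backbone chains side by side with small alternating partial
    charges, for multi-residue decomposition), or ``"random-packed"``
    (random non-overlapping atoms in a box).
    """

    geometry: str = "two-ion"
    receptor_atoms: int = 1
    ligand_atoms: int = 1
    separation: float = 5.0
    n_frames: int = 5
    jitter_sd: float = 0.02
    apolar_ligand: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.geometry not in ("two-ion", "helix-pair", "random-packed"):
            raise ValueError(f"unknown geometry {self.geometry!r}")
        if self.receptor_atoms < 1 or self.ligand_atoms < 1:
            raise ValueError("atom counts must be >= 1")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


def _ion(name, chain, resid, xyz, mass=22.99):
    return (name, chain, resid, np.asarray(xyz, float), mass)


def generate_toy_complex(
    spec: ToyComplexSpec, dt: float = 1.0
) -> tuple[Structure, EnergyParameters, Trajectory]:
    """Build a toy complex, its parameter table and a short jittered trajectory.

    The receptor occupies chain A, the ligand chain B.  Radii, screening
    factors and Lennard-Jones parameters are physically reasonable
    (1.2-2.0 Å radii, epsilon ~0.1 kcal/mol); charges are unit charges for
    the two-ion geometry and small alternating partial charges summing to
    zero per chain otherwise (or all-zero on the ligand when
    ``apolar_ligand`` is set).
    """
    rng = np.random.default_rng(spec.seed)
    if spec.geometry == "two-ion":
        atoms = [
            _ion("NA", "A", 1, [0.0, 0.0, 0.0]),
            _ion("CL", "B", 1, [spec.separation, 0.0, 0.0], 35.45),
        ]
        names, chains, resids, coords, masses = map(list, zip(*[
            (a[0], a[1], a[2], a[3], a[4]) for a in atoms
        ]))
        charge = np.array([1.0, -1.0])
        rmin_half = np.array([1.37, 2.27])
        epsilon = np.array([0.0874, 0.1])
        gb_radius = np.array([1.5, 1.7])
        gb_screen = np.array([0.8, 0.8])
    elif spec.geometry == "helix-pair":
        n_res_r = max(1, spec.receptor_atoms // 4)
        n_res_l = max(1, spec.ligand_atoms // 4)
        rec = build_chain(n_res_r, chain_id="A", first_resid=1)
        lig = build_chain(n_res_l, chain_id="B", first_resid=101)
        lig_coords = lig.coordinates + np.array([spec.separation + 3.0, 0.0, 0.0])
        names = list(rec.atom_names) + list(lig.atom_names)
        chains = list(rec.chain_ids) + list(lig.chain_ids)
        resids = list(rec.residue_ids) + list(lig.residue_ids)
        coords = list(rec.coordinates) + list(lig_coords)
        masses = list(rec.masses) + list(lig.masses)
        n = len(names)
        nr = rec.n_atoms
        charge = np.empty(n)
        charge[:nr] = 0.3 * np.where(np.arange(nr) % 2 == 0, 1.0, -1.0)
        if nr % 2 == 1:
            charge[nr - 1] = 0.0  # keep the chain neutral
        nl = n - nr
        charge[nr:] = 0.3 * np.where(np.arange(nl) % 2 == 0, 1.0, -1.0)
        if nl % 2 == 1:
            charge[n - 1] = 0.0
        rmin_half = np.full(n, 1.7)
        epsilon = np.full(n, 0.1)
        gb_radius = np.full(n, 1.55)
        gb_screen = np.full(n, 0.79)
    else:  # random-packed
        n = spec.receptor_atoms + spec.ligand_atoms
        coords_arr = _packed_points(rng, n, min_dist=2.8)
        coords_arr[spec.receptor_atoms:] += np.array(
            [spec.separation + 4.0, 0.0, 0.0]
        )
        names = ["C"] * n
        chains = ["A"] * spec.receptor_atoms + ["B"] * spec.ligand_atoms
        resids = list(range(1, spec.receptor_atoms + 1)) + list(
            range(101, 101 + spec.ligand_atoms)
        )
        coords = list(coords_arr)
        masses = [12.011] * n
        charge = rng.uniform(-0.4, 0.4, n)
        charge[: spec.receptor_atoms] -= charge[: spec.receptor_atoms].mean()
        charge[spec.receptor_atoms:] -= charge[spec.receptor_atoms:].mean()
        rmin_half = rng.uniform(1.5, 1.9, n)
        epsilon = rng.uniform(0.05, 0.15, n)
        gb_radius = rng.uniform(1.3, 1.8, n)
        gb_screen = np.full(n, 0.8)
    if spec.apolar_ligand:
        ligand_mask = np.array([c == "B" for c in chains])
        charge = np.where(ligand_mask, 0.0, charge)
    topology = Structure(
        atom_names=np.array(names, dtype=object),
        residue_ids=np.array(resids),
        residue_names=np.array(["ION" if spec.geometry == "two-ion" else "ALA"] * len(names), dtype=object),
        chain_ids=np.array(chains, dtype=object),
        coordinates=np.array(coords),
        masses=np.array(masses),
    )
    params = EnergyParameters(
        charge=charge,
        lj_rmin_half=rmin_half,
        lj_epsilon=epsilon,
        gb_radius=gb_radius,
        gb_screen=gb_screen,
        atom_names=topology.atom_names.copy(),
    )
    frames = topology.coordinates[None] + rng.normal(
        0.0, spec.jitter_sd, (spec.n_frames, topology.n_atoms, 3)
    )
    frames[0] = topology.coordinates  # frame 0 is the ideal geometry
    traj = Trajectory(
        frames=frames,
        times=np.arange(spec.n_frames) * dt,
        topology=topology,
    )
    return topology, params, traj


def _packed_points(
    rng: np.random.Generator, n: int, min_dist: float, box: float | None = None
) -> np.ndarray:
    """Rejection-sample n points with pairwise separation >= min_dist."""
    if box is None:
        box = max(8.0, 2.2 * min_dist * n ** (1 / 3))
    pts: list[np.ndarray] = []
    for _ in range(20000):
        cand = rng.uniform(0, box, 3)
        if all(np.linalg.norm(cand - p) >= min_dist for p in pts):
            pts.append(cand)
            if len(pts) == n:
                return np.array(pts)
    raise RuntimeError("could not pack points; increase the box")
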