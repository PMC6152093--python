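"""Core data model and file I/O.

Units used throughout the package: coordinates in Å, times in ns, masses in
amu, energies in kcal/mol, charges in elementary charge units.  Atom indices
are 0-based internally; residue identifiers are kept 1-based exactly as they
appear in the source files, and all reports use residue ids.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Structure",
    "Trajectory",
    "Selection",
    "EnergyParameters",
    "read_trajectory",
    "write_trajectory",
    "read_parameters",
    "write_parameters",
    "make_selection",
    "guess_element",
    "element_mass",
]

# Fallback masses (amu) for elements whose lookup is not covered by biotite.
_FALLBACK_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "ZN": 65.38, "MG": 24.305, "NA": 22.990, "CL": 35.45,
    "K": 39.098, "CA": 40.078, "FE": 55.845,
}

_TWO_LETTER_ELEMENTS = {"CL", "BR", "NA", "MG", "ZN", "FE", "MN", "CU", "SE"}


def guess_element(atom_name: str) -> str:
    """Guess the chemical element from a PDB-style atom name.

    Protein/nucleic atom names start with the element letter (N, CA, C, O,
    OP1, ...); a handful of two-letter ions are recognised explicitly.
    """
    stripped = re.sub(r"[^A-Za-z]", "", atom_name).upper()
    if not stripped:
        raise ValueError(f"cannot guess element for atom name {atom_name!r}")
    if stripped in _TWO_LETTER_ELEMENTS:
        return stripped
    return stripped[0]


def element_mass(element: str) -> float:
    """Atomic mass in amu for an element symbol."""
    try:
        from biotite.structure.info import mass as _biotite_mass

        m = _biotite_mass(element.capitalize())
        if m is not None and m > 0:
            return float(m)
    except Exception:
        pass
    key = element.upper()
    if key in _FALLBACK_MASSES:
        return _FALLBACK_MASSES[key]
    raise ValueError(f"unknown element {element!r}")


@dataclass
class Structure:
    """A single conformation with per-atom metadata.

    All per-atom arrays share length N >= 1.  ``coordinates`` is (N, 3) in Å
    and ``masses`` is in amu (strictly positive).
    """

    atom_names: np.ndarray
    residue_ids: np.ndarray
    residue_names: np.ndarray
    chain_ids: np.ndarray
    coordinates: np.ndarray
    masses: np.ndarray

    def __post_init__(self) -> None:
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.residue_names = np.asarray(self.residue_names, dtype=object)
        self.chain_ids = np.asarray(self.chain_ids, dtype=object)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        n = len(self.atom_names)
        if n < 1:
            raise ValueError("a Structure needs at least one atom")
        for name, arr in [
            ("residue_ids", self.residue_ids),
            ("residue_names", self.residue_names),
            ("chain_ids", self.chain_ids),
            ("masses", self.masses),
        ]:
            if len(arr) != n:
                raise ValueError(f"{name} has length {len(arr)}, expected {n}")
        if self.coordinates.shape != (n, 3):
            raise ValueError(
                f"coordinates have shape {self.coordinates.shape}, expected ({n}, 3)"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")
        if not np.all(self.masses > 0):
            raise ValueError("masses must be strictly positive")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def subset(self, indices: np.ndarray) -> "Structure":
        """New Structure restricted to the given 0-based atom indices."""
        idx = np.asarray(indices, dtype=int)
        return Structure(
            atom_names=self.atom_names[idx],
            residue_ids=self.residue_ids[idx],
            residue_names=self.residue_names[idx],
            chain_ids=self.chain_ids[idx],
            coordinates=self.coordinates[idx],
            masses=self.masses[idx],
        )

    def with_coordinates(self, coordinates: np.ndarray) -> "Structure":
        return Structure(
            atom_names=self.atom_names,
            residue_ids=self.residue_ids,
            residue_names=self.residue_names,
            chain_ids=self.chain_ids,
            coordinates=np.asarray(coordinates, dtype=float),
            masses=self.masses,
        )


@dataclass
class Trajectory:
    """An ordered ensemble of conformations sharing one topology.

    ``frames`` is (F, N, 3) in Å; ``times`` is in ns and strictly increasing.
    """

    frames: np.ndarray
    times: np.ndarray
    topology: Structure

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a non-empty (F, N, 3) array")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frames have {self.frames.shape[1]} atoms, topology has "
                f"{self.topology.n_atoms}"
            )
        if self.frames.shape[2] != 3:
            raise ValueError("frames must have 3 spatial dimensions")
        if len(self.times) != self.frames.shape[0]:
            raise ValueError("times length must equal frame count")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    def frame_structure(self, i: int) -> Structure:
        """The i-th frame as a Structure."""
        return self.topology.with_coordinates(self.frames[i])

    def subset_atoms(self, indices: np.ndarray) -> "Trajectory":
        idx = np.asarray(indices, dtype=int)
        return Trajectory(
            frames=self.frames[:, idx, :],
            times=self.times,
            topology=self.topology.subset(idx),
        )


@dataclass
class Selection:
    """A strictly increasing list of 0-based atom indices with a label."""

    indices: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.size == 0:
            raise ValueError(f"selection {self.label!r} is empty")
        if np.any(np.diff(self.indices) <= 0):
            raise ValueError("selection indices must be strictly increasing")
        if self.indices[0] < 0:
            raise ValueError("selection indices must be non-negative")

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class EnergyParameters:
    """Per-atom non-bonded parameters.

    charge (e), lj_rmin_half (Å, the Rmin/2 convention), lj_epsilon
    (kcal/mol, >= 0), gb_radius (Å, > 0, the intrinsic Born radius) and
    gb_screen (dimensionless HCT screening factor in (0, 2]).
    """

    charge: np.ndarray
    lj_rmin_half: np.ndarray
    lj_epsilon: np.ndarray
    gb_radius: np.ndarray
    gb_screen: np.ndarray
    atom_names: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.charge = np.asarray(self.charge, dtype=float)
        self.lj_rmin_half = np.asarray(self.lj_rmin_half, dtype=float)
        self.lj_epsilon = np.asarray(self.lj_epsilon, dtype=float)
        self.gb_radius = np.asarray(self.gb_radius, dtype=float)
        self.gb_screen = np.asarray(self.gb_screen, dtype=float)
        n = len(self.charge)
        for name, arr in [
            ("lj_rmin_half", self.lj_rmin_half),
            ("lj_epsilon", self.lj_epsilon),
            ("gb_radius", self.gb_radius),
            ("gb_screen", self.gb_screen),
        ]:
            if len(arr) != n:
                raise ValueError(f"{name} has length {len(arr)}, expected {n}")
        for name, arr in [
            ("charge", self.charge), ("lj_rmin_half", self.lj_rmin_half),
            ("lj_epsilon", self.lj_epsilon), ("gb_radius", self.gb_radius),
            ("gb_screen", self.gb_screen),
        ]:
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
        if np.any(self.lj_epsilon < 0):
            raise ValueError("lj_epsilon must be non-negative")
        if np.any(self.gb_radius <= 0):
            raise ValueError("gb_radius must be strictly positive")
        if np.any((self.gb_screen <= 0) | (self.gb_screen > 2)):
            raise ValueError("gb_screen must lie in (0, 2]")

    @property
    def n_atoms(self) -> int:
        return len(self.charge)

    def subset(self, indices: np.ndarray) -> "EnergyParameters":
        idx = np.asarray(indices, dtype=int)
        return EnergyParameters(
            charge=self.charge[idx],
            lj_rmin_half=self.lj_rmin_half[idx],
            lj_epsilon=self.lj_epsilon[idx],
            gb_radius=self.gb_radius[idx],
            gb_screen=self.gb_screen[idx],
            atom_names=None if self.atom_names is None else self.atom_names[idx],
        )


# ---------------------------------------------------------------------------
# Trajectory I/O
# ---------------------------------------------------------------------------

def _detect_format(path: Path, format: str | None) -> str:
    if format is not None:
        fmt = format.lower().replace("multi-model-", "")
        if fmt not in ("pdb", "xyz"):
            raise ValueError(f"unknown trajectory format {format!r}")
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".pdb", ".ent"):
        return "pdb"
    if suffix == ".xyz":
        return "xyz"
    raise ValueError(f"cannot infer trajectory format from {path.name!r}")


def _check_pdb_model_consistency(path: Path) -> None:
    """Count ATOM/HETATM records per MODEL and fail naming the bad frame."""
    counts: list[int] = []
    current: int | None = None
    saw_model = False
    with open(path) as fh:
        for line in fh:
            rec = line[:6].strip()
            if rec == "MODEL":
                saw_model = True
                if current is not None:
                    counts.append(current)
                current = 0
            elif rec in ("ATOM", "HETATM"):
                if current is None:
                    current = 0
                current += 1
            elif rec == "ENDMDL":
                if current is not None:
                    counts.append(current)
                    current = None
    if current is not None and (current > 0 or not counts):
        counts.append(current)
    if saw_model and len(set(counts)) > 1:
        ref = counts[0]
        for i, c in enumerate(counts):
            if c != ref:
                raise ValueError(
                    f"inconsistent atom count across frames: frame {i} has "
                    f"{c} atoms, frame 0 has {ref}"
                )


def _read_pdb(path: Path, dt: float) -> Trajectory:
    from biotite.structure.io.pdb import PDBFile

    _check_pdb_model_consistency(path)
    stack = PDBFile.read(str(path)).get_structure(model=None)
    coords = np.asarray(stack.coord, dtype=float)
    elements = [
        e if e else guess_element(n)
        for e, n in zip(stack.element, stack.atom_name)
    ]
    masses = np.array([element_mass(e) for e in elements])
    topology = Structure(
        atom_names=np.array(list(stack.atom_name), dtype=object),
        residue_ids=np.asarray(stack.res_id, dtype=int),
        residue_names=np.array(list(stack.res_name), dtype=object),
        chain_ids=np.array(list(stack.chain_id), dtype=object),
        coordinates=coords[0],
        masses=masses,
    )
    times = np.arange(coords.shape[0]) * dt
    return Trajectory(frames=coords, times=times, topology=topology)


def _read_xyz(path: Path, dt: float, topology: Structure | None) -> Trajectory:
    frames: list[np.ndarray] = []
    names: list[str] | None = None
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    n_line = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise ValueError(
                f"unparseable XYZ atom-count line {i + 1}: {lines[i]!r}"
            ) from exc
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise ValueError(
                f"inconsistent atom count across frames: frame {len(frames)} "
                f"is truncated ({len(block)} of {n} atoms)"
            )
        coords = np.empty((n, 3))
        block_names = []
        for j, line in enumerate(block):
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(
                    f"unparseable XYZ record at line {i + 3 + j}: {line!r}"
                )
            block_names.append(parts[0])
            try:
                coords[j] = [float(x) for x in parts[1:4]]
            except ValueError as exc:
                raise ValueError(
                    f"unparseable XYZ record at line {i + 3 + j}: {line!r}"
                ) from exc
        if names is None:
            names = block_names
            n_line = n
        elif n != n_line:
            raise ValueError(
                f"inconsistent atom count across frames: frame {len(frames)} "
                f"has {n} atoms, frame 0 has {n_line}"
            )
        frames.append(coords)
        i += 2 + n
    if not frames:
        raise ValueError(f"no frames found in {path}")
    coords = np.stack(frames)
    if topology is None:
        masses = np.array([element_mass(guess_element(n)) for n in names])
        topology = Structure(
            atom_names=np.array(names, dtype=object),
            residue_ids=np.ones(len(names), dtype=int),
            residue_names=np.array(["UNK"] * len(names), dtype=object),
            chain_ids=np.array(["A"] * len(names), dtype=object),
            coordinates=coords[0],
            masses=masses,
        )
    elif topology.n_atoms != coords.shape[1]:
        raise ValueError(
            f"topology has {topology.n_atoms} atoms but XYZ frames have "
            f"{coords.shape[1]}"
        )
    times = np.arange(coords.shape[0]) * dt
    return Trajectory(frames=coords, times=times, topology=topology)


def read_trajectory(
    path: str | Path,
    format: str | None = None,
    dt: float = 1.0,
    topology: Structure | None = None,
) -> Trajectory:
    """Read a trajectory from a multi-model PDB or an XYZ file.

    Parameters
    ----------
    path:
        Input file.  The format is inferred from the suffix unless given.
    format:
        ``"pdb"`` (multi-model, MODEL/ENDMDL) or ``"xyz"``.
    dt:
        Time spacing in ns assigned to the frames (neither dialect stores
        times).
    topology:
        Optional topology to attach when reading XYZ, which stores only
        element symbols and coordinates.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _detect_format(path, format)
    if fmt == "pdb":
        return _read_pdb(path, dt)
    return _read_xyz(path, dt, topology)


def write_trajectory(
    traj: Trajectory, path: str | Path, format: str | None = None
) -> None:
    """Write a trajectory as a multi-model PDB or an XYZ file.

    Round-trips through :func:`read_trajectory` within format precision
    (1e-3 Å for PDB fixed columns, 1e-5 Å for XYZ).
    """
    path = Path(path)
    fmt = _detect_format(path, format)
    top = traj.topology
    if fmt == "pdb":
        import biotite.structure as struc
        from biotite.structure.io.pdb import PDBFile

        arr = struc.AtomArray(top.n_atoms)
        arr.atom_name = np.array([str(a) for a in top.atom_names])
        arr.res_id = top.residue_ids.copy()
        arr.res_name = np.array([str(r) for r in top.residue_names])
        arr.chain_id = np.array([str(c) for c in top.chain_ids])
        arr.element = np.array(
            [guess_element(str(a)) for a in top.atom_names]
        )
        arrays = []
        for f in range(traj.n_frames):
            a = arr.copy()
            a.coord = np.asarray(traj.frames[f], dtype=np.float32)
            arrays.append(a)
        pdb = PDBFile()
        pdb.set_structure(struc.stack(arrays))
        pdb.write(str(path))
    else:
        with open(path, "w") as fh:
            for f in range(traj.n_frames):
                fh.write(f"{top.n_atoms}\n")
                fh.write(f"frame {f} t={traj.times[f]:.6f} ns\n")
                for name, xyz in zip(top.atom_names, traj.frames[f]):
                    fh.write(
                        f"{name} {xyz[0]:.5f} {xyz[1]:.5f} {xyz[2]:.5f}\n"
                    )


# ---------------------------------------------------------------------------
# Per-atom parameter tables
# ---------------------------------------------------------------------------

_PARAM_COLUMNS = ["name", "charge", "rmin_half", "epsilon", "gb_radius", "gb_screen"]


def read_parameters(
    path: str | Path, topology: Structure | None = None
) -> EnergyParameters:
    """Read a per-atom parameter table (CSV or whitespace separated).

    Columns: ``name,charge,rmin_half,epsilon,gb_radius,gb_screen``, one row
    per atom in topology order.  When a topology is supplied the row count
    must match; rows are aligned by position and a name mismatch raises a
    warning rather than an error (names in parameter tables frequently use a
    different convention than coordinate files).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    missing = [c for c in _PARAM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"parameter table is missing columns {missing}")
    if df[_PARAM_COLUMNS[1:]].isna().any().any():
        bad = df.index[df[_PARAM_COLUMNS[1:]].isna().any(axis=1)].tolist()
        raise ValueError(f"parameter table has NaN values in rows {bad}")
    params = EnergyParameters(
        charge=df["charge"].to_numpy(float),
        lj_rmin_half=df["rmin_half"].to_numpy(float),
        lj_epsilon=df["epsilon"].to_numpy(float),
        gb_radius=df["gb_radius"].to_numpy(float),
        gb_screen=df["gb_screen"].to_numpy(float),
        atom_names=df["name"].to_numpy(object),
    )
    if topology is not None:
        if params.n_atoms != topology.n_atoms:
            table_names = set(map(str, df["name"]))
            absent = [
                str(a) for a in topology.atom_names if str(a) not in table_names
            ]
            raise ValueError(
                f"parameter table has {params.n_atoms} rows but topology has "
                f"{topology.n_atoms} atoms; atoms without parameters: "
                f"{absent[:10]}"
            )
        mismatched = [
            (i, str(t), str(p))
            for i, (t, p) in enumerate(zip(topology.atom_names, params.atom_names))
            if str(t) != str(p)
        ]
        if mismatched:
            warnings.warn(
                f"{len(mismatched)} atom name(s) differ between topology and "
                f"parameter table (first: index {mismatched[0][0]}, "
                f"{mismatched[0][1]!r} vs {mismatched[0][2]!r}); rows aligned "
                "by position",
                stacklevel=2,
            )
    return params


def write_parameters(params: EnergyParameters, path: str | Path) -> None:
    """Write a parameter table in the CSV dialect read_parameters accepts."""
    names = (
        params.atom_names
        if params.atom_names is not None
        else np.array([f"X{i}" for i in range(params.n_atoms)], dtype=object)
    )
    df = pd.DataFrame(
        {
            "name": names,
            "charge": params.charge,
            "rmin_half": params.lj_rmin_half,
            "epsilon": params.lj_epsilon,
            "gb_radius": params.gb_radius,
            "gb_screen": params.gb_screen,
        }
    )
    df.to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

_BACKBONE_NAMES = {"N", "CA", "C", "O"}


def _eval_term(topology: Structure, tokens: list[str]) -> np.ndarray:
    """Evaluate one primitive term to a boolean mask."""
    if not tokens:
        raise ValueError("empty selection term")
    head = tokens[0].lower()
    names = np.array([str(a).upper() for a in topology.atom_names])
    if head == "backbone":
        if len(tokens) != 1:
            raise ValueError(f"unexpected token after 'backbone': {tokens[1]!r}")
        return np.isin(names, sorted(_BACKBONE_NAMES))
    if head == "all":
        if len(tokens) != 1:
            raise ValueError(f"unexpected token after 'all': {tokens[1]!r}")
        return np.ones(topology.n_atoms, dtype=bool)
    if head == "resid":
        if len(tokens) != 2:
            raise ValueError(f"'resid' expects one argument, got {tokens[1:]}")
        arg = tokens[1]
        m = re.fullmatch(r"(-?\d+)(?:-(-?\d+))?", arg)
        if m is None:
            raise ValueError(f"cannot parse residue range {arg!r}")
        lo = int(m.group(1))
        hi = int(m.group(2)) if m.group(2) is not None else lo
        if hi < lo:
            raise ValueError(f"inverted residue range {arg!r}")
        return (topology.residue_ids >= lo) & (topology.residue_ids <= hi)
    if head == "chain":
        if len(tokens) != 2:
            raise ValueError(f"'chain' expects one argument, got {tokens[1:]}")
        chains = np.array([str(c) for c in topology.chain_ids])
        return chains == tokens[1]
    raise ValueError(f"unknown selection token {tokens[0]!r}")


def make_selection(topology: Structure, expression: str) -> Selection:
    """Build a Selection from a small expression grammar.

    Grammar: primitive terms ``backbone``, ``all``, ``resid A-B`` (or
    ``resid A``), ``chain X``; ``and`` intersects terms and ``or`` (lower
    precedence) unions groups of ``and``-terms.  ``backbone`` matches atoms
    named N, CA, C, O.  An expression selecting no atoms is an error.
    """
    tokens = expression.split()
    if not tokens:
        raise ValueError("empty selection expression")
    # split on 'or', then on 'and' within each group
    or_groups: list[list[str]] = [[]]
    for tok in tokens:
        if tok.lower() == "or":
            or_groups.append([])
        else:
            or_groups[-1].append(tok)
    mask = np.zeros(topology.n_atoms, dtype=bool)
    for group in or_groups:
        and_terms: list[list[str]] = [[]]
        for tok in group:
            if tok.lower() == "and":
                and_terms.append([])
            else:
                and_terms[-1].append(tok)
        group_mask = np.ones(topology.n_atoms, dtype=bool)
        for term in and_terms:
            group_mask &= _eval_term(topology, term)
        mask |= group_mask
    indices = np.flatnonzero(mask)
    if indices.size == 0:
        raise ValueError(
            f"selection {expression!r} matches no atoms on this topology"
        )
    return Selection(indices=indices, label=expression)
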