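"""Molecular system data model, PDB I/O, and geometric primitives.

The central container is :class:`MolecularSystem` — an ordered list of atoms
annotated with residue identity plus a *chain partition* that assigns each
chain to one side of a protein–protein interface ("ligand" — e.g. the hormone
— or "receptor").  An ordered set of conformations of one topology is an
:class:`Ensemble`, the stand-in for frames sampled from molecular dynamics.

Geometry primitives: cutoff neighbour search (KD-tree, exact), least-squares
rigid-body superposition RMSD (Kabsch), and Shrake–Rupley sphere-sampling
solvent-accessible surface area.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import FormatOverflowError, ParameterError, PDBParseError, TopologyError
from .params import SOLVENT_RESNAMES, VDW_RADII

logger = logging.getLogger(__name__)

#: (chain id, residue number, insertion code)
ResidueKey = tuple[str, int, str]

LIGAND = "ligand"
RECEPTOR = "receptor"


@dataclass
class Atom:
    """One atom: identity, coordinates (Å) and residue membership."""

    serial: int
    name: str
    element: str
    coords: np.ndarray
    residue_key: ResidueKey
    residue_name: str
    formal_charge_contribution: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not self.element:
            raise ValueError(f"atom {self.serial} {self.name}: empty element")
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial} {self.name}: bad coordinates")
        self.residue_name = self.residue_name.upper()

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"

    @property
    def chain_id(self) -> str:
        return self.residue_key[0]


class Residue(NamedTuple):
    """A contiguous run of atoms sharing one residue key."""

    key: ResidueKey
    name: str
    indices: tuple[int, ...]


@dataclass
class MolecularSystem:
    """An ordered collection of atoms with an interface chain partition."""

    atoms: list[Atom]
    chain_partition: dict[str, str] = field(default_factory=dict)
    title: str = ""

    def __post_init__(self) -> None:
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("atom serials are not unique")
        for chain, side in self.chain_partition.items():
            if side not in (LIGAND, RECEPTOR):
                raise ValueError(f"chain {chain}: side must be ligand/receptor, got {side}")
        self._invalidate()

    def _invalidate(self) -> None:
        self.__dict__.pop("_coords", None)
        self.__dict__.pop("_residues", None)

    # -- array views -------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array (cached)."""
        if "_coords" not in self.__dict__:
            self.__dict__["_coords"] = np.array([a.coords for a in self.atoms])
        return self.__dict__["_coords"]

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def heavy_indices(self) -> np.ndarray:
        return np.array([i for i, a in enumerate(self.atoms) if not a.is_hydrogen], dtype=int)

    # -- residues and sides ------------------------------------------------

    def residues(self) -> list[Residue]:
        """Residues as contiguous runs of atoms sharing a residue key."""
        if "_residues" not in self.__dict__:
            runs: list[Residue] = []
            seen: set[ResidueKey] = set()
            current: list[int] = []
            for i, atom in enumerate(self.atoms):
                if current and atom.residue_key != self.atoms[current[-1]].residue_key:
                    key = self.atoms[current[0]].residue_key
                    if key in seen:
                        raise ValueError(f"residue {key} is not a contiguous atom run")
                    seen.add(key)
                    runs.append(Residue(key, self.atoms[current[0]].residue_name, tuple(current)))
                    current = []
                current.append(i)
            if current:
                key = self.atoms[current[0]].residue_key
                if key in seen:
                    raise ValueError(f"residue {key} is not a contiguous atom run")
                runs.append(Residue(key, self.atoms[current[0]].residue_name, tuple(current)))
            self.__dict__["_residues"] = runs
        return self.__dict__["_residues"]

    def residue(self, key: ResidueKey) -> Residue:
        for res in self.residues():
            if res.key == key:
                return res
        raise KeyError(f"no residue {key}")

    def side_of(self, chain_id: str) -> str | None:
        return self.chain_partition.get(chain_id)

    def side_indices(self, side: str) -> np.ndarray:
        """Indices of all atoms whose chain belongs to *side*."""
        return np.array(
            [i for i, a in enumerate(self.atoms) if self.chain_partition.get(a.chain_id) == side],
            dtype=int,
        )

    # -- derived systems ---------------------------------------------------

    def subset(self, indices: Iterable[int], title: str | None = None) -> "MolecularSystem":
        """New system containing the selected atoms (original order kept)."""
        idx = sorted(set(int(i) for i in indices))
        atoms = [replace(self.atoms[i], coords=self.atoms[i].coords.copy()) for i in idx]
        return MolecularSystem(atoms, dict(self.chain_partition), title or self.title)

    def with_coords(self, coords: np.ndarray, title: str | None = None) -> "MolecularSystem":
        """Same topology with replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise TopologyError(
                f"coordinate array shape {coords.shape} != ({self.n_atoms}, 3)"
            )
        atoms = [replace(a, coords=coords[i].copy()) for i, a in enumerate(self.atoms)]
        return MolecularSystem(atoms, dict(self.chain_partition), title or self.title)

    def max_serial(self) -> int:
        return max((a.serial for a in self.atoms), default=0)


@dataclass
class Ensemble:
    """Ordered snapshots of one topology — stands in for an MD trajectory."""

    topology: MolecularSystem
    frames: list[np.ndarray]
    frame_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.frames = [np.asarray(f, dtype=float) for f in self.frames]
        n = self.topology.n_atoms
        for i, f in enumerate(self.frames):
            if f.shape != (n, 3):
                raise TopologyError(f"frame {i}: shape {f.shape} != ({n}, 3)")
        if not self.frame_labels:
            self.frame_labels = [f"frame-{i}" for i in range(len(self.frames))]
        if len(self.frame_labels) != len(self.frames):
            raise ValueError("frame_labels length mismatch")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def system_at(self, i: int) -> MolecularSystem:
        return self.topology.with_coords(self.frames[i])

    def __iter__(self):
        return (self.system_at(i) for i in range(self.n_frames))


@dataclass
class GeometryMetrics:
    """Container for geometric observables."""

    rmsd: float | None = None
    sasa_total: float | None = None
    per_atom_sasa: np.ndarray | None = None


# ---------------------------------------------------------------------------
# PDB I/O (via biotite)
# ---------------------------------------------------------------------------

_ELEMENT_TWO_LETTER = {"CL", "BR", "FE", "ZN", "MG", "MN", "SE", "NA", "CA"}


def _guess_element(atom_name: str, res_name: str = "") -> str:
    """Element from a PDB atom name when columns 77-78 are blank."""
    name = atom_name.strip()
    stripped = name.lstrip("0123456789")
    if not stripped:
        raise PDBParseError(f"cannot infer element for atom name {atom_name!r}")
    # ions named like the element itself
    if res_name.strip().upper() in _ELEMENT_TWO_LETTER and name.upper() == res_name.strip().upper():
        return name.capitalize()
    if stripped[0] == "H" or (name and name[0].isdigit()):
        return "H"
    two = stripped[:2].upper()
    if two in _ELEMENT_TWO_LETTER and len(name) >= 4:
        return two.capitalize()
    return stripped[0].upper()


def _prevalidate_pdb(path: Path) -> None:
    """Cheap scan for malformed fixed columns, reporting the line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM  ", "HETATM")):
                continue
            if len(line.rstrip("\n")) < 54:
                raise PDBParseError("ATOM record shorter than coordinate columns", lineno)
            try:
                int(line[22:26])
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
            except ValueError as exc:
                raise PDBParseError(f"malformed ATOM record ({exc})", lineno) from None


def read_pdb(
    path: str | Path,
    chain_partition: dict[str, str] | None = None,
    drop_solvent: bool = True,
    altloc: str = "occupancy",
) -> MolecularSystem | Ensemble:
    """Read a PDB file into a system (single model) or ensemble (multi-model).

    Altloc variants collapse to the highest-occupancy one (ties resolved by
    altloc letter order).  Solvent and simple ion records are dropped with a
    logged count, since all downstream analyses act on the solute.
    """
    from biotite.structure.io.pdb import PDBFile

    path = Path(path)
    _prevalidate_pdb(path)
    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    try:
        stack = pdb.get_structure(altloc=altloc)
    except Exception as exc:  # biotite raises InvalidFileError on ragged models
        raise TopologyError(f"{path}: inconsistent models ({exc})") from exc

    arr0 = stack[0]
    elements = []
    for i in range(arr0.array_length()):
        el = arr0.element[i].strip()
        elements.append(el.capitalize() if el else _guess_element(arr0.atom_name[i], arr0.res_name[i]))

    keep = np.ones(arr0.array_length(), dtype=bool)
    if drop_solvent:
        solvent = np.array([rn.strip().upper() in SOLVENT_RESNAMES for rn in arr0.res_name])
        if solvent.any():
            logger.info("%s: dropped %d solvent/ion atoms", path.name, int(solvent.sum()))
        keep &= ~solvent

    idx = np.where(keep)[0]

    def build(model_arr) -> MolecularSystem:
        atoms = []
        for serial, i in enumerate(idx, start=1):
            ins = model_arr.ins_code[i].strip() if "ins_code" in model_arr.get_annotation_categories() else ""
            atoms.append(
                Atom(
                    serial=serial,
                    name=model_arr.atom_name[i].strip(),
                    element=elements[i],
                    coords=model_arr.coord[i],
                    residue_key=(str(model_arr.chain_id[i]).strip(), int(model_arr.res_id[i]), ins),
                    residue_name=str(model_arr.res_name[i]).strip(),
                )
            )
        return MolecularSystem(atoms, dict(chain_partition or {}), title=path.stem)

    system = build(arr0)
    if n_models <= 1:
        return system
    frames = [np.asarray(stack[m].coord[idx], dtype=float) for m in range(n_models)]
    return Ensemble(system, frames, [f"model-{m + 1}" for m in range(n_models)])


def read_pdb_directory(
    directory: str | Path,
    chain_partition: dict[str, str] | None = None,
    pattern: str = "*.pdb",
) -> Ensemble:
    """Treat an ordered directory of single-model PDB files as one ensemble."""
    directory = Path(directory)
    paths = sorted(directory.glob(pattern))
    if not paths:
        raise FileNotFoundError(f"no {pattern} files in {directory}")
    systems = []
    for p in paths:
        s = read_pdb(p, chain_partition=chain_partition)
        if isinstance(s, Ensemble):
            raise TopologyError(f"{p}: multi-model file inside an ensemble directory")
        systems.append(s)
    topo = systems[0]
    for p, s in zip(paths[1:], systems[1:]):
        if s.n_atoms != topo.n_atoms:
            raise TopologyError(f"{p}: atom count {s.n_atoms} != {topo.n_atoms}")
    return Ensemble(topo, [s.coords for s in systems], [p.stem for p in paths])


def write_pdb(system: "MolecularSystem | Ensemble", path: str | Path) -> None:
    """Write a system (or every frame of an ensemble) in PDB v3.3 format."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    if isinstance(system, Ensemble):
        topo = system.topology
        coords_list = system.frames
    else:
        topo = system
        coords_list = [topo.coords]

    for coords in coords_list:
        if np.any(np.abs(coords) >= 10000.0):
            raise FormatOverflowError("coordinate magnitude >= 10,000 Å does not fit PDB columns")

    n = topo.n_atoms
    arr = struc.AtomArray(n)
    arr.chain_id = np.array([a.residue_key[0] for a in topo.atoms], dtype="U4")
    arr.res_id = np.array([a.residue_key[1] for a in topo.atoms], dtype=int)
    arr.ins_code = np.array([a.residue_key[2] for a in topo.atoms], dtype="U1")
    arr.res_name = np.array([a.residue_name for a in topo.atoms], dtype="U5")
    arr.atom_name = np.array([a.name for a in topo.atoms], dtype="U6")
    arr.element = np.array([a.element.upper() for a in topo.atoms], dtype="U2")
    arr.hetero = np.zeros(n, dtype=bool)

    pdb = PDBFile()
    if len(coords_list) == 1:
        arr.coord = np.asarray(coords_list[0], dtype=np.float32)
        pdb.set_structure(arr)
    else:
        stack = struc.stack([arr] * len(coords_list))
        stack.coord = np.asarray(np.stack(coords_list), dtype=np.float32)
        pdb.set_structure(stack)
    pdb.write(str(path))


def write_xyz(system: MolecularSystem, path: str | Path, comment: str = "") -> None:
    """Write plain XYZ (element + Cartesian Å), e.g. for external QM codes."""
    lines = [str(system.n_atoms), comment or system.title]
    for a in system.atoms:
        x, y, z = a.coords
        lines.append(f"{a.element:<2s} {x:15.8f} {y:15.8f} {z:15.8f}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Geometry primitives
# ---------------------------------------------------------------------------


def neighbor_pairs(
    coords: np.ndarray,
    cutoff: float,
    selection_a: Sequence[int],
    selection_b: Sequence[int],
) -> set[tuple[int, int]]:
    """All pairs (a in A, b in B) with Euclidean distance <= cutoff.

    Exact (KD-tree backed, equal to brute force); self pairs (a == b) are
    excluded when the selections overlap.  Empty selections yield the empty
    set.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    sel_a = np.asarray(list(selection_a), dtype=int)
    sel_b = np.asarray(list(selection_b), dtype=int)
    if sel_a.size == 0 or sel_b.size == 0:
        return set()
    tree = cKDTree(coords[sel_b])
    hits = tree.query_ball_point(coords[sel_a], r=cutoff)
    pairs: set[tuple[int, int]] = set()
    for ia, neigh in zip(sel_a, hits):
        for jb in neigh:
            b = int(sel_b[jb])
            if b != int(ia):
                pairs.add((int(ia), b))
    return pairs


def superpose_rmsd(
    coords_x: np.ndarray, coords_y: np.ndarray, weights: np.ndarray | None = None
) -> float:
    """Least-squares rigid-body (rotation + translation, no reflection) RMSD.

    Kabsch algorithm on mean-centred coordinates; with *weights* the weighted
    RMSD after weighted superposition is returned.
    """
    X = np.asarray(coords_x, dtype=float)
    Y = np.asarray(coords_y, dtype=float)
    if X.shape != Y.shape or X.ndim != 2 or X.shape[1] != 3:
        raise ValueError(f"shape mismatch: {X.shape} vs {Y.shape}")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 points")
    if weights is None:
        w = np.ones(X.shape[0])
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (X.shape[0],) or np.any(w < 0) or w.sum() == 0:
            raise ValueError("bad weights")
    w = w / w.sum()
    xc = X - (w[:, None] * X).sum(axis=0)
    yc = Y - (w[:, None] * Y).sum(axis=0)
    H = (w[:, None] * xc).T @ yc
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    diff = yc - xc @ R.T
    msd = float((w * np.einsum("ij,ij->i", diff, diff)).sum())
    return math.sqrt(max(msd, 0.0))


def _sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform points on the unit sphere (golden-spiral lattice)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )


def atom_radii(elements: Sequence[str], table: dict[str, float] | None = None) -> np.ndarray:
    """Van der Waals radii for a list of elements; errors on missing entries."""
    table = table if table is not None else VDW_RADII
    missing = sorted({e for e in elements if e not in table})
    if missing:
        raise ParameterError(f"no van der Waals radius for element(s): {', '.join(missing)}")
    return np.array([table[e] for e in elements])


def sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> GeometryMetrics:
    """Shrake–Rupley solvent-accessible surface area.

    Each atom is expanded by the probe radius and sampled with a golden-spiral
    point lattice; a point is accessible when it lies outside every other
    expanded sphere.  Per-atom areas sum to the total exactly.
    """
    if probe_radius < 0:
        raise ValueError("probe radius must be >= 0")
    if n_points < 92:
        raise ValueError("n_points must be >= 92 for a usable sphere sampling")
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = coords.shape[0]
    if radii.shape != (n,):
        raise ValueError("radii length must match atom count")
    expanded = radii + probe_radius
    unit = _sphere_points(n_points)
    tree = cKDTree(coords)
    rmax = float(expanded.max()) if n else 0.0
    per_atom = np.zeros(n)
    for i in range(n):
        ri = expanded[i]
        pts = coords[i] + ri * unit
        neigh = [j for j in tree.query_ball_point(coords[i], ri + rmax) if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neigh:
            d2 = np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
            accessible &= d2 > expanded[j] ** 2
        per_atom[i] = 4.0 * np.pi * ri**2 * accessible.sum() / n_points
    return GeometryMetrics(sasa_total=float(per_atom.sum()), per_atom_sasa=per_atom)


def system_sasa(
    system: MolecularSystem,
    probe_radius: float = 1.4,
    n_points: int = 960,
    radii_table: dict[str, float] | None = None,
) -> GeometryMetrics:
    """SASA of a system using the bundled van der Waals radii."""
    return sasa(system.coords, atom_radii(system.elements, radii_table), probe_radius, n_points)
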