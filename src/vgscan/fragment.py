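"""QM-cluster fragmentation: truncation, chemical capping, charge bookkeeping.

For efficient interaction-energy calculations on a large complex, the
receptor is truncated at a given distance from the bound ligand
(whole-residue granularity) and every severed peptide bond is chemically
capped: an acetyl (ACE) group terminates an exposed N-terminus and an
N-methylamide (NME) group an exposed C-terminus, so no dangling valences or
artificial charges are introduced.  Cap atoms inherit the coordinates of the
removed neighbour's backbone atoms (C/O/CA for ACE, N/H/CA for NME), which
places them exactly along the removed carbonyl/amide direction.

A convergence scan repeats the truncation over a radius ladder (3–23 Å by
default), computes the interaction Gibbs free energy at each radius, and
reports the retention relative to the largest fragment, supporting the
choice of the smallest adequate model size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from . import params
from .errors import FragmentationError, ParameterError
from .structmodel import Atom, MolecularSystem, Residue, ResidueKey

logger = logging.getLogger(__name__)

ANY_HEAVY_ATOM = "any_heavy_atom"
C_ALPHA = "c_alpha"


@dataclass
class FragmentationConfig:
    """Parameters of the truncation protocol."""

    radius: float = 11.0  # Å from any ligand heavy atom
    radius_scan: tuple[float, ...] = tuple(float(r) for r in range(3, 24))
    distance_reference: str = ANY_HEAVY_ATOM  # or C_ALPHA
    prune_side_chains: bool = False

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if any(r <= 0 for r in self.radius_scan) or list(self.radius_scan) != sorted(
            self.radius_scan
        ):
            raise ValueError("radius_scan must be positive and ascending")
        if self.distance_reference not in (ANY_HEAVY_ATOM, C_ALPHA):
            raise ValueError(f"unknown distance reference {self.distance_reference!r}")


@dataclass
class CapRecord:
    """Bookkeeping for one placed cap."""

    cap_type: str  # "ACE" | "NME"
    capped_residue: ResidueKey  # retained residue whose cut bond is terminated
    replaced_residue: ResidueKey  # eliminated neighbour supplying the geometry
    new_serials: tuple[int, ...]


@dataclass
class Fragment:
    """A truncated, capped subsystem with charge bookkeeping."""

    system: MolecularSystem
    cap_log: list[CapRecord] = field(default_factory=list)
    total_charge: int = 0
    radius: float | None = None

    @property
    def n_atoms(self) -> int:
        return self.system.n_atoms


# ---------------------------------------------------------------------------
# formal charges
# ---------------------------------------------------------------------------


def find_disulfides(system: MolecularSystem, cutoff: float = 2.3) -> set[ResidueKey]:
    """Residue keys of cysteines whose SG pairs within *cutoff* Å."""
    sg = [
        (i, system.atoms[i].residue_key)
        for i, a in enumerate(system.atoms)
        if a.residue_name == "CYS" and a.name == "SG"
    ]
    bridged: set[ResidueKey] = set()
    for n, (i, key_i) in enumerate(sg):
        for j, key_j in sg[n + 1 :]:
            if np.linalg.norm(system.coords[i] - system.coords[j]) <= cutoff:
                bridged.update((key_i, key_j))
    return bridged


def assign_formal_charges(
    system: MolecularSystem | Fragment,
) -> tuple[int, dict[ResidueKey, int]]:
    """Formal charge per residue and the total, pH-7 convention.

    Asp/Glu −1, Lys/Arg +1, His 0 unless both ring nitrogens are protonated,
    free N-terminus +1, free C-terminus −1; ACE/NME-capped termini and cap
    residues contribute 0.  Cysteines (free or disulfide-bridged) are neutral.
    """
    if isinstance(system, Fragment):
        system = system.system
    per_residue: dict[ResidueKey, int] = {}
    residues = system.residues()
    # group by chain in order
    chains: dict[str, list[Residue]] = {}
    for res in residues:
        chains.setdefault(res.key[0], []).append(res)

    for chain_residues in chains.values():
        for pos, res in enumerate(chain_residues):
            name = res.name
            if name in params.CAP_RESNAMES:
                per_residue[res.key] = 0
                continue
            if name not in params.STANDARD_AA:
                raise ParameterError(f"unknown residue name {name!r} at {res.key}")
            charge = params.SIDECHAIN_FORMAL_CHARGE.get(name, 0)
            if name == "HIS":
                atom_names = {system.atoms[i].name for i in res.indices}
                if {"HD1", "HE2"} <= atom_names:
                    charge = +1
            # termini
            prev_name = chain_residues[pos - 1].name if pos > 0 else None
            next_name = (
                chain_residues[pos + 1].name if pos + 1 < len(chain_residues) else None
            )
            if prev_name is None:
                charge += 1  # free N-terminus (an ACE neighbour would be prev)
            if next_name is None:
                charge -= 1  # free C-terminus (an NME neighbour would be next)
            per_residue[res.key] = charge
    total = sum(per_residue.values())
    return total, per_residue


# ---------------------------------------------------------------------------
# truncation
# ---------------------------------------------------------------------------


def retained_receptor_residues(
    system: MolecularSystem, radius: float, distance_reference: str = ANY_HEAVY_ATOM
) -> list[Residue]:
    """Receptor residues with a reference atom within *radius* of any ligand
    heavy atom.  Cap residues follow their neighbour (see :func:`truncate`)."""
    lig_idx = [i for i in system.side_indices("ligand") if not system.atoms[i].is_hydrogen]
    if not lig_idx:
        raise FragmentationError("chain partition defines no ligand atoms")
    tree = cKDTree(system.coords[lig_idx])
    retained = []
    for res in system.residues():
        if system.side_of(res.key[0]) != "receptor":
            continue
        if res.name in params.CAP_RESNAMES:
            continue  # decided from the neighbour afterwards
        if distance_reference == C_ALPHA:
            ref = [i for i in res.indices if system.atoms[i].name == "CA"]
        else:
            ref = [i for i in res.indices if not system.atoms[i].is_hydrogen]
        if not ref:
            continue
        dmin, _ = tree.query(system.coords[ref])
        if float(np.min(dmin)) <= radius:
            retained.append(res)
    return retained


def _cap_atoms_from_neighbor(
    cap_type: str,
    neighbor: Residue,
    system: MolecularSystem,
    serial_start: int,
) -> list[Atom]:
    """Build ACE/NME cap atoms by inheriting the removed neighbour's backbone."""
    names = {system.atoms[i].name: i for i in neighbor.indices}
    chain, resnum, ins = neighbor.key

    def take(src: str, dst: str) -> tuple[str, np.ndarray] | None:
        if src in names:
            return dst, system.coords[names[src]].copy()
        return None

    if cap_type == "ACE":
        spec = [take("C", "C"), take("O", "O"), take("CA", "CH3") or take("CH3", "CH3")]
        elements = {"C": "C", "O": "O", "CH3": "C"}
    else:  # NME
        spec = [take("N", "N"), take("H", "H"), take("CA", "CH3") or take("CH3", "CH3")]
        elements = {"N": "N", "H": "H", "CH3": "C"}
    spec = [s for s in spec if s is not None]
    required = {"ACE": {"C", "CH3"}, "NME": {"N", "CH3"}}[cap_type]
    if not required <= {name for name, _ in spec}:
        raise FragmentationError(
            f"cannot build {cap_type} cap from residue {neighbor.name} {neighbor.key}: "
            f"backbone atoms missing"
        )
    atoms = []
    for off, (name, xyz) in enumerate(spec):
        atoms.append(
            Atom(
                serial=serial_start + off,
                name=name,
                element=elements[name],
                coords=xyz,
                residue_key=(chain, resnum, ins),
                residue_name=cap_type,
            )
        )
    return atoms


def truncate(
    system: MolecularSystem, config: FragmentationConfig, radius: float | None = None
) -> Fragment:
    """Truncate the receptor around the ligand and cap severed peptide bonds.

    Retains every receptor residue whose reference atoms come within the
    radius of any ligand heavy atom (whole-residue granularity); consecutive
    retained residues keep their peptide bond, and each chain break is capped
    (ACE on an exposed N, NME on an exposed C).  Ligand atoms are kept
    unchanged.  Raises :class:`FragmentationError` when nothing survives.
    """
    radius = config.radius if radius is None else float(radius)
    if not system.chain_partition:
        raise FragmentationError("system has no chain partition")
    retained = retained_receptor_residues(system, radius, config.distance_reference)
    if not retained:
        raise FragmentationError(f"radius {radius} Å retains zero receptor residues")
    retained_keys = {r.key for r in retained}

    # existing cap residues follow their adjacent residue
    chains: dict[str, list[Residue]] = {}
    for res in system.residues():
        if system.side_of(res.key[0]) == "receptor":
            chains.setdefault(res.key[0], []).append(res)
    for chain_residues in chains.values():
        for pos, res in enumerate(chain_residues):
            if res.name not in params.CAP_RESNAMES:
                continue
            neigh_pos = pos + 1 if res.name == "ACE" else pos - 1
            if 0 <= neigh_pos < len(chain_residues):
                if chain_residues[neigh_pos].key in retained_keys:
                    retained_keys.add(res.key)

    ligand_atoms = [
        replace(system.atoms[i], coords=system.atoms[i].coords.copy())
        for i in range(system.n_atoms)
        if system.side_of(system.atoms[i].chain_id) == "ligand"
    ]
    dropped_chains = {
        a.chain_id for a in system.atoms if system.side_of(a.chain_id) is None
    }
    if dropped_chains:
        logger.info("truncate: dropping unpartitioned chains %s", sorted(dropped_chains))

    new_atoms: list[Atom] = list(ligand_atoms)
    cap_log: list[CapRecord] = []
    next_serial = system.max_serial() + 1

    for chain_residues in chains.values():
        for pos, res in enumerate(chain_residues):
            if res.key not in retained_keys:
                continue
            if res.name not in params.CAP_RESNAMES:
                prev_res = chain_residues[pos - 1] if pos > 0 else None
                if prev_res is not None and prev_res.key not in retained_keys:
                    cap = _cap_atoms_from_neighbor("ACE", prev_res, system, next_serial)
                    next_serial += len(cap)
                    new_atoms.extend(cap)
                    cap_log.append(
                        CapRecord("ACE", res.key, prev_res.key, tuple(a.serial for a in cap))
                    )
            new_atoms.extend(
                replace(system.atoms[i], coords=system.atoms[i].coords.copy())
                for i in res.indices
            )
            if res.name not in params.CAP_RESNAMES:
                next_res = chain_residues[pos + 1] if pos + 1 < len(chain_residues) else None
                if next_res is not None and next_res.key not in retained_keys:
                    cap = _cap_atoms_from_neighbor("NME", next_res, system, next_serial)
                    next_serial += len(cap)
                    new_atoms.extend(cap)
                    cap_log.append(
                        CapRecord("NME", res.key, next_res.key, tuple(a.serial for a in cap))
                    )

    frag_system = MolecularSystem(
        new_atoms, dict(system.chain_partition), title=f"{system.title}|r{radius:g}"
    )
    _warn_cap_clashes(frag_system, cap_log)
    total_charge, _ = assign_formal_charges(frag_system)
    return Fragment(frag_system, cap_log, total_charge, radius)


def _warn_cap_clashes(system: MolecularSystem, cap_log: list[CapRecord]) -> None:
    cap_serials = {s for rec in cap_log for s in rec.new_serials}
    if not cap_serials:
        return
    serial_to_idx = {a.serial: i for i, a in enumerate(system.atoms)}
    tree = cKDTree(system.coords)
    for serial in sorted(cap_serials):
        i = serial_to_idx[serial]
        ai = system.atoms[i]
        for j in tree.query_ball_point(system.coords[i], 1.0):
            aj = system.atoms[j]
            if j == i or aj.residue_key == ai.residue_key:
                continue
            logger.warning(
                "cap atom %s %s (%s) within 1.0 Å of %s %s (%s)",
                ai.name, ai.residue_key, ai.residue_name,
                aj.name, aj.residue_key, aj.residue_name,
            )


def hydrogen_cap_side_chain(system: MolecularSystem, residue_key: ResidueKey) -> MolecularSystem:
    """Prune a side chain beyond CB and terminate the cut bond with hydrogen.

    The CB (cut atom) is replaced by an H placed along the CA→CB unit vector
    at 1.09 Å; used only when a configuration explicitly requests side-chain
    pruning of boundary residues.
    """
    from .vgs import _replace_side_chain_with_h  # shared geometry op

    return _replace_side_chain_with_h(system, residue_key, rename=None)


# ---------------------------------------------------------------------------
# convergence scan
# ---------------------------------------------------------------------------


@dataclass
class ConvergencePoint:
    radius: float
    n_atoms: int | None = None
    total_charge: int | None = None
    dG_int: float | None = None
    retention: float | None = None
    error: str | None = None


@dataclass
class ConvergenceProfile:
    """Per-radius fragment sizes, charges and interaction-energy retention."""

    points: list[ConvergencePoint]

    @property
    def radii(self) -> list[float]:
        return [p.radius for p in self.points]

    def select_radius(self, retention_threshold: float) -> float | None:
        """Smallest radius whose retention meets the threshold."""
        for p in self.points:
            if p.retention is not None and p.retention >= retention_threshold:
                return p.radius
        return None


def convergence_scan(system: MolecularSystem, config: FragmentationConfig, backend) -> ConvergenceProfile:
    """Interaction energy versus truncation radius, relative to the largest.

    Retention is ΔG_int(r) / ΔG_int(r_max); the profile carries fragment
    sizes and total charges alongside.  A backend failure at one radius is
    recorded and the scan continues.
    """
    from .energy import interaction_energy

    if len(config.radius_scan) < 2:
        raise ValueError("radius_scan needs at least two radii")
    points: list[ConvergencePoint] = []
    for r in config.radius_scan:
        point = ConvergencePoint(radius=float(r))
        try:
            frag = truncate(system, config, radius=r)
            point.n_atoms = frag.n_atoms
            point.total_charge = frag.total_charge
            point.dG_int = interaction_energy(frag.system, backend).dG_int
        except Exception as exc:  # partial profile with failure markers
            point.error = str(exc)
            logger.warning("convergence scan failed at %g Å: %s", r, exc)
        points.append(point)
    ref = points[-1].dG_int
    if ref is not None and ref != 0.0:
        for p in points:
            if p.dG_int is not None:
                p.retention = p.dG_int / ref
    return ConvergenceProfile(points)


# ---------------------------------------------------------------------------
# dimers
# ---------------------------------------------------------------------------


def extract_dimer(
    system: MolecularSystem, residue_i: ResidueKey, residue_j: ResidueKey
) -> Fragment:
    """Excise two residues as blocked amino acids (capped dimer).

    Each residue keeps its coordinates and is terminated by an ACE cap on the
    N side and an NME cap on the C side (inherited from its neighbours when
    they exist), making the dimer suitable for export to external QM codes.
    """
    cap_log: list[CapRecord] = []
    new_atoms: list[Atom] = []
    next_serial = system.max_serial() + 1

    chains: dict[str, list[Residue]] = {}
    for res in system.residues():
        chains.setdefault(res.key[0], []).append(res)

    for key in (residue_i, residue_j):
        res = system.residue(key)
        if res.name in params.CAP_RESNAMES:
            raise FragmentationError(f"residue {key} is a cap; cannot extract as dimer member")
        chain_residues = chains[key[0]]
        pos = next(i for i, r in enumerate(chain_residues) if r.key == key)
        prev_res = chain_residues[pos - 1] if pos > 0 else None
        next_res = chain_residues[pos + 1] if pos + 1 < len(chain_residues) else None
        if prev_res is not None:
            cap = _cap_atoms_from_neighbor("ACE", prev_res, system, next_serial)
            next_serial += len(cap)
            new_atoms.extend(cap)
            cap_log.append(CapRecord("ACE", key, prev_res.key, tuple(a.serial for a in cap)))
        new_atoms.extend(
            replace(system.atoms[i], coords=system.atoms[i].coords.copy()) for i in res.indices
        )
        if next_res is not None:
            cap = _cap_atoms_from_neighbor("NME", next_res, system, next_serial)
            next_serial += len(cap)
            new_atoms.extend(cap)
            cap_log.append(CapRecord("NME", key, next_res.key, tuple(a.serial for a in cap)))

    dimer = MolecularSystem(
        new_atoms, dict(system.chain_partition), title=f"dimer {residue_i}/{residue_j}"
    )
    total_charge, _ = assign_formal_charges(dimer)
    return Fragment(dimer, cap_log, total_charge, radius=None)
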