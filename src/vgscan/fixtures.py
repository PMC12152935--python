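"""Synthetic two-sided protein complex with planted interface interactions.

The generator emulates the kind of input the protocol consumes: a hormone-
like "ligand" chain facing a "receptor" chain, with a planted salt bridge
(Glu/Arg), a neutral H-bond (Ser hydroxyl to a backbone carbonyl), a
hydrophobic cluster (Leu/Phe) and an S···O chalcogen contact (Met sulfur to
a backbone carbonyl), plus a sequence of jittered snapshots standing in for
MD frames.

Geometry is deliberately idealized: each chain is an extended strand on a
3.8 Å Cα grid, side chains are rigid local templates pointing across the
interface, and only polar hydrogens are present (amide H plus hydroxyl /
amine / guanidinium hydrogens).  Receptor residues facing a planted partner
are placed at individually solved heights so that every planted contact
hits its target distance *exactly* in frame 0; the remaining receptor
residues sit at a default separation that keeps them out of contact range.
Chain termini are blocked with ACE/NME caps so that no artificial terminal
charges enter the energetics.  Frames beyond the first carry seeded,
isotropic Gaussian coordinate jitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import FixtureError
from .structmodel import Atom, Ensemble, MolecularSystem

# ---------------------------------------------------------------------------
# rigid local templates (CA at origin, backbone along +x, side chain +y)
# ---------------------------------------------------------------------------

# trans-peptide geometry on a 3.8 Å Cα grid: C–N 1.33, N–CA 1.46, CA–C 1.52,
# C=O 1.23, O_i···N_{i+1} 2.24 — so consecutive on-grid residues form proper
# peptide bonds.  The amide N–H points away from the side-chain face.
BACKBONE_TEMPLATE: dict[str, tuple[float, float, float]] = {
    "N": (-1.407, -0.397, 0.0),
    "H": (-1.649, -1.368, 0.0),
    "CA": (0.0, 0.0, 0.0),
    "C": (1.430, 0.520, 0.0),
    "O": (1.683, 1.723, 0.0),
}

SIDECHAIN_TEMPLATES: dict[str, dict[str, tuple[float, float, float]]] = {
    "GLY": {},
    "ALA": {"CB": (0.0, 1.53, 0.0)},
    # hydroxyl tilted 40° off the side-chain axis so a planted acceptor on
    # that axis sees a collinear O-H while a second donor can approach OG
    # from the other side (reciprocal H-bond dyad)
    "SER": {"CB": (0.0, 1.53, 0.0), "OG": (0.0, 2.95, 0.0), "HG": (-0.617, 3.685, 0.0)},
    "LEU": {
        "CB": (0.0, 1.53, 0.0),
        "CG": (0.0, 3.05, 0.0),
        "CD1": (1.26, 3.85, 0.0),
        "CD2": (-1.26, 3.85, 0.0),
    },
    "PHE": {
        "CB": (0.0, 1.53, 0.0),
        "CG": (0.0, 3.03, 0.0),
        "CD1": (1.20, 3.73, 0.0),
        "CD2": (-1.20, 3.73, 0.0),
        "CE1": (1.20, 5.12, 0.0),
        "CE2": (-1.20, 5.12, 0.0),
        "CZ": (0.0, 5.82, 0.0),
    },
    "MET": {
        "CB": (0.0, 1.53, 0.0),
        "CG": (0.0, 3.05, 0.0),
        "SD": (0.0, 4.85, 0.0),
        "CE": (0.0, 5.70, 1.60),
    },
    "GLU": {
        "CB": (0.0, 1.53, 0.0),
        "CG": (0.0, 3.05, 0.0),
        "CD": (0.0, 4.55, 0.0),
        "OE1": (1.08, 5.17, 0.0),
        "OE2": (-1.08, 5.17, 0.0),
    },
    "ARG": {
        "CB": (0.0, 1.53, 0.0),
        "CG": (0.0, 3.05, 0.0),
        "CD": (0.0, 4.55, 0.0),
        "NE": (0.0, 5.90, 0.0),
        "HE": (0.95, 6.20, 0.0),
        "CZ": (0.0, 7.23, 0.0),
        "NH1": (1.15, 7.93, 0.0),
        "NH2": (-1.15, 7.93, 0.0),
        "HH11": (1.20, 8.93, 0.0),
        "HH12": (1.98, 7.50, 0.0),
        "HH21": (-1.20, 8.93, 0.0),
        "HH22": (-1.98, 7.50, 0.0),
    },
    "LYS": {
        "CB": (0.0, 1.53, 0.0),
        "CG": (0.0, 3.05, 0.0),
        "CD": (0.0, 4.55, 0.0),
        "CE": (0.0, 6.05, 0.0),
        "NZ": (0.0, 7.45, 0.0),
        "HZ1": (0.94, 7.80, 0.0),
        "HZ2": (-0.47, 7.80, 0.82),
        "HZ3": (-0.47, 7.80, -0.82),
    },
    "ASN": {
        "CB": (0.0, 1.53, 0.0),
        "CG": (0.0, 3.03, 0.0),
        "OD1": (1.06, 3.72, 0.0),
        "ND2": (-1.06, 3.72, 0.0),
        "HD21": (-1.06, 4.72, 0.0),
        "HD22": (-1.90, 3.25, 0.0),
    },
}

ELEMENT_FROM_NAME = {"N": "N", "O": "O", "S": "S", "H": "H", "C": "C"}

CA_SPACING = 3.8  # Å between consecutive Cα positions along the strand


def _element(atom_name: str) -> str:
    return ELEMENT_FROM_NAME[atom_name[0]]


# ---------------------------------------------------------------------------
# fixture specification
# ---------------------------------------------------------------------------

#: kind -> (ligand residue, receptor residue, ligand pair atom, receptor pair atom)
PLANT_RULES: dict[str, tuple[str, str, str, str]] = {
    "salt_bridge": ("GLU", "ARG", "OE1", "NH1"),
    "hbond": ("SER", "GLY", "OG", "O"),
    "hbond_backbone_donor": ("SER", "GLY", "OG", "N"),
    "hydrophobic": ("LEU", "PHE", "CD1", "CZ"),
    "chalcogen": ("MET", "GLY", "SD", "O"),
}


@dataclass(frozen=True)
class PlantedInteraction:
    """One engineered cross-interface contact at a ligand/receptor slot pair.

    ``tilt_deg`` inclines the contact axis off the interface normal (in the
    strand plane); ``align_bond`` names a (heavy, hydrogen) pair on the
    receptor residue whose bond is rotated to point along the contact axis —
    used to aim a backbone amide donor at a ligand acceptor.
    """

    kind: str
    ligand_slot: int
    receptor_slot: int
    target_distance: float
    tilt_deg: float = 0.0
    align_bond: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        if self.kind not in PLANT_RULES:
            raise FixtureError(f"unknown planted interaction kind {self.kind!r}")
        if self.target_distance <= 0:
            raise FixtureError("target distance must be positive")


#: the default complex plants one contact of each class; the serine engages
#: in a reciprocal dyad (donates to a backbone carbonyl, accepts a backbone
#: amide H) as hydroxyls at real interfaces commonly do.
DEFAULT_PLANTED: tuple[PlantedInteraction, ...] = (
    PlantedInteraction("salt_bridge", 1, 1, 2.8),
    PlantedInteraction("hbond", 3, 3, 2.9, tilt_deg=-40.0),
    PlantedInteraction("hbond_backbone_donor", 3, 4, 2.9, tilt_deg=55.0, align_bond=("N", "H")),
    PlantedInteraction("hydrophobic", 5, 5, 3.8),
    PlantedInteraction("chalcogen", 7, 7, 3.3),
)


@dataclass
class FixtureSpec:
    """Deterministic recipe for the synthetic complex and its snapshots."""

    n_ligand_residues: int = 10
    n_receptor_residues: int = 22
    receptor_slot_offset: int = -3  # receptor grid starts before/extends past the ligand
    default_separation: float = 11.0  # Å, Cα height of non-planted receptor residues
    planted: tuple[PlantedInteraction, ...] = DEFAULT_PLANTED
    n_snapshots: int = 10
    jitter_sigma: float = 0.15  # Å, per-coordinate Gaussian jitter (frames > 0)
    seed: int = 0
    capped_termini: bool = True

    def __post_init__(self) -> None:
        lig_slots = [p.ligand_slot for p in self.planted]
        if lig_slots and (min(lig_slots) < 0 or max(lig_slots) >= self.n_ligand_residues):
            raise FixtureError("planted ligand slot outside the chain")
        rec_last = self.receptor_slot_offset + self.n_receptor_residues
        for p in self.planted:
            if not self.receptor_slot_offset <= p.receptor_slot < rec_last:
                raise FixtureError("planted receptor slot outside the chain")
        if self.n_snapshots < 1:
            raise FixtureError("need at least one snapshot")
        if self.jitter_sigma < 0:
            raise FixtureError("jitter must be non-negative")


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------


def _residue_atoms(
    res_name: str,
    slot_x: float,
    ca_y: float,
    mirror: bool,
    residue_key,
    serial_start: int,
    rotation: float = 0.0,
) -> list[Atom]:
    """Place one residue from the rigid templates; mirror=True flips y.

    ``rotation`` (radians) spins the whole residue about the z axis through
    its Cα — used to point a planted acceptor/pair atom straight across the
    interface.
    """
    sign = -1.0 if mirror else 1.0
    template = dict(BACKBONE_TEMPLATE)
    template.update(SIDECHAIN_TEMPLATES[res_name])
    cos_t, sin_t = np.cos(rotation), np.sin(rotation)
    atoms = []
    for off, (name, (tx, ty, tz)) in enumerate(template.items()):
        vx, vy = tx, sign * ty
        rx = vx * cos_t - vy * sin_t
        ry = vx * sin_t + vy * cos_t
        atoms.append(
            Atom(
                serial=serial_start + off,
                name=name,
                element=_element(name),
                coords=np.array([slot_x + rx, ca_y + ry, tz]),
                residue_key=residue_key,
                residue_name=res_name,
            )
        )
    return atoms


def _cap_atoms(cap: str, slot_x: float, ca_y: float, mirror: bool, residue_key, serial_start: int):
    """ACE/NME caps built from the backbone template of a virtual neighbour."""
    sign = -1.0 if mirror else 1.0
    if cap == "ACE":
        spec = [("C", (1.430, 0.520, 0.0)), ("O", (1.683, 1.723, 0.0)), ("CH3", (0.0, 0.0, 0.0))]
    else:
        spec = [("N", (-1.407, -0.397, 0.0)), ("H", (-1.649, -1.368, 0.0)), ("CH3", (0.0, 0.0, 0.0))]
    atoms = []
    for off, (name, (tx, ty, tz)) in enumerate(spec):
        atoms.append(
            Atom(
                serial=serial_start + off,
                name=name,
                element="C" if name == "CH3" else _element(name),
                coords=np.array([slot_x + tx, ca_y + sign * ty, tz]),
                residue_key=residue_key,
                residue_name=cap,
            )
        )
    return atoms


def _solve_receptor_placement(
    lig_atom_xyz: np.ndarray,
    template: dict[str, tuple[float, float, float]],
    pair_atom: str,
    target: float,
    tilt_deg: float = 0.0,
    align_bond: tuple[str, str] | None = None,
) -> tuple[float, float, float]:
    """Receptor Cα (x, height, rotation) realizing the planted pair exactly.

    The contact axis leaves the ligand atom at ``tilt_deg`` off the interface
    normal (in the strand plane); the receptor pair atom lands on that axis
    at the target distance.  The residue (mirrored, side chain toward −y) is
    rotated about its Cα so that either the Cα→pair-atom vector or — with
    ``align_bond`` — the named heavy→hydrogen bond points back down the axis
    (collinear planted H-bonds).
    """

    def mirrored(name: str) -> np.ndarray:
        tx, ty, tz = template[name]
        return np.array([tx, -ty, tz])

    t = np.deg2rad(tilt_deg)
    u = np.array([np.sin(t), np.cos(t)])  # contact axis, ligand -> receptor
    v_pair = mirrored(pair_atom)
    if abs(v_pair[2] + lig_atom_xyz[2]) > 1e-9:
        raise FixtureError("planted pair atoms must lie in the strand plane")
    pair_abs = np.array(
        [lig_atom_xyz[0] + target * u[0], lig_atom_xyz[1] + target * u[1]]
    )

    if align_bond is None:
        align_vec = v_pair[:2]
    else:
        heavy, hydrogen = align_bond
        align_vec = (mirrored(hydrogen) - mirrored(heavy))[:2]
    rho = float(np.hypot(*align_vec))
    if rho == 0.0:
        raise FixtureError("degenerate alignment vector for planted contact")
    # rotate align_vec onto -u
    rotation = float(np.arctan2(-u[1], -u[0]) - np.arctan2(align_vec[1], align_vec[0]))

    cos_t, sin_t = np.cos(rotation), np.sin(rotation)
    v_rot = np.array(
        [v_pair[0] * cos_t - v_pair[1] * sin_t, v_pair[0] * sin_t + v_pair[1] * cos_t]
    )
    ca = pair_abs - v_rot
    return float(ca[0]), float(ca[1]), rotation


def _receptor_slots(spec: FixtureSpec) -> list[int]:
    """Grid slots occupied by receptor residues.

    Within the planted span, non-planted slots are left empty (the planted
    residues dip toward the interface like loop residues whose flanking
    stretch is unresolved); flat stretches extend on both sides until the
    requested residue count is reached.
    """
    planted = sorted(p.receptor_slot for p in spec.planted)
    slots: list[int] = []
    slot = spec.receptor_slot_offset
    while len(slots) < spec.n_receptor_residues:
        in_span = planted and (planted[0] - 1) <= slot <= (planted[-1] + 1)
        if not in_span or slot in planted:
            slots.append(slot)
        slot += 1
    return slots


def generate_fixture(spec: FixtureSpec | None = None) -> Ensemble:
    """Build the synthetic complex and its jittered snapshot ensemble.

    Frame 0 is the ideal geometry (planted distances exact); frames 1..N−1
    add seeded Gaussian jitter of ``jitter_sigma`` per coordinate.  Raises
    :class:`FixtureError` when a planted geometry is infeasible or the
    assembled frame 0 contains a steric clash (< 1.5 Å between heavy atoms
    of different residues).
    """
    spec = spec or FixtureSpec()
    by_rec_slot = {p.receptor_slot: p for p in spec.planted}
    if len(by_rec_slot) != len(spec.planted):
        raise FixtureError("planted interactions must use distinct receptor slots")
    by_lig_slot: dict[int, PlantedInteraction] = {}
    for p in spec.planted:
        prev = by_lig_slot.get(p.ligand_slot)
        if prev is not None and PLANT_RULES[prev.kind][0] != PLANT_RULES[p.kind][0]:
            raise FixtureError(
                f"ligand slot {p.ligand_slot} assigned conflicting residue types"
            )
        by_lig_slot.setdefault(p.ligand_slot, p)

    atoms: list[Atom] = []
    serial = 1

    def emit(new_atoms: list[Atom]) -> None:
        nonlocal serial
        atoms.extend(new_atoms)
        serial += len(new_atoms)

    # --- ligand chain A at y = 0, side chains toward +y
    lig_types: dict[int, str] = {}
    for slot in range(spec.n_ligand_residues):
        plant = by_lig_slot.get(slot)
        lig_types[slot] = PLANT_RULES[plant.kind][0] if plant else "ALA"
    if spec.capped_termini:
        emit(_cap_atoms("ACE", -CA_SPACING, 0.0, False, ("A", 0, ""), serial))
    for slot in range(spec.n_ligand_residues):
        emit(
            _residue_atoms(
                lig_types[slot], slot * CA_SPACING, 0.0, False, ("A", slot + 1, ""), serial
            )
        )
    if spec.capped_termini:
        emit(
            _cap_atoms(
                "NME",
                spec.n_ligand_residues * CA_SPACING,
                0.0,
                False,
                ("A", spec.n_ligand_residues + 1, ""),
                serial,
            )
        )

    lig_atom_xyz = {
        (a.residue_key[1], a.name): a.coords for a in atoms if a.residue_key[0] == "A"
    }

    # --- receptor chain B, mirrored, per-slot solved heights
    rec_slots = _receptor_slots(spec)
    placement: dict[int, tuple[float, float, float]] = {}  # slot -> (x, height, rot)
    rec_types: dict[int, str] = {}
    for slot in rec_slots:
        plant = by_rec_slot.get(slot)
        if plant is None:
            continue
        lig_res, rec_res, lig_atom, rec_atom = PLANT_RULES[plant.kind]
        rec_types[slot] = rec_res
        template = dict(BACKBONE_TEMPLATE)
        template.update(SIDECHAIN_TEMPLATES[rec_res])
        lig_xyz = lig_atom_xyz[(plant.ligand_slot + 1, lig_atom)]
        placement[slot] = _solve_receptor_placement(
            lig_xyz,
            template,
            rec_atom,
            plant.target_distance,
            tilt_deg=plant.tilt_deg,
            align_bond=plant.align_bond,
        )

    # Non-planted residues lie flat on the grid at the default separation.
    for slot in rec_slots:
        if slot in placement:
            continue
        rec_types[slot] = "ALA"
        placement[slot] = (slot * CA_SPACING, spec.default_separation, 0.0)

    first_rec = rec_slots[0]
    if spec.capped_termini:
        x0, y0, _ = placement[first_rec]
        emit(_cap_atoms("ACE", x0 - CA_SPACING, y0, True, ("B", 0, ""), serial))
    for n, slot in enumerate(rec_slots, start=1):
        x, y, rot = placement[slot]
        emit(_residue_atoms(rec_types[slot], x, y, True, ("B", n, ""), serial, rotation=rot))
    if spec.capped_termini:
        xl, yl, _ = placement[rec_slots[-1]]
        emit(
            _cap_atoms(
                "NME", xl + CA_SPACING, yl, True, ("B", len(rec_slots) + 1, ""), serial
            )
        )

    system = MolecularSystem(
        atoms, {"A": "ligand", "B": "receptor"}, title="synthetic interface fixture"
    )
    _check_clashes(system)

    # --- snapshots: Gaussian jitter emulating local thermal motion, with
    # two constraints real MD obeys: (i) hydrogens ride their parent heavy
    # atom (X-H bonds are effectively rigid under constraint dynamics), and
    # (ii) formed contacts never compress deep into the r^-12 wall — a
    # candidate frame is redrawn when any close cross-residue heavy-atom
    # pair (< 4 Å in the reference frame, peptide neighbours exempt) falls
    # below 95% of its reference distance.
    parent = _hydrogen_parents(system)
    close_pairs, ref_dists = _close_contact_pairs(system)
    rng = np.random.default_rng(spec.seed)
    frames = [system.coords.copy()]
    for _ in range(1, spec.n_snapshots):
        for _attempt in range(500):
            disp = rng.normal(0.0, spec.jitter_sigma, size=system.coords.shape)
            disp[parent[:, 0]] = disp[parent[:, 1]]  # H inherits its heavy atom's move
            cand = system.coords + disp
            if close_pairs.size == 0:
                break
            d = np.linalg.norm(cand[close_pairs[:, 0]] - cand[close_pairs[:, 1]], axis=1)
            if np.all(d >= 0.95 * ref_dists):
                break
        else:
            raise FixtureError("could not draw a clash-free snapshot; jitter too large")
        frames.append(cand)
    return Ensemble(system, frames, [f"snapshot-{i}" for i in range(spec.n_snapshots)])


def _hydrogen_parents(system: MolecularSystem) -> np.ndarray:
    """(hydrogen index, bonded heavy-atom index) pairs within each residue."""
    pairs = []
    for res in system.residues():
        heavy = [i for i in res.indices if not system.atoms[i].is_hydrogen]
        for i in res.indices:
            if not system.atoms[i].is_hydrogen or not heavy:
                continue
            d = [float(np.linalg.norm(system.coords[i] - system.coords[j])) for j in heavy]
            pairs.append((i, heavy[int(np.argmin(d))]))
    if not pairs:
        return np.empty((0, 2), dtype=int)
    return np.asarray(pairs, dtype=int)


def _close_contact_pairs(
    system: MolecularSystem, cutoff: float = 4.0
) -> tuple[np.ndarray, np.ndarray]:
    """Cross-residue heavy-atom pairs in contact range in the reference frame."""
    heavy = system.heavy_indices()
    coords = system.coords[heavy]
    tree = cKDTree(coords)
    pairs = []
    for a, b in tree.query_pairs(cutoff):
        ai, bi = system.atoms[heavy[a]], system.atoms[heavy[b]]
        if ai.residue_key == bi.residue_key:
            continue
        if ai.residue_key[0] == bi.residue_key[0] and abs(ai.residue_key[1] - bi.residue_key[1]) <= 1:
            continue
        pairs.append((heavy[a], heavy[b]))
    if not pairs:
        return np.empty((0, 2), dtype=int), np.empty(0)
    arr = np.asarray(pairs, dtype=int)
    dists = np.linalg.norm(system.coords[arr[:, 0]] - system.coords[arr[:, 1]], axis=1)
    return arr, dists


def _check_clashes(system: MolecularSystem, cutoff: float = 1.5) -> None:
    heavy = system.heavy_indices()
    coords = system.coords[heavy]
    tree = cKDTree(coords)
    for a, b in tree.query_pairs(cutoff):
        ai, bi = system.atoms[heavy[a]], system.atoms[heavy[b]]
        if ai.residue_key == bi.residue_key:
            continue
        same_chain = ai.residue_key[0] == bi.residue_key[0]
        adjacent = same_chain and abs(ai.residue_key[1] - bi.residue_key[1]) == 1
        peptide_bond = adjacent and {ai.name, bi.name} in ({"C", "N"}, {"C", "CH3"}, {"N", "CH3"})
        if not peptide_bond:
            raise FixtureError(
                f"steric clash: {ai.name} {ai.residue_key} vs {bi.name} {bi.residue_key}"
            )


def planted_pair_indices(system: MolecularSystem, spec: FixtureSpec) -> dict[str, tuple[int, int]]:
    """Atom-index pairs realizing each planted interaction (for measurement)."""
    out = {}
    rec_slot_to_resnum = {slot: n for n, slot in enumerate(_receptor_slots(spec), start=1)}
    index = {(a.residue_key, a.name): i for i, a in enumerate(system.atoms)}
    for plant in spec.planted:
        _, _, lig_atom, rec_atom = PLANT_RULES[plant.kind]
        i = index[(("A", plant.ligand_slot + 1, ""), lig_atom)]
        j = index[(("B", rec_slot_to_resnum[plant.receptor_slot], ""), rec_atom)]
        out[plant.kind] = (i, j)
    return out


# ---------------------------------------------------------------------------
# small peptide builder (handy for unit tests and examples)
# ---------------------------------------------------------------------------


def build_peptide(
    sequence: list[str] | tuple[str, ...],
    chain: str = "A",
    side: str | None = None,
    capped: bool = False,
    ca_y: float = 0.0,
    mirror: bool = False,
) -> MolecularSystem:
    """A straight template peptide; ``capped`` blocks the termini with ACE/NME."""
    atoms: list[Atom] = []
    serial = 1
    if capped:
        cap = _cap_atoms("ACE", -CA_SPACING, ca_y, mirror, (chain, 0, ""), serial)
        atoms.extend(cap)
        serial += len(cap)
    for i, res in enumerate(sequence):
        res_atoms = _residue_atoms(
            res.upper(), i * CA_SPACING, ca_y, mirror, (chain, i + 1, ""), serial
        )
        atoms.extend(res_atoms)
        serial += len(res_atoms)
    if capped:
        cap = _cap_atoms(
            "NME", len(sequence) * CA_SPACING, ca_y, mirror, (chain, len(sequence) + 1, ""), serial
        )
        atoms.extend(cap)
        serial += len(cap)
    partition = {chain: side} if side else {}
    return MolecularSystem(atoms, partition, title="peptide " + "-".join(sequence))
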