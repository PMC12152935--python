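"""Interface contact detection, ensemble occupancies, and classification.

Two detectors act per frame across the ligand/receptor interface:

* **Hydrogen bonds** — a donor/hydrogen/acceptor triple is an H-bond when the
  donor···acceptor distance is at most 3.6 Å and the D–H···A angle (measured
  at the hydrogen) is at least 120°, i.e. 180 ± 60°.  Donor and acceptor
  typing comes from bundled per-residue tables; salt bridges are subsumed by
  charged H-bonds.
* **Nonpolar contacts** — pairs of apolar heavy atoms (carbon and sulfur by
  default) within 4.1 Å, grouped by residue pair with the pairwise atom–atom
  contact count.

Occupancy is the percentage of frames (within an explicit frame window) in
which a contact is present.  Classification follows two schemes: H-bonds are
*well-established* when the occupancy exceeds 70% in every ensemble, else
*presumable*; nonpolar residue-pair contacts are weak/medium/strong by the
mean of the per-ensemble occupancies (< 50 / 50–70 / ≥ 70 %).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from . import params
from .errors import VgscanError
from .structmodel import Ensemble, MolecularSystem, ResidueKey, neighbor_pairs

logger = logging.getLogger(__name__)

WELL_ESTABLISHED = "well_established"
PRESUMABLE = "presumable"


def round1(x: float) -> float:
    """Round to one decimal, half away from zero (as in printed tables)."""
    return math.copysign(math.floor(abs(x) * 10.0 + 0.5) / 10.0, x)


@dataclass
class ContactCriteria:
    """Geometric cutoffs for contact detection."""

    hbond_da_cutoff: float = 3.6  # donor-acceptor distance, Å
    hbond_angle_min: float = 120.0  # D-H···A angle at H, degrees (180 ± 60°)
    nonpolar_cutoff: float = 4.1  # heavy-atom distance, Å
    interface_only: bool = True
    #: elements counted as apolar; set to None to use all heavy atoms.
    apolar_elements: frozenset[str] | None = params.APOLAR_ELEMENTS

    def __post_init__(self) -> None:
        if self.hbond_da_cutoff <= 0 or self.nonpolar_cutoff <= 0:
            raise ValueError("cutoffs must be positive")
        if not 0 < self.hbond_angle_min <= 180:
            raise ValueError("angle_min must lie in (0, 180]")


@dataclass(frozen=True)
class HBondHit:
    """One detected H-bond triple in one frame (atom indices into the system)."""

    donor: int
    hydrogen: int
    acceptor: int
    donor_residue: ResidueKey
    acceptor_residue: ResidueKey
    distance: float
    angle: float


@dataclass(frozen=True)
class NonpolarHit:
    """One detected apolar heavy-atom pair in one frame."""

    atom_i: int
    atom_j: int
    residue_i: ResidueKey
    residue_j: ResidueKey
    distance: float


@dataclass
class ContactRecord:
    """A contact tracked over an ensemble with its occupancy."""

    kind: str  # "hbond" | "nonpolar"
    ligand_residue: ResidueKey
    receptor_residue: ResidueKey
    ligand_residue_name: str = ""
    receptor_residue_name: str = ""
    #: for hbond: (donor atom name, hydrogen name, acceptor atom name)
    atom_roles: tuple[str, ...] = ()
    ligand_is_backbone: bool | None = None
    receptor_is_backbone: bool | None = None
    per_frame_present: list[bool] = field(default_factory=list)
    occupancy: float = 0.0
    #: for nonpolar: atom-pair contact count in the reference frame window
    n_atom_pairs: int = 0

    @property
    def location_flag(self) -> str:
        """'b' / 's' flags in ligand//receptor order (e.g. ``b//s``)."""

        def flag(b: bool | None) -> str:
            return "?" if b is None else ("b" if b else "s")

        return f"{flag(self.ligand_is_backbone)}//{flag(self.receptor_is_backbone)}"


@dataclass
class ContactClassification:
    """Outcome of the two classification schemes."""

    hbond_class: str | None = None  # well_established | presumable
    nonpolar_class: str | None = None  # w | m | s
    average_occupancy: float | None = None


# ---------------------------------------------------------------------------
# typing helpers
# ---------------------------------------------------------------------------


def _donor_triples(system: MolecularSystem) -> list[tuple[int, int]]:
    """(donor heavy atom index, attached hydrogen index) pairs."""
    triples: list[tuple[int, int]] = []
    n_hydrogens = sum(1 for a in system.atoms if a.is_hydrogen)
    if n_hydrogens == 0:
        raise VgscanError(
            "system contains no hydrogens; H-bond detection needs explicit "
            "(at least polar) hydrogens — protonate the structure first"
        )
    for res in system.residues():
        names = {system.atoms[i].name: i for i in res.indices}
        donor_map: dict[str, tuple[str, ...]] = {}
        if res.name in params.STANDARD_AA or res.name == "NME":
            if res.name != "PRO":
                donor_map["N"] = params.BACKBONE_DONOR_H
        donor_map.update(params.SIDECHAIN_DONORS.get(res.name, {}))
        for heavy_name, h_names in donor_map.items():
            if heavy_name not in names:
                continue
            attached = [names[h] for h in h_names if h in names]
            if not attached:
                if heavy_name != "N":  # terminal/backbone variants are common
                    logger.warning(
                        "donor %s of %s %s lacks an attached hydrogen; skipped",
                        heavy_name, res.name, res.key,
                    )
                continue
            for h_idx in attached:
                triples.append((names[heavy_name], h_idx))
    return triples


def _acceptor_indices(system: MolecularSystem) -> list[int]:
    acceptors: list[int] = []
    for res in system.residues():
        names = {system.atoms[i].name: i for i in res.indices}
        wanted: list[str] = []
        if res.name in params.STANDARD_AA or res.name == "ACE":
            wanted.extend(params.BACKBONE_ACCEPTORS)
        for acc in params.SIDECHAIN_ACCEPTORS.get(res.name, ()):
            if res.name == "HIS":
                # tautomer from present hydrogens: a protonated ring N donates
                h_for = {"ND1": "HD1", "NE2": "HE2"}[acc]
                if h_for in names:
                    continue
            wanted.append(acc)
        acceptors.extend(names[w] for w in wanted if w in names)
    return acceptors


def _is_backbone(atom_name: str) -> bool:
    return atom_name in params.BACKBONE_ATOMS


# ---------------------------------------------------------------------------
# per-frame detectors
# ---------------------------------------------------------------------------


def _angle_at(h: np.ndarray, d: np.ndarray, a: np.ndarray) -> float:
    """D–H···A angle at the hydrogen, degrees."""
    v1 = d - h
    v2 = a - h
    cosang = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def detect_hbonds(
    system: MolecularSystem,
    criteria: ContactCriteria | None = None,
    coords: np.ndarray | None = None,
) -> list[HBondHit]:
    """Detect H-bond triples in one frame.

    With ``criteria.interface_only`` (default), only cross-interface triples
    (donor and acceptor on different sides of the chain partition) are
    reported; triples within one side are excluded.
    """
    criteria = criteria or ContactCriteria()
    coords = system.coords if coords is None else np.asarray(coords, dtype=float)
    donors = _donor_triples(system)
    acceptors = _acceptor_indices(system)
    if not donors or not acceptors:
        return []
    donor_heavy = [d for d, _ in donors]
    pairs = neighbor_pairs(coords, criteria.hbond_da_cutoff, donor_heavy, acceptors)
    by_donor: dict[int, list[int]] = {}
    for d, a in pairs:
        by_donor.setdefault(d, []).append(a)

    side = system.chain_partition
    hits: list[HBondHit] = []
    for d_idx, h_idx in donors:
        d_atom = system.atoms[d_idx]
        for a_idx in sorted(by_donor.get(d_idx, ())):
            a_atom = system.atoms[a_idx]
            if d_atom.residue_key == a_atom.residue_key:
                continue
            if criteria.interface_only:
                sd, sa = side.get(d_atom.chain_id), side.get(a_atom.chain_id)
                if sd is None or sa is None or sd == sa:
                    continue
            ang = _angle_at(coords[h_idx], coords[d_idx], coords[a_idx])
            if ang >= criteria.hbond_angle_min:
                hits.append(
                    HBondHit(
                        donor=d_idx,
                        hydrogen=h_idx,
                        acceptor=a_idx,
                        donor_residue=d_atom.residue_key,
                        acceptor_residue=a_atom.residue_key,
                        distance=float(np.linalg.norm(coords[d_idx] - coords[a_idx])),
                        angle=ang,
                    )
                )
    return hits


def detect_nonpolar(
    system: MolecularSystem,
    criteria: ContactCriteria | None = None,
    coords: np.ndarray | None = None,
) -> list[NonpolarHit]:
    """Detect cross-interface apolar heavy-atom pairs in one frame."""
    criteria = criteria or ContactCriteria()
    coords = system.coords if coords is None else np.asarray(coords, dtype=float)

    def apolar(i: int) -> bool:
        a = system.atoms[i]
        if a.is_hydrogen:
            return False
        if criteria.apolar_elements is None:
            return True
        return a.element in criteria.apolar_elements

    if criteria.interface_only:
        sel_l = [int(i) for i in system.side_indices("ligand") if apolar(int(i))]
        sel_r = [int(i) for i in system.side_indices("receptor") if apolar(int(i))]
    else:
        sel = [i for i in range(system.n_atoms) if apolar(i)]
        sel_l = sel_r = sel
    hits: list[NonpolarHit] = []
    seen: set[tuple[int, int]] = set()
    for i, j in neighbor_pairs(coords, criteria.nonpolar_cutoff, sel_l, sel_r):
        key = (min(i, j), max(i, j))
        if key in seen:
            continue
        seen.add(key)
        ai, aj = system.atoms[i], system.atoms[j]
        if ai.residue_key == aj.residue_key:
            continue
        hits.append(
            NonpolarHit(
                atom_i=i,
                atom_j=j,
                residue_i=ai.residue_key,
                residue_j=aj.residue_key,
                distance=float(np.linalg.norm(coords[i] - coords[j])),
            )
        )
    return hits


# ---------------------------------------------------------------------------
# occupancy over an ensemble
# ---------------------------------------------------------------------------


def occupancy(per_frame_present: Sequence[bool], frame_window: Sequence[int] | None = None) -> float:
    """Occupancy (%) of a contact over a frame window, to one decimal."""
    if frame_window is None:
        window = range(len(per_frame_present))
    else:
        window = list(frame_window)
        if any(w < 0 or w >= len(per_frame_present) for w in window):
            raise IndexError("frame window outside available frames")
    n = len(list(window))
    if n == 0:
        raise ValueError("empty frame window")
    present = sum(1 for w in window if per_frame_present[w])
    return round1(100.0 * present / n)


def hbond_contact_records(
    ensemble: Ensemble,
    criteria: ContactCriteria | None = None,
    frame_window: Sequence[int] | None = None,
) -> list[ContactRecord]:
    """Track H-bonds over an ensemble, one record per

    (donor residue, acceptor residue, backbone/side-chain role) combination —
    mirroring how interface H-bond tables are reported.  A contact is present
    in a frame when at least one matching triple satisfies the criteria.
    """
    criteria = criteria or ContactCriteria()
    topo = ensemble.topology
    window = list(frame_window) if frame_window is not None else list(range(ensemble.n_frames))
    if not window:
        raise ValueError("empty frame window")

    presence: dict[tuple, list[bool]] = {}
    meta: dict[tuple, tuple] = {}
    for wi, fi in enumerate(window):
        for hit in detect_hbonds(topo, criteria, coords=ensemble.frames[fi]):
            d_atom, a_atom = topo.atoms[hit.donor], topo.atoms[hit.acceptor]
            d_side = topo.side_of(d_atom.chain_id)
            if d_side == "ligand":
                lig_res, rec_res = hit.donor_residue, hit.acceptor_residue
                lig_bb, rec_bb = _is_backbone(d_atom.name), _is_backbone(a_atom.name)
                lig_name, rec_name = d_atom.residue_name, a_atom.residue_name
            else:
                lig_res, rec_res = hit.acceptor_residue, hit.donor_residue
                lig_bb, rec_bb = _is_backbone(a_atom.name), _is_backbone(d_atom.name)
                lig_name, rec_name = a_atom.residue_name, d_atom.residue_name
            key = (lig_res, rec_res, lig_bb, rec_bb)
            if key not in presence:
                presence[key] = [False] * len(window)
                meta[key] = (lig_name, rec_name, (d_atom.name, topo.atoms[hit.hydrogen].name, a_atom.name))
            presence[key][wi] = True

    records = []
    for key in sorted(presence, key=str):
        lig_res, rec_res, lig_bb, rec_bb = key
        lig_name, rec_name, roles = meta[key]
        pf = presence[key]
        records.append(
            ContactRecord(
                kind="hbond",
                ligand_residue=lig_res,
                receptor_residue=rec_res,
                ligand_residue_name=lig_name,
                receptor_residue_name=rec_name,
                atom_roles=roles,
                ligand_is_backbone=lig_bb,
                receptor_is_backbone=rec_bb,
                per_frame_present=pf,
                occupancy=occupancy(pf),
            )
        )
    return records


def nonpolar_contact_records(
    ensemble: Ensemble,
    criteria: ContactCriteria | None = None,
    frame_window: Sequence[int] | None = None,
) -> list[ContactRecord]:
    """Track nonpolar contacts over an ensemble, grouped by residue pair.

    The residue-pair occupancy is the mean over its atom pairs' occupancies
    (each atom pair contributes the fraction of window frames in which it is
    within the cutoff); the atom-pair count is the number of distinct atom
    pairs seen in the window.
    """
    criteria = criteria or ContactCriteria()
    topo = ensemble.topology
    window = list(frame_window) if frame_window is not None else list(range(ensemble.n_frames))
    if not window:
        raise ValueError("empty frame window")

    # per atom-pair presence
    pair_presence: dict[tuple, list[bool]] = {}
    pair_respair: dict[tuple, tuple] = {}
    for wi, fi in enumerate(window):
        for hit in detect_nonpolar(topo, criteria, coords=ensemble.frames[fi]):
            ai, aj = topo.atoms[hit.atom_i], topo.atoms[hit.atom_j]
            if topo.side_of(ai.chain_id) == "ligand":
                lig_atom, rec_atom = hit.atom_i, hit.atom_j
            else:
                lig_atom, rec_atom = hit.atom_j, hit.atom_i
            key = (lig_atom, rec_atom)
            if key not in pair_presence:
                pair_presence[key] = [False] * len(window)
                pair_respair[key] = (
                    topo.atoms[lig_atom].residue_key,
                    topo.atoms[rec_atom].residue_key,
                )
            pair_presence[key][wi] = True

    grouped: dict[tuple, list[tuple]] = {}
    for key, respair in pair_respair.items():
        grouped.setdefault(respair, []).append(key)

    records = []
    for respair in sorted(grouped, key=str):
        lig_res, rec_res = respair
        pairs = grouped[respair]
        occs = [100.0 * sum(pair_presence[p]) / len(window) for p in pairs]
        pf = [any(pair_presence[p][wi] for p in pairs) for wi in range(len(window))]
        records.append(
            ContactRecord(
                kind="nonpolar",
                ligand_residue=lig_res,
                receptor_residue=rec_res,
                ligand_residue_name=topo.residue(lig_res).name,
                receptor_residue_name=topo.residue(rec_res).name,
                per_frame_present=pf,
                occupancy=round1(float(np.mean(occs))),
                n_atom_pairs=len(pairs),
            )
        )
    return records


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def average_and_classify(per_ensemble_occupancies: Iterable[float]) -> ContactClassification:
    """Mean occupancy over ensembles (1 decimal) and its w/m/s class.

    weak: average < 50; medium: 50 <= average < 70; strong: average >= 70.
    """
    occs = [float(o) for o in per_ensemble_occupancies]
    if not occs:
        raise ValueError("need at least one occupancy value")
    avg = round1(sum(occs) / len(occs))
    if avg < 50.0:
        cls = "w"
    elif avg < 70.0:
        cls = "m"
    else:
        cls = "s"
    return ContactClassification(nonpolar_class=cls, average_occupancy=avg)


def classify_hbond(per_ensemble_occupancies: Iterable[float]) -> str:
    """``well_established`` iff the occupancy exceeds 70% in *every* ensemble."""
    occs = [float(o) for o in per_ensemble_occupancies]
    if not occs:
        raise ValueError("need at least one occupancy value")
    return WELL_ESTABLISHED if all(o > 70.0 for o in occs) else PRESUMABLE
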