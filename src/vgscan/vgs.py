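"""Virtual glycine scan: in-silico mutagenesis and hotspot classification.

Each scanned residue is mutated to glycine in 3D — the side chain beyond Cβ
is removed and Cβ is replaced by a hydrogen at 1.09 Å along the Cα→Cβ
vector — and the interaction free energy is recomputed on the *same*
geometry (no re-optimization; conformational relaxation upon mutation is a
documented limitation of the approach).  The per-residue contribution is

    ΔΔG_int = ΔG_int(Gly) − ΔG_int(wild type),

aggregated over an ensemble of snapshots.  A residue is a *hotspot* when
ΔΔG_int ≥ 2 kcal/mol in every considered snapshot, and is tiered by its
mean contribution: weak [2, 6), medium [6, 10), strong ≥ 10 kcal/mol.
Glycines and prolines are never scanned (no Cβ / backbone-constrained).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import params
from .energy import BackendContract, EnergyComponents, interaction_energy, split_complex
from .errors import MutationError
from .fragment import Fragment, retained_receptor_residues
from .structmodel import Atom, MolecularSystem, ResidueKey

logger = logging.getLogger(__name__)

TIER_NONE = "none"
TIER_WEAK = "weak"
TIER_MEDIUM = "medium"
TIER_STRONG = "strong"


@dataclass
class HotspotCriteria:
    """Hotspot gate and tier bounds (kcal/mol)."""

    min_ddG: float = 2.0
    require_all_snapshots: bool = True
    weak_low: float = 2.0
    medium_low: float = 6.0
    strong_low: float = 10.0
    interface_shell: float = 6.0  # Å, receptor residues considered

    def __post_init__(self) -> None:
        if not 0 < self.weak_low < self.medium_low < self.strong_low:
            raise ValueError("tier bounds must be increasing and positive")

    def tier(self, mean_ddG: float) -> str:
        """Tier from the mean ΔΔG_int (half-open boundaries)."""
        if mean_ddG >= self.strong_low:
            return TIER_STRONG
        if mean_ddG >= self.medium_low:
            return TIER_MEDIUM
        if mean_ddG >= self.weak_low:
            return TIER_WEAK
        return TIER_NONE


@dataclass
class VGSRecord:
    """Per-residue scan outcome across snapshots."""

    residue_key: ResidueKey
    residue_name: str
    side: str
    dG_wt: list[float] = field(default_factory=list)
    dG_gly: list[float] = field(default_factory=list)
    ddG_per_snapshot: list[float] = field(default_factory=list)
    mean: float = math.nan
    std_dev: float = math.nan
    tier: str = TIER_NONE
    is_hotspot: bool = False
    failed: bool = False
    failure_reason: str | None = None


@dataclass
class SiteContribution:
    """Summed hotspot contribution of one interface sub-site."""

    label: str
    summed_mean_ddG: float
    fraction_of_total: float


# ---------------------------------------------------------------------------
# mutation
# ---------------------------------------------------------------------------

_GLY_HEAVY = {"N", "CA", "C", "O"}


def _replace_side_chain_with_h(
    system: MolecularSystem,
    residue_key: ResidueKey,
    rename: str | None = "GLY",
    h_name: str = "HA2",
) -> MolecularSystem:
    """Remove side-chain atoms beyond CB and put H at 1.09 Å along Cα→Cβ."""
    res = system.residue(residue_key)
    names = {system.atoms[i].name: i for i in res.indices}
    if "CA" not in names or "CB" not in names:
        raise MutationError(f"residue {res.name} {residue_key} lacks CA/CB")
    ca = system.coords[names["CA"]]
    cb = system.coords[names["CB"]]
    unit = (cb - ca) / np.linalg.norm(cb - ca)
    h_coords = ca + 1.09 * unit

    keep_backbone = params.BACKBONE_ATOMS
    new_atoms: list[Atom] = []
    serial_h = system.max_serial() + 1
    for i, atom in enumerate(system.atoms):
        if atom.residue_key != residue_key:
            new_atoms.append(replace(atom, coords=atom.coords.copy()))
            continue
        if atom.name == "CB":
            new_atoms.append(
                Atom(
                    serial=serial_h,
                    name=h_name,
                    element="H",
                    coords=h_coords,
                    residue_key=residue_key,
                    residue_name=rename or atom.residue_name,
                )
            )
        elif atom.name in keep_backbone:
            new_atoms.append(
                replace(
                    atom,
                    coords=atom.coords.copy(),
                    residue_name=rename or atom.residue_name,
                )
            )
        # all other side-chain atoms are dropped
    return MolecularSystem(new_atoms, dict(system.chain_partition), system.title)


def mutate_to_glycine(system: MolecularSystem, residue_key: ResidueKey) -> MolecularSystem:
    """Mutate one residue to glycine in place (3D side-chain truncation).

    Backbone atoms and every other residue are bit-identical to the input;
    the mutated residue's heavy-atom composition equals the glycine
    template.  Glycine and proline targets are refused (nothing to remove /
    backbone ring), mirroring scan practice.
    """
    res = system.residue(residue_key)
    if res.name not in params.STANDARD_AA:
        raise MutationError(f"residue {res.name} {residue_key} is not a standard amino acid")
    if res.name in ("GLY", "PRO"):
        raise MutationError(f"{res.name} {residue_key} is skipped by the glycine scan")
    return _replace_side_chain_with_h(system, residue_key, rename="GLY")


# ---------------------------------------------------------------------------
# residue selection
# ---------------------------------------------------------------------------


def interface_residues(
    system: MolecularSystem, shell: float = 6.0
) -> dict[str, list[ResidueKey]]:
    """Scannable residues per side.

    Receptor: residues with any heavy atom within *shell* of any ligand
    heavy atom (all of them — the scan itself skips glycines/prolines).
    Ligand: all standard residues except glycines and prolines (the whole
    ligand is scanned).  Caps are never listed.
    """
    receptor = [res.key for res in retained_receptor_residues(system, shell)]
    ligand = [
        res.key
        for res in system.residues()
        if system.side_of(res.key[0]) == "ligand"
        and res.name in params.STANDARD_AA
        and res.name not in ("GLY", "PRO")
    ]
    return {"ligand": ligand, "receptor": receptor}


# ---------------------------------------------------------------------------
# the scan
# ---------------------------------------------------------------------------


def run_vgs(
    snapshots: list[MolecularSystem | Fragment],
    backend: BackendContract,
    residues: list[ResidueKey] | None = None,
    criteria: HotspotCriteria | None = None,
) -> list[VGSRecord]:
    """Scan residues over an ensemble of snapshots.

    The wild-type ΔG_int is evaluated once per snapshot; per mutant, the
    side untouched by the mutation is reused from the wild-type evaluation
    (numerically identical, one evaluation instead of three).  A backend
    failure for one mutant marks that record failed and the scan continues.
    """
    criteria = criteria or HotspotCriteria()
    systems = [s.system if isinstance(s, Fragment) else s for s in snapshots]
    if not systems:
        raise ValueError("need at least one snapshot")

    if residues is None:
        sel = interface_residues(systems[0], criteria.interface_shell)
        scannable = [
            key
            for key in sel["receptor"]
            if systems[0].residue(key).name not in ("GLY", "PRO")
        ]
        residues = sel["ligand"] + scannable

    # wild-type evaluations, cached per snapshot
    wt: list = []
    for sys_ in systems:
        wt.append(interaction_energy(sys_, backend))

    records: list[VGSRecord] = []
    for key in residues:
        res0 = systems[0].residue(key)
        side = systems[0].side_of(key[0]) or "?"
        rec = VGSRecord(residue_key=key, residue_name=res0.name, side=side)
        try:
            for si, sys_ in enumerate(systems):
                mutant = mutate_to_glycine(sys_, key)
                reuse: dict[str, EnergyComponents] = {}
                if side == "ligand":
                    reuse["receptor_components"] = wt[si].receptor_components
                elif side == "receptor":
                    reuse["ligand_components"] = wt[si].ligand_components
                ie = interaction_energy(mutant, backend, **reuse)
                rec.dG_wt.append(wt[si].dG_int)
                rec.dG_gly.append(ie.dG_int)
                rec.ddG_per_snapshot.append(ie.dG_int - wt[si].dG_int)
        except Exception as exc:
            rec.failed = True
            rec.failure_reason = str(exc)
            logger.warning("scan of %s %s failed: %s", rec.residue_name, key, exc)
            records.append(rec)
            continue
        ddg = np.asarray(rec.ddG_per_snapshot)
        rec.mean = float(ddg.mean())
        rec.std_dev = float(ddg.std(ddof=1)) if ddg.size > 1 else 0.0
        rec.tier = criteria.tier(rec.mean)
        if criteria.require_all_snapshots:
            rec.is_hotspot = bool(np.all(ddg >= criteria.min_ddG))
        else:
            rec.is_hotspot = rec.mean >= criteria.min_ddG
        records.append(rec)
    return records


def site_contributions(
    records: list[VGSRecord], grouping: dict[ResidueKey, str]
) -> list[SiteContribution]:
    """Per-site sums of hotspot mean ΔΔG_int and fractions of the total.

    Every hotspot residue must be assigned to exactly one group; fractions
    over the (disjoint, exhaustive) groups sum to 1.
    """
    sums: dict[str, float] = {}
    for rec in records:
        if not rec.is_hotspot:
            continue
        group = grouping.get(rec.residue_key)
        if group is None:
            raise ValueError(
                f"hotspot residue {rec.residue_name} {rec.residue_key} has no site assignment"
            )
        sums[group] = sums.get(group, 0.0) + rec.mean
    total = sum(sums.values())
    if total == 0.0:
        return [SiteContribution(g, s, 0.0) for g, s in sorted(sums.items())]
    return [SiteContribution(g, s, s / total) for g, s in sorted(sums.items())]
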