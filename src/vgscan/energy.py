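"""Energy backends and interaction Gibbs free energies.

The Gibbs free energy of a species is approximated as a gas-phase term plus
a solvation term, ΔG = ΔE + ΔΔG_solv, and the interaction free energy of a
two-sided complex as

    ΔG_int = ΔG_complex − (ΔG_ligand + ΔG_receptor),

with all three species evaluated on identical coordinates (no
re-optimization).  Both identities hold exactly in every report.

Two backends satisfy the same contract (``evaluate(system) ->
EnergyComponents``):

* :class:`ReferenceBackend` — a self-contained pairwise model: Coulomb plus
  Lennard-Jones in the gas phase, generalized-Born (Still equation) plus a
  SASA term for solvation.  Its role is protocol plumbing and ranking
  sanity, **not** force-field fidelity; absolute magnitudes are not
  comparable to semiempirical QM or production MM/GBSA energies.
* :class:`ExternalBackend` — an adapter that writes an input file, invokes an
  external engine through a command template, and parses the energy back;
  semiempirical QM or any other engine is reached only through this
  contract and never reimplemented here.
"""

from __future__ import annotations

import math
import re
import shlex
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol

import numpy as np

from . import params
from .errors import EngineError, EngineParseError, ParameterError
from .structmodel import MolecularSystem, system_sasa

KCAL_PER_HARTREE = 627.509474
KCAL_PER_KJ = 1.0 / 4.184


@dataclass
class EnergyComponents:
    """ΔE (gas phase), ΔΔG_solv and their exact sum ΔG."""

    E_gas: float
    G_solv: float

    @property
    def G_total(self) -> float:
        return self.E_gas + self.G_solv


@dataclass
class InteractionEnergy:
    """Species free energies and the interaction free energy ΔG_int."""

    complex_components: EnergyComponents
    ligand_components: EnergyComponents
    receptor_components: EnergyComponents

    @property
    def G_complex(self) -> float:
        return self.complex_components.G_total

    @property
    def G_ligand(self) -> float:
        return self.ligand_components.G_total

    @property
    def G_receptor(self) -> float:
        return self.receptor_components.G_total

    @property
    def dG_int(self) -> float:
        return self.G_complex - (self.G_ligand + self.G_receptor)


@dataclass
class BackendOptions:
    """Tunable constants of the reference backend (kcal/mol, Å, e)."""

    dielectric_solvent: float = 78.4
    coulomb_constant: float = params.COULOMB_CONSTANT
    gamma_sasa: float = 0.0072  # kcal/(mol·Å²); 0 disables the SASA term
    sasa_probe_radius: float = 1.4
    sasa_n_points: int = 240
    lj_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(params.LJ_PARAMS)
    )
    gb_radii: dict[str, float] = field(default_factory=lambda: dict(params.GB_RADII))
    hct_descreening: bool = True
    #: passthrough switch for engines that scale charged-group H-bonds; it has
    #: no effect on the reference backend itself.
    charge_hbond_scaling: bool = True

    def __post_init__(self) -> None:
        if self.dielectric_solvent <= 1:
            raise ValueError("solvent dielectric must exceed 1")


class BackendContract(Protocol):
    """What every energy backend provides."""

    name: str
    deterministic: bool

    def evaluate(self, system: MolecularSystem) -> EnergyComponents: ...


# ---------------------------------------------------------------------------
# partial charges
# ---------------------------------------------------------------------------


def assign_partial_charges(system: MolecularSystem) -> np.ndarray:
    """Coarse per-atom partial charges (e) from the bundled residue tables.

    Named polar-group atoms take template charges; whatever charge the
    template does not account for (free termini, missing or extra atoms) is
    redistributed evenly over the residue's untabulated atoms so that every
    residue sums exactly to its formal charge.
    """
    from .fragment import assign_formal_charges

    _, per_residue = assign_formal_charges(system)
    q = np.zeros(system.n_atoms)
    for res in system.residues():
        template: dict[str, float] = {}
        if res.name in params.STANDARD_AA:
            template.update(params.BACKBONE_CHARGES)
        template.update(params.SIDECHAIN_CHARGES.get(res.name, {}))
        untabulated = []
        assigned = 0.0
        for i in res.indices:
            name = system.atoms[i].name
            if name in template:
                q[i] = template[name]
                assigned += template[name]
            else:
                untabulated.append(i)
        residual = per_residue[res.key] - assigned
        if abs(residual) > 1e-12:
            targets = untabulated if untabulated else list(res.indices)
            for i in targets:
                q[i] += residual / len(targets)
    return q


# ---------------------------------------------------------------------------
# bonded exclusions
# ---------------------------------------------------------------------------

_BOND_CUTOFF_HEAVY = 1.9
_BOND_CUTOFF_H = 1.3
_BOND_CUTOFF_S = 2.4


def _residue_bond_exclusions(system: MolecularSystem) -> set[tuple[int, int]]:
    """Intra-residue atom pairs separated by fewer than 3 bonds (1-2, 1-3).

    Bonds are perceived from distances within each residue.  Pairs in
    different residues are always treated as nonbonded.
    """
    coords = system.coords
    excluded: set[tuple[int, int]] = set()
    for res in system.residues():
        idx = list(res.indices)
        n = len(idx)
        adj: dict[int, list[int]] = {i: [] for i in idx}
        for a in range(n):
            ia = idx[a]
            for b in range(a + 1, n):
                ib = idx[b]
                ai, bi = system.atoms[ia], system.atoms[ib]
                if ai.is_hydrogen and bi.is_hydrogen:
                    continue
                if ai.is_hydrogen or bi.is_hydrogen:
                    cutoff = _BOND_CUTOFF_H
                elif "S" in (ai.element, bi.element):
                    cutoff = _BOND_CUTOFF_S
                else:
                    cutoff = _BOND_CUTOFF_HEAVY
                if np.linalg.norm(coords[ia] - coords[ib]) <= cutoff:
                    adj[ia].append(ib)
                    adj[ib].append(ia)
        # path length <= 2 (1-2 and 1-3 pairs)
        for ia in idx:
            for ib in adj[ia]:
                excluded.add((min(ia, ib), max(ia, ib)))
                for ic in adj[ib]:
                    if ic != ia:
                        excluded.add((min(ia, ic), max(ia, ic)))
    return excluded


# ---------------------------------------------------------------------------
# reference backend
# ---------------------------------------------------------------------------


class ReferenceBackend:
    """Pairwise Coulomb + Lennard-Jones / generalized-Born + SASA backend.

    Gas phase:  E = Σ_{i<j} [ k q_i q_j / r_ij + 4 ε_ij ((σ_ij/r_ij)¹² −
    (σ_ij/r_ij)⁶) ] over nonbonded pairs (different residues, or the same
    residue at ≥ 3 bonds).  Solvation: the Still generalized-Born double sum

        G_GB = −(k/2)(1 − 1/ε_w) Σ_{i,j} q_i q_j / f_GB(r_ij, R_i, R_j),
        f_GB = sqrt(r² + R_i R_j exp(−r² / (4 R_i R_j))),

    whose i = j terms are the Born self-energies, plus γ·SASA.  Evaluation is
    deterministic (fixed summation order) and side-effect-free.
    """

    name = "reference-gb"
    deterministic = True

    def __init__(self, options: BackendOptions | None = None):
        self.options = options or BackendOptions()

    # -- parameter resolution ---------------------------------------------

    def _atom_params(self, system: MolecularSystem) -> tuple[np.ndarray, ...]:
        opt = self.options
        sigma = np.empty(system.n_atoms)
        eps = np.empty(system.n_atoms)
        born = np.empty(system.n_atoms)
        for i, atom in enumerate(system.atoms):
            try:
                sigma[i], eps[i] = opt.lj_params[atom.element]
                born[i] = opt.gb_radii[atom.element]
            except KeyError:
                raise ParameterError(
                    f"no nonbonded parameters for atom {atom.serial} {atom.name} "
                    f"({atom.residue_name} {atom.residue_key}, element {atom.element})"
                ) from None
        return sigma, eps, born

    _HCT_SCALE = 0.8

    def effective_born_radii(self, system: MolecularSystem) -> np.ndarray:
        """Effective Born radii: intrinsic, HCT-descreened by default.

        The Hawkins–Cramer–Truhlar pairwise integral grows an atom's radius
        with burial, which is what makes buried polar interactions less
        screened than surface ones; switching descreening off falls back to
        the bare intrinsic radii.
        """
        _, _, born = self._atom_params(system)
        if not self.options.hct_descreening or system.n_atoms < 2:
            return born
        coords = system.coords
        diff = coords[:, None, :] - coords[None, :, :]
        r = np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
        rho_i = born[:, None]
        rho_j = self._HCT_SCALE * born[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            L = np.maximum(np.abs(r - rho_j), rho_i)
            U = r + rho_j
            term = 0.5 * (
                1.0 / L
                - 1.0 / U
                + (r / 4.0) * (1.0 / U**2 - 1.0 / L**2)
                + (1.0 / (2.0 * r)) * np.log(L / U)
                + (rho_j**2 / (4.0 * r)) * (1.0 / L**2 - 1.0 / U**2)
            )
        np.fill_diagonal(term, 0.0)
        term[U <= rho_i] = 0.0  # neighbour fully inside the intrinsic sphere
        inv = np.maximum(1.0 / born - term.sum(axis=1), 1.0 / (10.0 * born))
        return 1.0 / inv

    # -- evaluation --------------------------------------------------------

    def evaluate(self, system: MolecularSystem) -> EnergyComponents:
        opt = self.options
        n = system.n_atoms
        coords = system.coords
        q = assign_partial_charges(system)
        sigma, eps, _ = self._atom_params(system)
        born = self.effective_born_radii(system)

        diff = coords[:, None, :] - coords[None, :, :]
        r2 = np.einsum("ijk,ijk->ij", diff, diff)
        r = np.sqrt(r2)

        iu, ju = np.triu_indices(n, k=1)
        include = np.ones(iu.shape[0], dtype=bool)
        for a, b in _residue_bond_exclusions(system):
            # closed-form flat index of (a, b), a < b, in the upper triangle
            include[a * n - a * (a + 1) // 2 + (b - a - 1)] = False

        rij = r[iu, ju][include]
        qq = (q[iu] * q[ju])[include]
        sij = 0.5 * (sigma[iu] + sigma[ju])[include]
        eij = np.sqrt(eps[iu] * eps[ju])[include]

        e_coul = float(np.sum(opt.coulomb_constant * qq / rij))
        sr6 = (sij / rij) ** 6
        e_lj = float(np.sum(4.0 * eij * (sr6**2 - sr6)))
        E_gas = e_coul + e_lj

        # GB double sum over all i, j (self terms on the diagonal)
        bb = born[:, None] * born[None, :]
        f_gb = np.sqrt(r2 + bb * np.exp(-r2 / (4.0 * bb)))
        pref = -(opt.coulomb_constant / 2.0) * (1.0 - 1.0 / opt.dielectric_solvent)
        G_gb = float(pref * np.sum((q[:, None] * q[None, :]) / f_gb))

        G_np = 0.0
        if opt.gamma_sasa > 0.0:
            metrics = system_sasa(
                system, probe_radius=opt.sasa_probe_radius, n_points=opt.sasa_n_points
            )
            G_np = opt.gamma_sasa * metrics.sasa_total

        return EnergyComponents(E_gas=E_gas, G_solv=G_gb + G_np)


# ---------------------------------------------------------------------------
# interaction energy
# ---------------------------------------------------------------------------


def split_complex(system: MolecularSystem) -> tuple[MolecularSystem, MolecularSystem]:
    """Ligand-side and receptor-side subsystems on identical coordinates."""
    lig = system.side_indices("ligand")
    rec = system.side_indices("receptor")
    if lig.size == 0 or rec.size == 0:
        raise ValueError("chain partition must define both a ligand and a receptor side")
    if lig.size + rec.size != system.n_atoms:
        unknown = sorted(
            {a.chain_id for a in system.atoms if system.side_of(a.chain_id) is None}
        )
        raise ValueError(f"chains {unknown} are not assigned to either side")
    return system.subset(lig, title="ligand"), system.subset(rec, title="receptor")


def interaction_energy(
    complex_system: MolecularSystem,
    backend: BackendContract,
    ligand_components: EnergyComponents | None = None,
    receptor_components: EnergyComponents | None = None,
) -> InteractionEnergy:
    """ΔG_int = ΔG_complex − (ΔG_ligand + ΔG_receptor) on one geometry.

    Precomputed side components may be passed to skip re-evaluating a side
    that is unchanged (used by the glycine scan); backend errors propagate
    with the species label attached.
    """
    ligand, receptor = split_complex(complex_system)
    species = [
        ("complex", complex_system, None),
        ("ligand", ligand, ligand_components),
        ("receptor", receptor, receptor_components),
    ]
    out: dict[str, EnergyComponents] = {}
    for label, sys_, pre in species:
        if pre is not None:
            out[label] = pre
            continue
        try:
            out[label] = backend.evaluate(sys_)
        except Exception as exc:
            raise EngineError(f"backend {backend.name!r} failed on {label}: {exc}") from exc
    return InteractionEnergy(out["complex"], out["ligand"], out["receptor"])


# ---------------------------------------------------------------------------
# external engine adapter
# ---------------------------------------------------------------------------


@dataclass
class ExternalEngineConfig:
    """Contract for reaching an external energy engine.

    ``command`` is a shell-style template with ``{input}`` and (optionally)
    ``{output}`` placeholders.  ``energy_pattern`` is a regular expression
    applied to the engine output with either a named group ``g_total`` or
    the pair ``e_gas``/``g_solv``; values are converted from ``units`` to
    kcal/mol.
    """

    command: str
    energy_pattern: str
    input_writer: str = "pdb"  # or "xyz"
    units: str = "kcal/mol"  # or "kj/mol", "hartree"
    name: str = "external"
    deterministic: bool = True
    timeout_s: float = 3600.0

    _UNIT_FACTORS = {"kcal/mol": 1.0, "kj/mol": KCAL_PER_KJ, "hartree": KCAL_PER_HARTREE}

    def unit_factor(self) -> float:
        try:
            return self._UNIT_FACTORS[self.units.lower()]
        except KeyError:
            raise ValueError(f"unknown energy units {self.units!r}") from None


class ExternalBackend:
    """Run an external engine per evaluation and parse its energy output."""

    def __init__(self, config: ExternalEngineConfig):
        self.config = config
        self.name = config.name
        self.deterministic = config.deterministic

    def evaluate(self, system: MolecularSystem) -> EnergyComponents:
        from .structmodel import write_pdb, write_xyz

        cfg = self.config
        with tempfile.TemporaryDirectory(prefix="vgscan-engine-") as tmp:
            tmpdir = Path(tmp)
            suffix = "pdb" if cfg.input_writer == "pdb" else "xyz"
            inp = tmpdir / f"species.{suffix}"
            outp = tmpdir / "engine.out"
            if cfg.input_writer == "pdb":
                write_pdb(system, inp)
            elif cfg.input_writer == "xyz":
                write_xyz(system, inp)
            else:
                raise ValueError(f"unknown input writer {cfg.input_writer!r}")
            cmd = [
                part.format(input=str(inp), output=str(outp))
                for part in shlex.split(cfg.command)
            ]
            try:
                proc = subprocess.run(
                    cmd, capture_output=True, text=True, timeout=cfg.timeout_s
                )
            except FileNotFoundError as exc:
                raise EngineError(f"engine executable not found: {cmd[0]}") from exc
            except subprocess.TimeoutExpired as exc:
                raise EngineError(f"engine timed out after {cfg.timeout_s}s") from exc
            if proc.returncode != 0:
                raise EngineError(
                    f"engine exited with status {proc.returncode}",
                    log=proc.stdout + proc.stderr,
                )
            text = outp.read_text() if outp.exists() else proc.stdout
            return self._parse(text)

    def _parse(self, text: str) -> EnergyComponents:
        cfg = self.config
        match = re.search(cfg.energy_pattern, text, flags=re.MULTILINE)
        if match is None:
            raise EngineParseError(
                f"pattern {cfg.energy_pattern!r} not found in engine output"
            )
        groups = match.groupdict()
        factor = cfg.unit_factor()
        if "g_total" in groups and groups["g_total"] is not None:
            return EnergyComponents(E_gas=float(groups["g_total"]) * factor, G_solv=0.0)
        if groups.get("e_gas") is not None and groups.get("g_solv") is not None:
            return EnergyComponents(
                E_gas=float(groups["e_gas"]) * factor,
                G_solv=float(groups["g_solv"]) * factor,
            )
        raise EngineParseError(
            "energy pattern must define group 'g_total' or groups 'e_gas' and 'g_solv'"
        )
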