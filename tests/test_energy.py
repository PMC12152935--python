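"""Reference backend physics, interaction-energy identities, engine adapter."""

import shutil
import sys

import numpy as np
import pytest

from conftest import make_atoms, two_sided_system
from vgscan.energy import (
    BackendOptions,
    EnergyComponents,
    ExternalBackend,
    ExternalEngineConfig,
    ReferenceBackend,
    assign_partial_charges,
    interaction_energy,
    split_complex,
)
from vgscan.errors import EngineError, EngineParseError, ParameterError
from vgscan.fixtures import build_peptide
from vgscan.params import COULOMB_CONSTANT
from vgscan.structmodel import MolecularSystem
from vgscan.vgs import mutate_to_glycine


def ion(element="O", resname="GLU"):
    """A bare single-atom species carrying the residue's net formal charge."""
    return MolecularSystem(make_atoms([("X", element, (0, 0, 0))], resname=resname))


class TestReferenceBackendClosedForms:
    def test_born_self_energy_single_ion(self):
        """G_solv of an isolated unit charge equals the Born expression to
        1e-9 relative (no SASA term)."""
        be = ReferenceBackend(BackendOptions(gamma_sasa=0.0))
        system = ion()  # q = -1 spread over the single atom
        out = be.evaluate(system)
        a = be.options.gb_radii["O"]
        exact = -(COULOMB_CONSTANT / 2.0) * (1.0 - 1.0 / 78.4) * 1.0 / a
        assert out.E_gas == 0.0
        assert out.G_solv == pytest.approx(exact, rel=1e-9)

    def test_lj_minimum_two_neutral_particles(self):
        sigma, eps = ReferenceBackend().options.lj_params["C"]
        r = 2.0 ** (1.0 / 6.0) * sigma
        # separate chains: each single-atom residue carries both termini -> net 0
        atoms = make_atoms([("X1", "C", (0, 0, 0))], resname="ALA") + make_atoms(
            [("X2", "C", (r, 0, 0))], chain="B", resname="ALA", serial_start=5
        )
        be = ReferenceBackend(BackendOptions(gamma_sasa=0.0))
        out = be.evaluate(MolecularSystem(atoms))
        assert out.E_gas == pytest.approx(-eps, rel=1e-12)

    def test_gas_energy_equals_naive_double_loop(self):
        """20 random atoms, one per residue (no bonded exclusions): the
        vectorised sum must match an independent direct-sum oracle to 1e-8."""
        rng = np.random.default_rng(11)
        elements = rng.choice(["C", "N", "O", "S", "H"], size=20)
        atoms = []
        for i, el in enumerate(elements):
            atoms.extend(
                make_atoms(
                    [(f"X{i}", el, tuple(rng.uniform(0, 12, 3)))],
                    resnum=i + 1,
                    resname="ALA",
                    serial_start=i + 1,
                )
            )
        system = MolecularSystem(atoms)
        opt = BackendOptions(gamma_sasa=0.0)
        be = ReferenceBackend(opt)
        q = assign_partial_charges(system)
        expected = 0.0
        for i in range(20):
            for j in range(i + 1, 20):
                r = float(np.linalg.norm(system.coords[i] - system.coords[j]))
                si, ei = opt.lj_params[system.atoms[i].element]
                sj, ej = opt.lj_params[system.atoms[j].element]
                sij, eij = 0.5 * (si + sj), (ei * ej) ** 0.5
                expected += COULOMB_CONSTANT * q[i] * q[j] / r
                expected += 4.0 * eij * ((sij / r) ** 12 - (sij / r) ** 6)
        assert be.evaluate(system).E_gas == pytest.approx(expected, abs=1e-8)

    def test_intra_residue_bonded_pairs_excluded(self):
        """A serine's 1-2/1-3 pairs contribute nothing to the gas term."""
        system = build_peptide(["SER"], capped=True)
        be = ReferenceBackend(BackendOptions(gamma_sasa=0.0))
        from vgscan.energy import _residue_bond_exclusions

        excl = _residue_bond_exclusions(system)
        name = {i: a.name for i, a in enumerate(system.atoms)}
        by_names = {(name[i], name[j]) for i, j in excl} | {(name[j], name[i]) for i, j in excl}
        assert ("OG", "HG") in by_names  # 1-2
        assert ("CB", "HG") in by_names  # 1-3
        assert ("N", "O") not in by_names  # 3 bonds apart: nonbonded

    def test_missing_parameters_name_the_atom(self):
        system = MolecularSystem(make_atoms([("FE", "Fe", (0, 0, 0))], resname="ALA"))
        with pytest.raises(ParameterError, match="FE"):
            ReferenceBackend().evaluate(system)


@pytest.fixture(scope="module")
def peptide():
    return build_peptide(["SER", "GLU", "LEU"], capped=True)


class TestReferenceBackendInvariances:
    def test_translation_invariance(self, peptide, fast_backend):
        ref = fast_backend.evaluate(peptide)
        moved = peptide.with_coords(peptide.coords + np.array([11.0, -3.0, 7.0]))
        out = fast_backend.evaluate(moved)
        assert out.E_gas == pytest.approx(ref.E_gas, abs=1e-8)
        assert out.G_solv == pytest.approx(ref.G_solv, abs=1e-8)

    def test_rotation_invariance(self, peptide, fast_backend):
        theta = 0.83
        R = np.array(
            [[np.cos(theta), -np.sin(theta), 0], [np.sin(theta), np.cos(theta), 0], [0, 0, 1]]
        )
        ref = fast_backend.evaluate(peptide)
        out = fast_backend.evaluate(peptide.with_coords(peptide.coords @ R.T))
        assert out.E_gas == pytest.approx(ref.E_gas, abs=1e-8)
        assert out.G_solv == pytest.approx(ref.G_solv, abs=1e-8)

    def test_deterministic_re_evaluation(self, peptide, backend):
        a = backend.evaluate(peptide)
        b = backend.evaluate(peptide)
        assert (a.E_gas, a.G_solv) == (b.E_gas, b.G_solv)

    def test_partial_charges_sum_to_formal_charge_per_residue(self, frame0):
        from vgscan.fragment import assign_formal_charges

        q = assign_partial_charges(frame0)
        _, per = assign_formal_charges(frame0)
        for res in frame0.residues():
            assert q[list(res.indices)].sum() == pytest.approx(per[res.key], abs=1e-9)


class TestInteractionEnergy:
    def test_identities_hold_exactly(self, frame0, backend):
        ie = interaction_energy(frame0, backend)
        assert ie.dG_int == ie.G_complex - (ie.G_ligand + ie.G_receptor)
        for comp in (ie.complex_components, ie.ligand_components, ie.receptor_components):
            assert comp.G_total == comp.E_gas + comp.G_solv

    def test_separated_neutral_species_noninteracting(self, backend):
        lig = build_peptide(["ALA", "ALA"], chain="A", side="ligand", capped=True)
        rec = build_peptide(["ALA", "ALA"], chain="B", side="receptor", capped=True)
        atoms = [a for a in lig.atoms]
        offset = max(a.serial for a in atoms)
        for a in rec.atoms:
            a.serial += offset
            a.coords = a.coords + np.array([0.0, 500.0, 0.0])
        system = MolecularSystem(atoms + rec.atoms, {"A": "ligand", "B": "receptor"})
        ie = interaction_energy(system, backend)
        assert abs(ie.dG_int) <= 1e-3

    def test_planted_complex_binds_favorably(self, frame0, backend):
        assert interaction_energy(frame0, backend).dG_int < 0

    def test_recomputing_from_components_is_exact(self, frame0, fast_backend):
        ie = interaction_energy(frame0, fast_backend)
        rebuilt = ie.complex_components.G_total - (
            ie.ligand_components.G_total + ie.receptor_components.G_total
        )
        assert rebuilt == ie.dG_int

    def test_precomputed_side_reuse_is_identical(self, frame0, fast_backend):
        full = interaction_energy(frame0, fast_backend)
        reused = interaction_energy(
            frame0, fast_backend, receptor_components=full.receptor_components
        )
        assert reused.dG_int == full.dG_int

    def test_unpartitioned_chain_rejected(self, frame0):
        system = MolecularSystem(
            [a for a in frame0.atoms], {"A": "ligand"}  # chain B unassigned
        )
        with pytest.raises(ValueError):
            split_complex(system)

    def test_backend_error_carries_species_label(self, frame0):
        class Broken:
            name = "broken"
            deterministic = True

            def evaluate(self, system):
                raise RuntimeError("boom")

        with pytest.raises(EngineError, match="complex"):
            interaction_energy(frame0, Broken())

    def test_pairwise_additivity_of_distant_mutations(self, frame0):
        """Under the pairwise backend (environment-independent radii), the
        effect of mutating two well-separated ligand residues is the sum of
        the single effects.  Many-body engines need not satisfy this."""
        be = ReferenceBackend(BackendOptions(gamma_sasa=0.0, hct_descreening=False))
        glu, met = ("A", 2, ""), ("A", 8, "")
        wt = interaction_energy(frame0, be).dG_int
        d_glu = interaction_energy(mutate_to_glycine(frame0, glu), be).dG_int - wt
        d_met = interaction_energy(mutate_to_glycine(frame0, met), be).dG_int - wt
        both = mutate_to_glycine(mutate_to_glycine(frame0, glu), met)
        d_both = interaction_energy(both, be).dG_int - wt
        assert d_both == pytest.approx(d_glu + d_met, abs=1e-6)


class TestExternalBackend:
    def test_mock_engine_loopback(self, frame0, tmp_path):
        """A stand-in engine echoing a fixed energy line parses correctly."""
        script = tmp_path / "engine.py"
        script.write_text(
            "import sys\n"
            "open(sys.argv[2], 'w').write('FINAL ENERGY = -12.50 kcal/mol\\n')\n"
        )
        cfg = ExternalEngineConfig(
            command=f"{sys.executable} {script} {{input}} {{output}}",
            energy_pattern=r"FINAL ENERGY =\s+(?P<g_total>-?\d+\.\d+)",
        )
        out = ExternalBackend(cfg).evaluate(frame0)
        assert out.G_total == pytest.approx(-12.50)

    def test_units_converted_to_kcal(self, frame0, tmp_path):
        script = tmp_path / "engine.py"
        script.write_text(
            "import sys\nopen(sys.argv[2], 'w').write('E = -1.000000 hartree\\n')\n"
        )
        cfg = ExternalEngineConfig(
            command=f"{sys.executable} {script} {{input}} {{output}}",
            energy_pattern=r"E = (?P<g_total>-?\d+\.\d+)",
            units="hartree",
        )
        out = ExternalBackend(cfg).evaluate(frame0)
        assert out.G_total == pytest.approx(-627.509474, rel=1e-9)

    def test_split_components_parsed(self, frame0, tmp_path):
        script = tmp_path / "engine.py"
        script.write_text(
            "import sys\nopen(sys.argv[2], 'w').write('GAS -10.0 SOLV -2.5\\n')\n"
        )
        cfg = ExternalEngineConfig(
            command=f"{sys.executable} {script} {{input}} {{output}}",
            energy_pattern=r"GAS (?P<e_gas>-?\d+\.\d+) SOLV (?P<g_solv>-?\d+\.\d+)",
        )
        out = ExternalBackend(cfg).evaluate(frame0)
        assert (out.E_gas, out.G_solv) == (-10.0, -2.5)

    def test_missing_executable_is_engine_error(self, frame0):
        cfg = ExternalEngineConfig(
            command="definitely-not-a-real-engine {input}",
            energy_pattern=r"(?P<g_total>-?\d+\.\d+)",
        )
        assert shutil.which("definitely-not-a-real-engine") is None
        with pytest.raises(EngineError):
            ExternalBackend(cfg).evaluate(frame0)

    def test_pattern_not_found_is_parse_error(self, frame0, tmp_path):
        script = tmp_path / "engine.py"
        script.write_text("import sys\nopen(sys.argv[2], 'w').write('no numbers here\\n')\n")
        cfg = ExternalEngineConfig(
            command=f"{sys.executable} {script} {{input}} {{output}}",
            energy_pattern=r"FINAL = (?P<g_total>-?\d+\.\d+)",
        )
        with pytest.raises(EngineParseError):
            ExternalBackend(cfg).evaluate(frame0)

    def test_engine_input_readable_by_pdb_parser(self, frame0, tmp_path):
        """The adapter's input writer emits a file read_pdb round-trips."""
        from vgscan.structmodel import read_pdb, write_pdb

        path = tmp_path / "species.pdb"
        ligand, _ = split_complex(frame0)
        write_pdb(ligand, path)
        back = read_pdb(path)
        assert back.n_atoms == ligand.n_atoms

    def test_nonzero_exit_is_engine_error_with_log(self, frame0, tmp_path):
        script = tmp_path / "engine.py"
        script.write_text("import sys\nprint('fatal: bad input'); sys.exit(3)\n")
        cfg = ExternalEngineConfig(
            command=f"{sys.executable} {script} {{input}} {{output}}",
            energy_pattern=r"(?P<g_total>-?\d+\.\d+)",
        )
        with pytest.raises(EngineError) as err:
            ExternalBackend(cfg).evaluate(frame0)
        assert "fatal: bad input" in err.value.log


def test_energy_components_total_is_exact_sum():
    comp = EnergyComponents(E_gas=-1.25, G_solv=0.75)
    assert comp.G_total == -0.5
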