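"""Glycine mutation, interface selection, scan aggregation, hotspot tiers."""

import numpy as np
import pytest

from vgscan.energy import BackendOptions, ReferenceBackend, assign_partial_charges, split_complex
from vgscan.errors import MutationError
from vgscan.fixtures import FixtureSpec, build_peptide, generate_fixture
from vgscan.fragment import assign_formal_charges
from vgscan.params import COULOMB_CONSTANT
from vgscan.structmodel import MolecularSystem
from vgscan.vgs import (
    HotspotCriteria,
    interface_residues,
    mutate_to_glycine,
    run_vgs,
    site_contributions,
)

GLY_HEAVY = {"N", "CA", "C", "O"}


class TestMutation:
    def test_ala_to_gly_minimal_case(self, frame0):
        key = ("A", 1, "")
        mutant = mutate_to_glycine(frame0, key)
        res = mutant.residue(key)
        assert res.name == "GLY"
        heavy = {mutant.atoms[i].name for i in res.indices if not mutant.atoms[i].is_hydrogen}
        assert heavy == GLY_HEAVY
        # every other atom bit-identical
        others_before = [a for a in frame0.atoms if a.residue_key != key]
        others_after = [a for a in mutant.atoms if a.residue_key != key]
        assert len(others_before) == len(others_after)
        for a, b in zip(others_before, others_after):
            assert a.name == b.name
            np.testing.assert_array_equal(a.coords, b.coords)

    def test_arg_to_gly_removes_seven_heavy_atoms_and_charge(self, frame0):
        key = ("B", 4, "")  # planted arginine
        before = frame0.residue(key)
        n_heavy_before = sum(1 for i in before.indices if not frame0.atoms[i].is_hydrogen)
        mutant = mutate_to_glycine(frame0, key)
        after = mutant.residue(key)
        n_heavy_after = sum(1 for i in after.indices if not mutant.atoms[i].is_hydrogen)
        assert n_heavy_before - n_heavy_after == 7
        assert assign_formal_charges(frame0)[1][key] == +1
        assert assign_formal_charges(mutant)[1][key] == 0

    def test_replacement_hydrogen_geometry(self, frame0):
        key = ("A", 2, "")
        res = frame0.residue(key)
        names = {frame0.atoms[i].name: i for i in res.indices}
        ca, cb = frame0.coords[names["CA"]], frame0.coords[names["CB"]]
        mutant = mutate_to_glycine(frame0, key)
        mres = mutant.residue(key)
        h = [i for i in mres.indices if mutant.atoms[i].name == "HA2"][0]
        vec = mutant.coords[h] - ca
        assert np.linalg.norm(vec) == pytest.approx(1.09, abs=1e-6)
        unit = (cb - ca) / np.linalg.norm(cb - ca)
        np.testing.assert_allclose(vec / 1.09, unit, atol=1e-9)

    @pytest.mark.parametrize("resname", ["GLY", "PRO"])
    def test_gly_and_pro_refused(self, resname, frame0):
        if resname == "GLY":
            key = ("B", 5, "")  # planted acceptor glycine
            with pytest.raises(MutationError, match="skipped"):
                mutate_to_glycine(frame0, key)
        else:
            system = build_peptide(["ALA"], capped=True)
            for atom in system.atoms:
                if atom.residue_key == ("A", 1, ""):
                    atom.residue_name = "PRO"
            system._invalidate()
            system.__dict__.pop("_residues", None)
            with pytest.raises(MutationError, match="skipped"):
                mutate_to_glycine(system, ("A", 1, ""))

    def test_missing_cb_is_error(self):
        system = build_peptide(["GLU"], capped=True)
        atoms = [a for a in system.atoms if a.name != "CB"]
        broken = MolecularSystem(atoms, dict(system.chain_partition))
        with pytest.raises(MutationError, match="CB"):
            mutate_to_glycine(broken, ("A", 1, ""))


class TestInterfaceResidues:
    def test_tiny_shell_on_separated_complex_is_empty(self, frame0):
        assert interface_residues(frame0, shell=0.1)["receptor"] == []

    def test_fixture_shell_matches_min_distance_oracle(self, frame0):
        shell = 6.0
        lig_heavy = [i for i in frame0.side_indices("ligand") if not frame0.atoms[i].is_hydrogen]
        expected = []
        for res in frame0.residues():
            if frame0.side_of(res.key[0]) != "receptor" or res.name in ("ACE", "NME"):
                continue
            heavy = [i for i in res.indices if not frame0.atoms[i].is_hydrogen]
            dmin = min(
                np.linalg.norm(frame0.coords[i] - frame0.coords[j])
                for i in heavy
                for j in lig_heavy
            )
            if dmin <= shell:
                expected.append(res.key)
        assert interface_residues(frame0, shell)["receptor"] == expected
        # the default fixture puts exactly the planted residues in the shell
        assert len(expected) == 5

    def test_ligand_list_excludes_gly_pro_and_caps(self):
        system = build_peptide(["ALA", "GLY", "SER"], side="ligand", capped=True)
        # need a receptor side for the partition to be valid downstream
        rec = build_peptide(["ALA"], chain="B", side="receptor", ca_y=30.0, mirror=True)
        atoms = system.atoms + [a for a in rec.atoms]
        for i, a in enumerate(atoms):
            a.serial = i + 1
        combined = MolecularSystem(atoms, {"A": "ligand", "B": "receptor"})
        ligand = interface_residues(combined)["ligand"]
        names = [combined.residue(k).name for k in ligand]
        assert names == ["ALA", "SER"]


class TestTiers:
    @pytest.mark.parametrize(
        "mean,tier",
        [
            (1.99, "none"),
            (2.0, "weak"),
            (5.999, "weak"),
            (6.0, "medium"),
            (9.999, "medium"),
            (10.0, "strong"),
            (25.0, "strong"),
        ],
    )
    def test_boundaries_half_open(self, mean, tier):
        assert HotspotCriteria().tier(mean) == tier

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            HotspotCriteria(weak_low=6.0, medium_low=2.0)


@pytest.fixture(scope="module")
def scan_records(default_ensemble, backend):
    snapshots = [default_ensemble.system_at(i) for i in range(4)]
    return run_vgs(snapshots, backend)


class TestScan:
    def test_per_snapshot_identity_exact(self, scan_records):
        for rec in scan_records:
            assert not rec.failed
            for wt, gly, dd in zip(rec.dG_wt, rec.dG_gly, rec.ddG_per_snapshot):
                assert dd == gly - wt

    def test_glycines_and_prolines_not_scanned(self, scan_records, frame0):
        scanned = {r.residue_key for r in scan_records}
        for res in frame0.residues():
            if res.name in ("GLY", "PRO", "ACE", "NME"):
                assert res.key not in scanned

    def test_hotspot_decision_invariant_to_snapshot_order(self, default_ensemble, backend):
        fwd = [default_ensemble.system_at(i) for i in (0, 1, 2)]
        rev = list(reversed(fwd))
        keys = [("A", 2, ""), ("A", 4, "")]
        a = run_vgs(fwd, backend, residues=keys)
        b = run_vgs(rev, backend, residues=keys)
        for ra, rb in zip(a, b):
            assert ra.is_hotspot == rb.is_hotspot
            assert ra.mean == pytest.approx(rb.mean, abs=1e-9)

    def test_far_residues_fall_off(self, default_ensemble, backend):
        """Receptor residues whose atoms all sit > 25 Å from the ligand
        contribute essentially nothing."""
        topo = default_ensemble.topology
        lig = topo.side_indices("ligand")
        far_keys = []
        for res in topo.residues():
            if topo.side_of(res.key[0]) != "receptor" or res.name in ("ACE", "NME", "GLY", "PRO"):
                continue
            dmin = min(
                float(np.linalg.norm(topo.coords[i] - topo.coords[j]))
                for i in res.indices
                for j in lig
            )
            if dmin > 25.0:
                far_keys.append(res.key)
        assert far_keys, "fixture should contain far receptor residues"
        snapshots = [default_ensemble.system_at(i) for i in range(3)]
        for rec in run_vgs(snapshots, backend, residues=far_keys[:2]):
            assert all(abs(d) <= 0.5 for d in rec.ddG_per_snapshot)
            assert rec.tier == "none"

    def test_failed_mutant_marks_record_and_continues(self, default_ensemble):
        class CountingBackend(ReferenceBackend):
            def __init__(self):
                super().__init__(BackendOptions(gamma_sasa=0.0))
                self.n = 0

            def evaluate(self, system):
                self.n += 1
                if self.n == 7:  # fail inside one mutant evaluation
                    raise RuntimeError("transient failure")
                return super().evaluate(system)

        snapshots = [default_ensemble.system_at(0)]
        keys = [("A", 2, ""), ("A", 4, ""), ("A", 6, "")]
        records = run_vgs(snapshots, CountingBackend(), residues=keys)
        assert sum(1 for r in records if r.failed) == 1
        assert sum(1 for r in records if not r.failed) == 2

    def test_planted_coulomb_recovery_against_pairwise_oracle(self, frame0):
        """With environment-independent radii and no surface term the scan's
        ΔΔG must recover an independently summed cross-interface pair energy
        for the mutated side chain (within 15%)."""
        be = ReferenceBackend(BackendOptions(gamma_sasa=0.0, hct_descreening=False))
        key = ("A", 2, "")  # planted glutamate
        wt_ie = be.evaluate(frame0)
        rec_idx = [int(i) for i in frame0.side_indices("receptor")]

        def cross_energy(system):
            q = assign_partial_charges(system)
            sigma, eps, born = be._atom_params(system)
            coords = system.coords
            lig_idx = [int(i) for i in system.side_indices("ligand")]
            rec = [int(i) for i in system.side_indices("receptor")]
            total = 0.0
            for i in lig_idx:
                for j in rec:
                    r = float(np.linalg.norm(coords[i] - coords[j]))
                    total += COULOMB_CONSTANT * q[i] * q[j] / r
                    sij = 0.5 * (sigma[i] + sigma[j])
                    eij = float(np.sqrt(eps[i] * eps[j]))
                    total += 4 * eij * ((sij / r) ** 12 - (sij / r) ** 6)
                    f = float(
                        np.sqrt(r * r + born[i] * born[j] * np.exp(-r * r / (4 * born[i] * born[j])))
                    )
                    total += -COULOMB_CONSTANT * (1 - 1 / 78.4) * q[i] * q[j] / f
            return total

        oracle = cross_energy(mutate_to_glycine(frame0, key)) - cross_energy(frame0)
        records = run_vgs([frame0], be, residues=[key])
        assert records[0].ddG_per_snapshot[0] == pytest.approx(oracle, rel=0.15)


class TestSiteContributions:
    def _record(self, key, mean, hotspot=True):
        from vgscan.vgs import VGSRecord

        rec = VGSRecord(residue_key=key, residue_name="ALA", side="ligand")
        rec.mean = mean
        rec.is_hotspot = hotspot
        return rec

    def test_single_group_fraction_one(self):
        recs = [self._record(("A", 1, ""), 4.0)]
        out = site_contributions(recs, {("A", 1, ""): "site-1a"})
        assert out[0].fraction_of_total == 1.0

    def test_three_to_one_split(self):
        recs = [self._record(("A", 1, ""), 3.0), self._record(("A", 2, ""), 1.0)]
        out = site_contributions(recs, {("A", 1, ""): "1a", ("A", 2, ""): "1b"})
        by = {c.label: c.fraction_of_total for c in out}
        assert by == {"1a": 0.75, "1b": 0.25}

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(2)
        recs = [self._record(("A", i, ""), float(v)) for i, v in enumerate(rng.uniform(1, 9, 6))]
        grouping = {("A", i, ""): f"g{i % 3}" for i in range(6)}
        out = site_contributions(recs, grouping)
        assert sum(c.fraction_of_total for c in out) == pytest.approx(1.0, abs=1e-12)

    def test_unassigned_hotspot_is_error(self):
        recs = [self._record(("A", 1, ""), 4.0)]
        with pytest.raises(ValueError, match="site assignment"):
            site_contributions(recs, {})

    def test_non_hotspots_ignored(self):
        recs = [self._record(("A", 1, ""), 4.0), self._record(("A", 2, ""), 9.0, hotspot=False)]
        out = site_contributions(recs, {("A", 1, ""): "1a"})
        assert len(out) == 1 and out[0].summed_mean_ddG == 4.0
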