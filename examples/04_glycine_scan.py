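"""Virtual glycine scan: per-residue contributions and hotspot tiers.

Every scannable residue is mutated to glycine in 3D (side chain beyond Cβ
replaced by H at 1.09 Å) and ΔΔG_int = ΔG_int(Gly) − ΔG_int(wt) is
aggregated over the snapshot ensemble.  Hotspots must contribute at least
2 kcal/mol in every snapshot.
"""

from vgscan import FixtureSpec, ReferenceBackend, generate_fixture, run_vgs

ensemble = generate_fixture(FixtureSpec())  # 10 seeded snapshots
records = run_vgs(list(ensemble), ReferenceBackend())

print("residue        side      mean ΔΔG (std)   tier     hotspot")
for rec in sorted(records, key=lambda r: -r.mean):
    print(f"{rec.residue_name}{rec.residue_key[1]:<4}      {rec.side:9s}"
          f"{rec.mean:7.2f} ({rec.std_dev:4.2f})   {rec.tier:8s} {rec.is_hotspot}")

# The planted salt bridge (Glu/Arg) and the H-bonding serine clear the
# 2 kcal/mol gate in all snapshots; single hydrophobic contacts sit below
# it, and residues far from the interface contribute essentially nothing.
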