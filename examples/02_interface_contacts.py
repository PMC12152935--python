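"""Detect interface contacts over an ensemble and classify occupancies.

Two detectors run per frame: hydrogen bonds (donor-acceptor <= 3.6 Å,
D-H···A angle >= 120°) and nonpolar contacts (apolar heavy atoms within
4.1 Å).  Occupancy is the percentage of frames a contact persists; the
bundled insulin-IR dataset shows the two classification schemes on real
occupancy columns.
"""

from vgscan import (
    FixtureSpec,
    average_and_classify,
    classify_hbond,
    generate_fixture,
    hbond_contact_records,
    nonpolar_contact_records,
)
from vgscan import refdata

ensemble = generate_fixture(FixtureSpec(n_snapshots=50))

print("H-bonds over 50 snapshots:")
for rec in hbond_contact_records(ensemble):
    print(f"  {rec.ligand_residue_name}{rec.ligand_residue[1]:>2} ... "
          f"{rec.receptor_residue_name}{rec.receptor_residue[1]:>2}  "
          f"{rec.location_flag}  occupancy {rec.occupancy:5.1f}%")

print("nonpolar residue pairs:")
for rec in nonpolar_contact_records(ensemble):
    print(f"  {rec.ligand_residue_name}{rec.ligand_residue[1]:>2} ... "
          f"{rec.receptor_residue_name}{rec.receptor_residue[1]:>2}  "
          f"{rec.n_atom_pairs} atom pair(s), occupancy {rec.occupancy:5.1f}%")

# classification on the bundled insulin-IR occupancy dataset
row = refdata.load_nonpolar_occupancies().iloc[0]
cls = average_and_classify([row.traj1, row.traj2, row.traj3])
print(f"\n{row.insulin_residue} / {row.ir_residue}: per-trajectory "
      f"({row.traj1}, {row.traj2}, {row.traj3})% -> average "
      f"{cls.average_occupancy}% class '{cls.nonpolar_class}'")
hb = refdata.load_hbond_occupancies().iloc[0]
print(f"{hb.insulin_residue} / {hb.ir_residue}: "
      f"({hb.traj1}, {hb.traj2}, {hb.traj3})% -> {classify_hbond([hb.traj1, hb.traj2, hb.traj3])}")
# 'well_established' requires > 70% occupancy in every trajectory;
# nonpolar classes w/m/s split at 50% and 70% of the trajectory average.
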