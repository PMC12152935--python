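# vgscan

Per-residue interaction analysis of flexible protein–protein interfaces:
contact occupancies over conformational ensembles, QM-cluster fragmentation
with chemical capping, interaction Gibbs free energies through pluggable
energy backends, and a virtual glycine scan with hotspot classification.

## The problem

Large hormone–receptor interfaces (the insulin–insulin receptor complex is
the archetype) are flexible: a single static structure misrepresents which
contacts actually hold the complex together, and experimental mutagenesis
cannot be run residue-by-residue at scale. A practical computational answer
is hierarchical: sample conformations, measure which noncovalent contacts
persist, cut the receptor down to a tractable capped model around the
ligand, and then ask — residue by residue — how much each side chain
contributes to binding.

`vgscan` is a library (plus a thin CLI) for that protocol, aimed at
structural bioinformaticians and molecular modellers who want the
bookkeeping — ensembles, occupancies, truncation, capping, charges,
mutation, aggregation — done correctly and reproducibly, with the energy
function swappable.

## The model

For a two-sided complex evaluated on one set of coordinates,

```
ΔG_int = ΔG_complex − (ΔG_ligand + ΔG_receptor),      ΔG = ΔE + ΔΔG_solv
```

where ΔE is a gas-phase term and ΔΔG_solv an implicit-solvation term. The
bundled reference backend computes ΔE as Coulomb + Lennard-Jones over
nonbonded pairs and ΔΔG_solv with the Still generalized-Born equation
(HCT-descreened effective radii) plus a γ·SASA surface term. External
engines (semiempirical QM, production MM/GBSA, anything scriptable) plug in
through an adapter that writes an input file, runs a command template and
regex-parses the energy.

The virtual glycine scan mutates each scannable residue to glycine in 3D —
side chain beyond Cβ removed, Cβ replaced by H at 1.09 Å along Cα→Cβ, no
re-optimization — and records

```
ΔΔG_int = ΔG_int(Gly) − ΔG_int(wild type)
```

per snapshot. A residue is a *hotspot* when ΔΔG_int ≥ 2 kcal/mol in every
snapshot; tiers by the mean: weak [2, 6), medium [6, 10), strong ≥ 10
kcal/mol. Interface H-bonds are *well-established* when their occupancy
exceeds 70% in every ensemble; nonpolar residue pairs are weak/medium/strong
by the trajectory-average occupancy (< 50 / 50–70 / ≥ 70%).

## Worked example

The package ships a deterministic synthetic complex — two idealized peptide
strands with a planted salt bridge (2.8 Å), a neutral H-bond dyad (2.9 Å),
a hydrophobic contact (3.8 Å) and an S···O chalcogen contact (3.3 Å), plus
seeded jittered snapshots standing in for MD frames:

```python
from vgscan import FixtureSpec, ReferenceBackend, generate_fixture, run_vgs

ensemble = generate_fixture(FixtureSpec())   # 230 atoms, 10 snapshots
records = run_vgs(list(ensemble), ReferenceBackend())
for rec in sorted(records, key=lambda r: -r.mean)[:5]:
    print(rec.residue_name, rec.residue_key, round(rec.mean, 2),
          round(rec.std_dev, 2), rec.tier, rec.is_hotspot)
```

prints

```
ARG ('B', 4, '') 11.21 2.14 strong True
GLU ('A', 2, '') 6.98 2.02 medium True
SER ('A', 4, '') 3.8 0.48 weak True
LEU ('A', 6, '') 1.15 0.11 none False
PHE ('B', 7, '') 1.09 0.09 none False
```

Reading: removing the arginine side chain destabilizes binding by ~11
kcal/mol on average across the 10 snapshots (a strong hotspot — it loses a
salt bridge), the glutamate is its counter-ion, the serine's reciprocal
H-bond dyad clears the 2 kcal/mol hotspot gate in every snapshot, and a
single hydrophobic contact sits honestly below it. The `examples/`
directory walks through each capability the same way (fixture construction,
contact occupancies, fragmentation/convergence, the scan, and the external
engine adapter); `vgscan run` drives the whole pipeline from a YAML config.

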