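# Methods

`vgscan` implements a hierarchical protocol for quantifying per-residue
contributions at flexible protein–protein interfaces. Given an ordered
ensemble of conformations of a two-sided complex (a hormone-like *ligand*
bound to a *receptor*), it

1. detects interface contacts per frame and aggregates their occupancies,
2. truncates the receptor around the ligand into a chemically capped
   fragment (QM-cluster construction) and checks convergence of the
   interaction free energy with fragment radius,
3. selects snapshots by interaction free energy, and
4. runs a virtual glycine scan (VGS) that mutates one residue at a time to
   glycine and records the change in interaction free energy, classifying
   robust contributors as hotspots.

This note records the models, the parameters that matter, the synthetic
data generator's assumptions, and the numerical choices — in the order the
pipeline runs them.

## Contact analysis

A hydrogen bond is a donor/hydrogen/acceptor triple with donor–acceptor
distance ≤ 3.6 Å and a D–H···A angle at the hydrogen of ≥ 120° (i.e.
180 ± 60°). Donor/acceptor typing comes from bundled per-residue tables
(backbone amide N–H donates, backbone carbonyl O accepts; hydroxyl, amide,
thiol, ammonium, guanidinium and imidazole groups per side chain; carboxylates
accept only; histidine tautomers are read from the hydrogens present).
Explicit — at least polar — hydrogens are required; a system without any
hydrogens is rejected with a pointer to protonate first. Salt bridges are
detected as charged hydrogen bonds, not as a separate category.

A nonpolar contact is a pair of apolar heavy atoms within 4.1 Å across the
interface. "Apolar" defaults to carbon and sulfur, which keeps carbonyl and
carboxylate oxygens from double-counting hydrogen-bond partners; a
configuration switch widens it to all heavy atoms for the literal
non-hydrogen reading.

Occupancy is the percentage of frames of an explicit frame window in which
a contact is present, reported to one decimal using round-half-away-from-zero
(matching how such tables are conventionally printed). Frame windows are
plain frame-index lists; no time units are assumed. For nonpolar contacts the
residue-pair occupancy is the mean of its atom pairs' occupancies, and the
atom-pair count is reported alongside — this is an interpretation choice,
flagged here, since the arithmetic mean of per-trajectory values reproduces
conventionally printed averages.

Two classification schemes operate on per-ensemble occupancies:

* H-bonds are **well-established** when the occupancy exceeds 70% in *every*
  ensemble (strict inequality), else **presumable**.
* Nonpolar residue pairs are **weak** (mean < 50%), **medium** (50–70%) or
  **strong** (≥ 70%), with the class applied to the rounded mean.

The package bundles a reference dataset of insulin–insulin-receptor
interface contact occupancies over three short MD trajectories
(`vgscan.refdata`); re-running the classifiers on its occupancy columns
reproduces every recorded average and class letter, which the test suite
asserts.

## Fragmentation and capping

Truncation retains every receptor residue with at least one heavy atom
within the radius of any ligand heavy atom (whole-residue granularity; a
Cα-distance variant is configurable). Consecutive retained residues keep
their peptide bond. Each severed bond is capped: acetyl (ACE) on an exposed
N-terminus, N-methylamide (NME) on an exposed C-terminus. Cap atoms inherit
the removed neighbour's backbone coordinates (C/O/CA → ACE's C/O/CH3,
N/H/CA → NME's N/H/CH3), which by construction lies exactly along the
removed carbonyl/amide direction and cannot clash; a 1.0 Å proximity check
is retained defensively. Whole-residue retention means the default protocol
never prunes side chains; an explicit hydrogen-capping helper
(`hydrogen_cap_side_chain`) covers configurations that do, replacing Cβ by
H at 1.09 Å along the cut bond.

Formal charges follow the pH-7 convention: Asp/Glu −1, Lys/Arg +1, His
neutral unless both ring nitrogens carry hydrogens, free N/C termini ±1,
capped termini and cap residues 0, cysteines neutral (disulfides detected at
Sγ–Sγ ≤ 2.3 Å). A fragment's total charge is the sum of its residues'
charges, and capping guarantees truncation never invents charge.

The convergence scan repeats truncation over a radius ladder (3–23 Å in
1 Å steps by default), computes ΔG_int at each radius and reports the
*retention* ΔG_int(r)/ΔG_int(r_max); a selector returns the smallest radius
whose retention meets a user threshold. Backend failures at individual radii
leave failure markers rather than aborting the profile.

`extract_dimer` excises two residues (same or different sides) as blocked
amino acids — original coordinates, ACE/NME caps inherited from their chain
neighbours — for export (PDB/XYZ) to external quantum-chemistry codes.

## Energies

The free energy of a species is ΔG = ΔE + ΔΔG_solv, and the interaction
free energy of a complex is

    ΔG_int = ΔG_complex − (ΔG_ligand + ΔG_receptor),

all three species evaluated on identical coordinates (no re-optimization).
Both identities hold exactly, by construction, in every report.

Two backends satisfy one contract (`evaluate(system) → EnergyComponents`):

**Reference backend** — a self-contained pairwise model:

* Gas phase: Coulomb (k = 332.0637 kcal·Å/(mol·e²)) plus Lennard-Jones
  (Lorentz–Berthelot combining, per-element σ/ε) over nonbonded pairs —
  atoms in different residues, or the same residue at ≥ 3 bonds (bonds
  perceived from distances within each residue). Note that pairs in
  *different* residues are always summed, including peptide-bonded
  neighbours; those large terms are identical in the complex and its
  isolated sides and cancel exactly in ΔG_int, but per-species totals are
  dominated by them and are not meaningful in isolation.
* Solvation: the Still generalized-Born double sum with
  f_GB = √(r² + R_iR_j·exp(−r²/4R_iR_j)), the i=j terms giving Born
  self-energies, a solvent dielectric of 78.4, plus a nonpolar surface term
  γ·SASA with γ = 0.0072 kcal/(mol·Å²).
* Effective Born radii: intrinsic per-element radii descreened with the
  Hawkins–Cramer–Truhlar pairwise integral (uniform screening factor 0.8),
  **on by default**. Bare intrinsic radii over-screen buried polar pairs and
  make hydrogen bonds nearly free; descreening makes buried interactions
  respond to their environment, which is the behaviour the scan relies on.
  The flag `hct_descreening=False` restores the cruder intrinsic-radius
  model (and with it, strict pairwise additivity — useful for oracle tests).
* Partial charges: a coarse fixed table for the polar groups of the twenty
  amino acids and the ACE/NME caps, in a polar-hydrogen representation.
  Whatever charge the template does not account for is spread evenly over
  the residue's untabulated atoms, so every residue sums *exactly* to its
  formal charge regardless of composition (mutants, caps, termini).
* No cutoffs; deterministic summation order; evaluation is side-effect-free.

The backend's role is protocol plumbing and ranking sanity, **not**
force-field fidelity. It is calibrated only in the sense that canonical
interface motifs behave physically: a formed salt bridge contributes several
kcal/mol net of screening, a neutral H-bond ~2–4, a single hydrophobic
contact ~1.

**External backend** — an adapter that writes a PDB or XYZ input, runs a
command template (`{input}`/`{output}` placeholders), and parses the energy
back through a configurable regular expression (either a combined `g_total`
group or `e_gas`/`g_solv`), with unit conversion from kcal/mol, kJ/mol or
hartree. Engine failures carry the captured log; a missing executable or an
unmatched pattern raise typed errors so a pipeline can skip a snapshot and
continue. Semiempirical QM engines and continuum-solvation models are
reached *only* through this contract; nothing of their internals is
reimplemented. The `charge_hbond_scaling` option is a passthrough switch
recorded for engines that scale charged-group H-bonds; it has no effect on
the reference backend.

Protocol variants are labelled with the standard single-point//geometry
notation (SQM//SQM, SQM//MM, SQM//MD, MM//MM, MM//MD), where the geometry
id records provenance (raw ensemble frames vs externally optimized ones);
the package consumes geometries and records which, it does not optimize.

## Virtual glycine scan

Each scanned residue is mutated in place: side-chain atoms beyond Cβ are
removed and Cβ is replaced by a hydrogen at 1.09 Å along the Cα→Cβ unit
vector; the residue is renamed GLY and its heavy-atom composition then
equals the glycine template. Backbone atoms and all other residues are
bit-identical to the input, and no re-optimization follows the mutation —
conformational relaxation upon mutation is deliberately neglected (a stated
limitation of the approach, shared with its uses in the literature).
Glycines and prolines are never scanned. Scanned residues default to the
whole ligand (minus Gly/Pro) plus receptor residues with any heavy atom
within 6 Å of the ligand.

Per residue and snapshot, ΔΔG_int = ΔG_int(Gly) − ΔG_int(wild type). The
wild-type evaluation is cached once per snapshot, and the side untouched by
a mutation is reused from it — numerically identical, three times cheaper.
Aggregation over snapshots reports the mean and the sample (n−1) standard
deviation. A residue is a **hotspot** when ΔΔG_int ≥ 2 kcal/mol in *every*
snapshot (configurable to a pooled-mean gate); tiers use the mean with
half-open bounds: weak [2, 6), medium [6, 10), strong ≥ 10 kcal/mol. The
2 kcal/mol floor guards against false positives from the intrinsic accuracy
limits of the energy models. Site contributions sum hotspot means over
user-defined disjoint groups and report each group's fraction of the total.

## The synthetic complex generator

`generate_fixture` builds the study system the tests and the acceptance
script run on: a ligand strand facing a receptor strand, with one planted
contact of each class —

| kind | motif | pair atoms | target |
|---|---|---|---|
| salt bridge | Glu⁻ carboxylate / Arg⁺ guanidinium | OE1···NH1 | 2.8 Å |
| neutral H-bond | Ser hydroxyl → backbone C=O | OG···O | 2.9 Å |
| reciprocal H-bond | backbone N–H → Ser hydroxyl | N···OG | 2.9 Å |
| hydrophobic | Leu isopropyl / Phe ring | CD1···CZ | 3.8 Å |
| chalcogen | Met sulfur / backbone C=O | SD···O | 3.3 Å |

Geometry is idealized: extended strands on a 3.8 Å Cα grid with a correct
trans-peptide backbone template (C–N 1.33 Å, O_i···N_{i+1} 2.24 Å), rigid
side-chain templates, and polar hydrogens only. Receptor residues facing a
planted partner are displaced toward the interface as isolated loop-like
residues (their flanking filler positions are left empty, the way flexible
loops go unresolved in real interface structures) and rotated so each
planted contact is collinear with its contact axis; every planted distance
is realized exactly in frame 0. The serine engages a reciprocal hydroxyl
dyad — donating to a carbonyl while accepting a backbone amide H — as
hydroxyls commonly do at interfaces; a single fully exposed neutral H-bond
sits right at the 2 kcal/mol hotspot floor under the reference backend, and
the dyad is the physically ordinary way such residues clear it. Chain
termini are ACE/NME-blocked so no artificial terminal charges enter the
energetics. The far receptor stretch extends > 25 Å from the ligand to
provide genuinely non-interacting scan targets.

Snapshots emulate local thermal motion: seeded Gaussian jitter of
`jitter_sigma` (default 0.15 Å) per heavy-atom coordinate, with two
constraints real trajectories obey — hydrogens ride their parent heavy atom
(X–H bonds are effectively rigid under constraint dynamics; independent
hydrogen jitter would unphysically swing dipole orientations), and a
candidate frame is redrawn if any close cross-residue heavy-atom contact
(< 4 Å in frame 0) compresses below 95% of its reference distance, because
Boltzmann-weighted sampling does not dive into the r⁻¹² wall. Frame 0 is
the unjittered reference. All randomness derives from the single `seed`.

What the generator does **not** emulate: real backbone dihedral statistics,
side-chain rotamer exchange, correlated loop motions, solvent structure,
and conformational change upon binding or mutation. Tests passing on this
fixture therefore demonstrate that the *protocol machinery* — detection,
bookkeeping, capping, energy plumbing, aggregation, classification — is
correct and deterministic, not that the reference backend predicts real
binding thermodynamics.

## Numerical choices

* Coordinates in Å, energies in kcal/mol, charges in e, 0-based atom
  indices internally, residue numbers as authored (1-based PDB).
* Altloc variants collapse to the highest occupancy, ties by letter order.
* Solvent/ion records (HOH, WAT, NA, CL, …) are dropped on read with a
  logged count; all analyses act on the solute.
* SASA is Shrake–Rupley with a golden-spiral point lattice (default 960
  points for the standalone operation, 240 inside the energy backend),
  probe 1.4 Å, per-element van der Waals radii (C 1.70, N 1.55, O 1.52,
  S 1.80, H 1.20 Å). Per-atom areas sum to the total exactly.
* Superposition RMSD is Kabsch (SVD) with reflection guarded; weighted
  variant available.
* Rounding of occupancies: half away from zero at one decimal;
  classification applies to the rounded value.
* Tie-breaks everywhere prefer the lower index (frames, ensembles), for
  reproducibility over arbitrariness.
* Scan problem sizes: the bundled study conditions are a ~230-atom complex,
  10 snapshots, ~12 scanned residues — small enough that the full protocol
  runs in seconds to minutes on one CPU while exercising every stage.

## Limitations

* The reference backend is a coarse pairwise model. It does **not**
  reproduce the absolute interaction-energy scales of semiempirical QM
  (e.g. PM6-class methods with dispersion/H-bond corrections and COSMO-class
  solvation) or of production MM/GBSA setups, and no attempt is made to:
  published complex-specific magnitudes, hotspot identities for the
  insulin–receptor system, dimer-benchmark errors, method-to-method
  correlations, and fragment-size retention percentages for deposited
  structures all require external engines (MOPAC-, TURBOMOLE-, AMBER-class)
  and the deposited coordinates, and are outside what this package computes.
  Such engines are reachable only through the external-backend adapter.
* Pairwise additivity is built into the reference backend (exactly so with
  descreening off); many-body cooperativity — cooperative H-bond networks,
  polarization, σ-hole chalcogen bonding — is precisely what it cannot
  describe, and the S···O contact planted in the fixture is expected to
  score near zero under it. Engines that do describe such effects need not
  satisfy the additivity probe in the test suite; the contrast is
  documented there deliberately.
* VGS measures side-chain contributions only, skips Gly/Pro, neglects
  relaxation after mutation, and inherits the conformational ensemble it is
  given; its spread across snapshots is information, not noise to be
  averaged away.
* The synthetic generator's idealizations are listed above; no claim about
  real proteins follows from fixture-based tests alone.
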