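"""Bundled per-element and per-residue parameter tables.

These tables are coarse, fixed parameters intended for protocol plumbing and
ranking sanity, not for force-field fidelity:

* van der Waals radii for surface-area calculations,
* intrinsic (Born) radii for the generalized-Born solvation term,
* Lennard-Jones well depths/diameters by element,
* partial charges for the polar groups of the twenty standard amino acids in
  a polar-hydrogen representation (apolar hydrogens may be absent; any charge
  not covered by the template is redistributed so that every residue sums
  exactly to its formal charge),
* hydrogen-bond donor/acceptor typing per residue.
"""

from __future__ import annotations

# --- element tables -------------------------------------------------------

#: van der Waals radii (Angstrom) for SASA.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
}

#: intrinsic Born radii (Angstrom), mbondi-style coarse values.
GB_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.50,
    "S": 1.80,
    "P": 1.85,
}

#: Lennard-Jones parameters by element: (sigma in Angstrom, epsilon in kcal/mol).
LJ_PARAMS: dict[str, tuple[float, float]] = {
    "H": (1.00, 0.0157),
    "C": (3.40, 0.1094),
    "N": (3.25, 0.1700),
    "O": (2.96, 0.2100),
    "S": (3.56, 0.2500),
    "P": (3.74, 0.2000),
}

#: Coulomb constant, kcal*Angstrom/(mol*e^2).
COULOMB_CONSTANT = 332.0637

# --- residue vocabulary ---------------------------------------------------

STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

CAP_RESNAMES = {"ACE", "NME"}

#: solvent/ion records dropped on read.
SOLVENT_RESNAMES = {"HOH", "WAT", "DOD", "NA", "CL", "K", "MG", "NA+", "CL-"}

#: side-chain formal charges at pH 7 (His handled from protonation).
SIDECHAIN_FORMAL_CHARGE: dict[str, int] = {
    "ASP": -1, "GLU": -1, "LYS": +1, "ARG": +1,
}

# --- partial charges ------------------------------------------------------

#: backbone charges shared by all standard residues (sum 0).
BACKBONE_CHARGES: dict[str, float] = {
    "N": -0.40, "H": 0.30, "CA": 0.10, "C": 0.55, "O": -0.55,
}

#: polar/charged side-chain group charges; each template sums to the
#: side-chain formal charge of the residue.
SIDECHAIN_CHARGES: dict[str, dict[str, float]] = {
    "SER": {"CB": 0.25, "OG": -0.65, "HG": 0.40},
    "THR": {"CB": 0.25, "OG1": -0.65, "HG1": 0.40},
    "TYR": {"CZ": 0.25, "OH": -0.65, "HH": 0.40},
    "CYS": {"CB": 0.10, "SG": -0.30, "HG": 0.20},
    "MET": {"CG": 0.125, "SD": -0.25, "CE": 0.125},
    "ASN": {"CG": 0.60, "OD1": -0.60, "ND2": -0.80, "HD21": 0.40, "HD22": 0.40},
    "GLN": {"CD": 0.60, "OE1": -0.60, "NE2": -0.80, "HE21": 0.40, "HE22": 0.40},
    "ASP": {"CB": -0.15, "CG": 0.75, "OD1": -0.80, "OD2": -0.80},
    "GLU": {"CG": -0.15, "CD": 0.75, "OE1": -0.80, "OE2": -0.80},
    "LYS": {"CE": 0.30, "NZ": -0.35, "HZ1": 0.35, "HZ2": 0.35, "HZ3": 0.35},
    "ARG": {
        "CD": 0.20, "NE": -0.55, "HE": 0.35, "CZ": 0.80,
        "NH1": -0.70, "NH2": -0.70,
        "HH11": 0.40, "HH12": 0.40, "HH21": 0.40, "HH22": 0.40,
    },
    "HIS": {
        "CG": 0.10, "ND1": -0.55, "HD1": 0.35, "CD2": 0.05,
        "CE1": 0.25, "NE2": -0.55, "HE2": 0.35,
    },
    "TRP": {"NE1": -0.55, "HE1": 0.35, "CD1": 0.10, "CE2": 0.10},
    # caps
    "ACE": {"C": 0.55, "O": -0.55},
    "NME": {"N": -0.40, "H": 0.30, "CH3": 0.10},
}

# --- hydrogen-bond typing -------------------------------------------------

#: side-chain donor heavy atoms and the hydrogen names attached to them.
SIDECHAIN_DONORS: dict[str, dict[str, tuple[str, ...]]] = {
    "SER": {"OG": ("HG",)},
    "THR": {"OG1": ("HG1",)},
    "TYR": {"OH": ("HH",)},
    "CYS": {"SG": ("HG",)},
    "ASN": {"ND2": ("HD21", "HD22")},
    "GLN": {"NE2": ("HE21", "HE22")},
    "LYS": {"NZ": ("HZ1", "HZ2", "HZ3")},
    "ARG": {
        "NE": ("HE",),
        "NH1": ("HH11", "HH12"),
        "NH2": ("HH21", "HH22"),
    },
    "TRP": {"NE1": ("HE1",)},
    "HIS": {"ND1": ("HD1",), "NE2": ("HE2",)},
}

#: backbone amide donor (hydrogen naming variants allowed).
BACKBONE_DONOR_H = ("H", "HN", "H1", "H2", "H3")

#: side-chain acceptor heavy atoms.  His N acceptors apply only when the
#: matching hydrogen is absent (tautomer read from present hydrogens).
SIDECHAIN_ACCEPTORS: dict[str, tuple[str, ...]] = {
    "SER": ("OG",),
    "THR": ("OG1",),
    "TYR": ("OH",),
    "CYS": ("SG",),
    "MET": ("SD",),
    "ASN": ("OD1",),
    "GLN": ("OE1",),
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "HIS": ("ND1", "NE2"),
}

#: backbone acceptors present on every residue.
BACKBONE_ACCEPTORS = ("O", "OXT")

#: elements counted as apolar for nonpolar-contact detection.
APOLAR_ELEMENTS = frozenset({"C", "S"})

#: atom names regarded as backbone for the backbone/side-chain flags.
BACKBONE_ATOMS = frozenset(
    {"N", "CA", "C", "O", "OXT", "H", "HN", "H1", "H2", "H3", "HA", "HA2", "HA3"}
)
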