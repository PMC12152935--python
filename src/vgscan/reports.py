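"""Report writers: human-readable TSV tables and machine-readable JSON.

The contact tables mirror the conventional interface-analysis layout
(residue pair, backbone/side-chain flags, per-ensemble occupancy, average,
class letter); the scan table mirrors per-residue mean (std) contributions
with partner residues and tiers.  Energies are printed to 2 decimals in the
TSV tables and kept at full precision in JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .contacts import ContactRecord, average_and_classify, classify_hbond
from .vgs import VGSRecord


def _res_label(key, name: str) -> str:
    chain, num, ins = key
    return f"{name} {chain}{num}{ins}"


def contact_records_frame(records: list[ContactRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        rows.append(
            {
                "kind": rec.kind,
                "ligand_residue": _res_label(rec.ligand_residue, rec.ligand_residue_name),
                "receptor_residue": _res_label(rec.receptor_residue, rec.receptor_residue_name),
                "location": rec.location_flag if rec.kind == "hbond" else "",
                "n_atom_pairs": rec.n_atom_pairs if rec.kind == "nonpolar" else "",
                "occupancy_pct": rec.occupancy,
            }
        )
    return pd.DataFrame(rows)


def write_contact_reports(
    hbonds: list[ContactRecord], nonpolar: list[ContactRecord], outdir: str | Path
) -> None:
    outdir = Path(outdir)
    contact_records_frame(hbonds).to_csv(outdir / "hbonds.tsv", sep="\t", index=False)
    contact_records_frame(nonpolar).to_csv(outdir / "nonpolar.tsv", sep="\t", index=False)
    payload = [
        {
            "kind": r.kind,
            "ligand_residue": list(r.ligand_residue),
            "receptor_residue": list(r.receptor_residue),
            "ligand_residue_name": r.ligand_residue_name,
            "receptor_residue_name": r.receptor_residue_name,
            "occupancy_pct": r.occupancy,
            "n_atom_pairs": r.n_atom_pairs,
            "per_frame_present": [bool(b) for b in r.per_frame_present],
        }
        for r in hbonds + nonpolar
    ]
    (outdir / "contacts.json").write_text(json.dumps(payload, indent=2))


def classification_frame(
    per_ensemble: dict[str, list[ContactRecord]], kind: str
) -> pd.DataFrame:
    """Combine the same contact across several ensembles and classify it.

    ``per_ensemble`` maps ensemble labels to that ensemble's records; a
    contact is matched across ensembles by its residue pair (occupancy 0
    where absent).
    """
    labels = list(per_ensemble)
    keys: dict[tuple, ContactRecord] = {}
    for records in per_ensemble.values():
        for rec in records:
            if rec.kind == kind:
                keys.setdefault((rec.ligand_residue, rec.receptor_residue), rec)
    rows = []
    for key, proto in sorted(keys.items(), key=str):
        occs = []
        for label in labels:
            match = [
                r
                for r in per_ensemble[label]
                if r.kind == kind and (r.ligand_residue, r.receptor_residue) == key
            ]
            occs.append(match[0].occupancy if match else 0.0)
        row = {
            "ligand_residue": _res_label(proto.ligand_residue, proto.ligand_residue_name),
            "receptor_residue": _res_label(proto.receptor_residue, proto.receptor_residue_name),
        }
        row.update({label: occ for label, occ in zip(labels, occs)})
        if kind == "hbond":
            row["class"] = classify_hbond(occs)
        else:
            cls = average_and_classify(occs)
            row["average"] = cls.average_occupancy
            row["class"] = cls.nonpolar_class
        rows.append(row)
    return pd.DataFrame(rows)


def write_convergence_report(profile, outdir: str | Path) -> None:
    outdir = Path(outdir)
    rows = [
        {
            "radius_A": p.radius,
            "n_atoms": p.n_atoms,
            "total_charge": p.total_charge,
            "dG_int_kcal_mol": None if p.dG_int is None else round(p.dG_int, 2),
            "retention": None if p.retention is None else round(p.retention, 4),
            "error": p.error or "",
        }
        for p in profile.points
    ]
    pd.DataFrame(rows).to_csv(outdir / "convergence.tsv", sep="\t", index=False)


def vgs_frame(records: list[VGSRecord], contacts=None) -> pd.DataFrame:
    """Scan summary; partner residues are derived from contact records."""
    partners: dict = {}
    if contacts is not None:
        hb, np_ = contacts
        for rec in hb + np_:
            partners.setdefault(rec.ligand_residue, []).append(
                (rec.occupancy, _res_label(rec.receptor_residue, rec.receptor_residue_name))
            )
            partners.setdefault(rec.receptor_residue, []).append(
                (rec.occupancy, _res_label(rec.ligand_residue, rec.ligand_residue_name))
            )
    rows = []
    for rec in sorted(records, key=lambda r: -(r.mean if r.mean == r.mean else -1e9)):
        best_partners = sorted(partners.get(rec.residue_key, []), reverse=True)
        rows.append(
            {
                "residue": _res_label(rec.residue_key, rec.residue_name),
                "side": rec.side,
                "ddG_mean_kcal_mol": None if rec.failed else round(rec.mean, 2),
                "ddG_std": None if rec.failed else round(rec.std_dev, 2),
                "tier": rec.tier,
                "is_hotspot": rec.is_hotspot,
                "partners": "; ".join(p for _, p in best_partners[:3]),
                "failed": rec.failed,
            }
        )
    return pd.DataFrame(rows)


def write_vgs_reports(records: list[VGSRecord], outdir: str | Path, contacts=None) -> None:
    outdir = Path(outdir)
    vgs_frame(records, contacts).to_csv(outdir / "vgs.tsv", sep="\t", index=False)
    payload = [
        {
            "residue_key": list(rec.residue_key),
            "residue_name": rec.residue_name,
            "side": rec.side,
            "dG_wt": rec.dG_wt,
            "dG_gly": rec.dG_gly,
            "ddG_per_snapshot": rec.ddG_per_snapshot,
            "mean": rec.mean,
            "std_dev": rec.std_dev,
            "tier": rec.tier,
            "is_hotspot": rec.is_hotspot,
            "failed": rec.failed,
            "failure_reason": rec.failure_reason,
        }
        for rec in records
    ]
    (outdir / "vgs.json").write_text(json.dumps(payload, indent=2))
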