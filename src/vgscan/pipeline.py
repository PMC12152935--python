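"""End-to-end orchestration of the hierarchical interface-analysis protocol.

The protocol runs: contact/occupancy analysis → fragmentation (optionally a
radius-convergence scan) → snapshot selection by interaction energy → virtual
glycine scan, emitting a report bundle plus a run manifest.  Protocol
variants are labelled with the field's single-point//geometry notation
(e.g. ``MM//MD`` — fast single points on raw ensemble geometries).
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .contacts import ContactCriteria, detect_hbonds, detect_nonpolar, hbond_contact_records, nonpolar_contact_records
from .energy import BackendContract, BackendOptions, ReferenceBackend, interaction_energy
from .errors import VgscanError
from .fixtures import FixtureSpec, generate_fixture
from .fragment import ConvergenceProfile, FragmentationConfig, convergence_scan, truncate
from .structmodel import Ensemble, read_pdb, read_pdb_directory
from .vgs import HotspotCriteria, run_vgs

logger = logging.getLogger(__name__)

#: single-point energy backend // geometry provenance
VARIANT_LABELS = {"SQM//SQM", "SQM//MM", "SQM//MD", "MM//MM", "MM//MD"}


@dataclass(frozen=True)
class ProtocolVariant:
    """A single-point method paired with a geometry provenance.

    ``single_point`` and ``geometry`` use the field ids "SQM" (external
    semiempirical engine), "MM" (fast reference backend) and "MD" (raw,
    unoptimized ensemble geometries — geometry side only).
    """

    single_point: str
    geometry: str

    @property
    def label(self) -> str:
        return f"{self.single_point}//{self.geometry}"

    def __post_init__(self) -> None:
        if self.label not in VARIANT_LABELS:
            raise ValueError(f"unknown protocol variant {self.label!r}")

    @classmethod
    def from_label(cls, label: str) -> "ProtocolVariant":
        sp, _, geo = label.partition("//")
        return cls(sp, geo)


@dataclass
class SnapshotRanking:
    """Per-frame scores and the selected subset."""

    contact_counts: list[int] = field(default_factory=list)
    dG_int: list[float | None] = field(default_factory=list)
    selected: list[int] = field(default_factory=list)
    selection_rule: str = ""


def rank_ensembles_by_contacts(
    ensembles: list[Ensemble], criteria: ContactCriteria | None = None
) -> list[int]:
    """Order ensembles by total interface contact count, descending.

    The score is the number of H-bond plus nonpolar contact events summed
    over all frames; ties preserve input order (stable sort).
    """
    if not ensembles:
        raise ValueError("need at least one ensemble")
    criteria = criteria or ContactCriteria()
    scores = []
    for ens in ensembles:
        n = 0
        for fi in range(ens.n_frames):
            n += len(detect_hbonds(ens.topology, criteria, coords=ens.frames[fi]))
            n += len(detect_nonpolar(ens.topology, criteria, coords=ens.frames[fi]))
        scores.append(n)
    order = sorted(range(len(ensembles)), key=lambda i: (-scores[i], i))
    return order


def select_top_snapshots(
    ensemble: Ensemble,
    k: int,
    backend: BackendContract,
    fragment_config: FragmentationConfig | None = None,
) -> SnapshotRanking:
    """Pick the k frames with the most favourable interaction free energy.

    A fragment is built per frame (when a fragmentation config is given) and
    ΔG_int computed with the fast backend; the k most negative values win,
    ties broken by lower frame index.  Backend failures shrink the candidate
    pool with a warning.
    """
    if k > ensemble.n_frames:
        raise ValueError(f"k={k} exceeds {ensemble.n_frames} frames")
    ranking = SnapshotRanking(selection_rule=f"best-{k}-dG_int")
    criteria = ContactCriteria()
    for fi in range(ensemble.n_frames):
        system = ensemble.system_at(fi)
        n_contacts = len(detect_hbonds(system, criteria)) + len(detect_nonpolar(system, criteria))
        ranking.contact_counts.append(n_contacts)
        try:
            if fragment_config is not None:
                system = truncate(system, fragment_config).system
            ranking.dG_int.append(interaction_energy(system, backend).dG_int)
        except VgscanError as exc:
            logger.warning("frame %d dropped from selection: %s", fi, exc)
            ranking.dG_int.append(None)
    candidates = [(dg, fi) for fi, dg in enumerate(ranking.dG_int) if dg is not None]
    candidates.sort()  # most negative first; index breaks ties
    ranking.selected = sorted(fi for _, fi in candidates[:k])
    return ranking


# ---------------------------------------------------------------------------
# protocol configuration and run
# ---------------------------------------------------------------------------


@dataclass
class ProtocolConfig:
    """One configuration drives all stages (YAML-serializable)."""

    input_path: str | None = None  # PDB file or directory; None -> fixture
    chain_partition: dict[str, str] = field(default_factory=dict)
    variant: str = "MM//MD"
    seed: int = 0
    fixture: FixtureSpec = field(default_factory=FixtureSpec)
    contacts: ContactCriteria = field(default_factory=ContactCriteria)
    fragmentation: FragmentationConfig = field(default_factory=FragmentationConfig)
    hotspots: HotspotCriteria = field(default_factory=HotspotCriteria)
    backend_options: BackendOptions = field(default_factory=BackendOptions)
    run_convergence_scan: bool = True
    n_selected_snapshots: int = 10
    output_dir: str = "vgscan-out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ProtocolConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            current = getattr(cfg, key)
            if hasattr(current, "__dataclass_fields__") and isinstance(value, dict):
                setattr(cfg, key, type(current)(**value))
            else:
                setattr(cfg, key, value)
        return cfg


def _load_ensemble(config: ProtocolConfig) -> Ensemble:
    if config.input_path is None:
        spec = config.fixture
        if config.seed != spec.seed:
            from dataclasses import replace as dc_replace

            spec = dc_replace(spec, seed=config.seed)
        return generate_fixture(spec)
    path = Path(config.input_path)
    if path.is_dir():
        return read_pdb_directory(path, chain_partition=config.chain_partition)
    loaded = read_pdb(path, chain_partition=config.chain_partition)
    if isinstance(loaded, Ensemble):
        return loaded
    return Ensemble(loaded, [loaded.coords], ["frame-0"])


def run_protocol(config: ProtocolConfig, backend: BackendContract | None = None) -> dict:
    """Execute the full protocol and write the report bundle.

    Returns the manifest (also written as JSON).  A stage failure is
    recorded in the manifest and downstream stages are skipped.
    """
    from . import reports

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    backend = backend or ReferenceBackend(config.backend_options)
    manifest: dict = {
        "package_version": __version__,
        "python": platform.python_version(),
        "variant": config.variant,
        "seed": config.seed,
        "backend": backend.name,
        "stages": {},
    }
    ProtocolVariant.from_label(config.variant)  # validate

    ensemble: Ensemble | None = None
    stage = "load"
    try:
        ensemble = _load_ensemble(config)
        manifest["stages"][stage] = {
            "status": "ok",
            "n_atoms": ensemble.topology.n_atoms,
            "n_frames": ensemble.n_frames,
        }
    except Exception as exc:
        manifest["stages"][stage] = {"status": "failed", "error": str(exc)}

    contact_bundle = None
    if ensemble is not None:
        stage = "contacts"
        try:
            hb = hbond_contact_records(ensemble, config.contacts)
            np_ = nonpolar_contact_records(ensemble, config.contacts)
            contact_bundle = (hb, np_)
            reports.write_contact_reports(hb, np_, outdir)
            manifest["stages"][stage] = {
                "status": "ok",
                "n_hbond_contacts": len(hb),
                "n_nonpolar_contacts": len(np_),
            }
        except Exception as exc:
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}

    profile: ConvergenceProfile | None = None
    if ensemble is not None and config.run_convergence_scan:
        stage = "convergence_scan"
        try:
            profile = convergence_scan(
                ensemble.system_at(0), config.fragmentation, backend
            )
            reports.write_convergence_report(profile, outdir)
            manifest["stages"][stage] = {
                "status": "ok",
                "n_radii": len(profile.points),
                "selected_radius_0.9": profile.select_radius(0.9),
            }
        except Exception as exc:
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}

    ranking = None
    if ensemble is not None:
        stage = "snapshot_selection"
        try:
            k = min(config.n_selected_snapshots, ensemble.n_frames)
            ranking = select_top_snapshots(ensemble, k, backend, config.fragmentation)
            (outdir / "selection.json").write_text(
                json.dumps(
                    {
                        "contact_counts": ranking.contact_counts,
                        "dG_int": ranking.dG_int,
                        "selected": ranking.selected,
                        "rule": ranking.selection_rule,
                    },
                    indent=2,
                )
            )
            manifest["stages"][stage] = {"status": "ok", "selected": ranking.selected}
        except Exception as exc:
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}

    if ensemble is not None and ranking is not None:
        stage = "vgs"
        try:
            frags = [
                truncate(ensemble.system_at(fi), config.fragmentation)
                for fi in ranking.selected
            ]
            records = run_vgs(frags, backend, criteria=config.hotspots)
            reports.write_vgs_reports(records, outdir, contacts=contact_bundle)
            manifest["stages"][stage] = {
                "status": "ok",
                "n_scanned": len(records),
                "n_hotspots": sum(1 for r in records if r.is_hotspot),
            }
        except Exception as exc:
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
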