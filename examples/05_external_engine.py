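"""Wire an external energy engine through the adapter contract.

Any engine reachable as a shell command can serve as the single-point
method: the adapter writes a PDB/XYZ input, substitutes it into a command
template, and parses the energy back with a regular expression.  Here a
tiny stand-in script plays the engine so the example runs anywhere.
"""

import sys
import tempfile
from pathlib import Path

from vgscan import ExternalBackend, ExternalEngineConfig, FixtureSpec, generate_fixture
from vgscan.energy import interaction_energy

with tempfile.TemporaryDirectory() as tmp:
    engine = Path(tmp) / "toy_engine.py"
    # a stand-in engine: counts atoms and reports -0.05 kcal/mol per atom
    engine.write_text(
        "import sys\n"
        "n = sum(1 for l in open(sys.argv[1]) if l.startswith(('ATOM', 'HETATM')))\n"
        "open(sys.argv[2], 'w').write(f'TOTAL FREE ENERGY = {-0.05 * n:.4f} kcal/mol\\n')\n"
    )
    config = ExternalEngineConfig(
        command=f"{sys.executable} {engine} {{input}} {{output}}",
        energy_pattern=r"TOTAL FREE ENERGY =\s+(?P<g_total>-?\d+\.\d+)",
        name="toy-engine",
    )
    backend = ExternalBackend(config)

    system = generate_fixture(FixtureSpec(n_snapshots=1)).system_at(0)
    ie = interaction_energy(system, backend)
    print(f"engine: {backend.name}")
    print(f"G(complex)  = {ie.G_complex:9.2f} kcal/mol")
    print(f"G(ligand)   = {ie.G_ligand:9.2f} kcal/mol")
    print(f"G(receptor) = {ie.G_receptor:9.2f} kcal/mol")
    print(f"dG_int      = {ie.dG_int:9.2f} kcal/mol")
    # For this size-proportional toy engine dG_int is exactly 0 — the
    # complex has as many atoms as its two sides combined.  A real engine
    # (semiempirical QM, MM/GBSA, ...) plugs in the same way.
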