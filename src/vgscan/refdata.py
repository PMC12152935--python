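"""Bundled reference dataset: insulin–insulin receptor contact occupancies.

Per-trajectory MD occupancies of interface hydrogen bonds and nonpolar
residue-pair contacts for the insulin–IR complex (three short independent
trajectories), together with the published classification of each contact.
The dataset serves as a real-world input for the classification operations:
feeding the per-trajectory occupancy columns through
:func:`vgscan.contacts.classify_hbond` and
:func:`vgscan.contacts.average_and_classify` must reproduce every reported
class letter and trajectory average.

A reported occupancy of 0.0 marks a contact absent from that trajectory.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_TRAJ_COLS = ["traj1", "traj2", "traj3"]


def _load(name: str) -> pd.DataFrame:
    with resources.files("vgscan.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_hbond_occupancies() -> pd.DataFrame:
    """Interface H-bonds with per-trajectory occupancies (%)."""
    return _load("insulin_ir_hbonds.tsv")


def load_nonpolar_occupancies() -> pd.DataFrame:
    """Interface nonpolar residue-pair contacts with occupancies (%)."""
    return _load("insulin_ir_nonpolar.tsv")


def occupancy_columns(frame: pd.DataFrame) -> pd.DataFrame:
    """The per-trajectory occupancy columns of a reference table."""
    return frame[_TRAJ_COLS]
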