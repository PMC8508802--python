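"""Packaged reference tables for the 1,4-naphthoquinone compound family.

These are small published tables shipped with the package: X-ray/DFT bond
lengths for the parent compounds (1a = 1,4-naphthoquinone, 2a =
8-hydroxy-1,4-naphthoquinone, 3a = naphthazarin) and the bromo pair
2b/2b(M), the substitution-pattern grammar of the 25-compound series, the
ring-bond label lists, and CPMD donor-possession percentages for group 3
(reference values only — the underlying trajectories are not public).
"""

from __future__ import annotations

from importlib.resources import files
from pathlib import Path

import pandas as pd
import yaml

from .aromaticity import BondLengthSet, read_bond_table

__all__ = [
    "data_path",
    "parent_bond_lengths",
    "bromo_bond_lengths",
    "ring_bond_labels",
    "substitution_patterns",
    "cpmd_donor_possession",
]


def data_path(name: str) -> Path:
    """Filesystem path of a packaged data file."""
    return Path(str(files("nqbridge").joinpath("data", name)))


def parent_bond_lengths() -> dict[str, BondLengthSet]:
    """Bond sets per column (1a/2a/3a, X-ray and DFT)."""
    return read_bond_table(data_path("parent_bond_lengths.tsv"))


def bromo_bond_lengths() -> dict[str, BondLengthSet]:
    """Bond sets for 2b (two X-ray molecules + DFT) and 2b(M)."""
    return read_bond_table(data_path("bromo_bond_lengths.tsv"))


def ring_bond_labels() -> dict[str, list[str]]:
    """Bond labels of ring I (quinoid) and ring II (benzene)."""
    return yaml.safe_load(data_path("ring_bonds.yaml").read_text())


def substitution_patterns() -> pd.DataFrame:
    """R1–R4 substituents (H/Br) for every compound label."""
    return pd.read_csv(data_path("substitution_patterns.tsv"), sep="\t")


def cpmd_donor_possession() -> pd.DataFrame:
    """Published donor proton-possession percentages for group 3 (CPMD)."""
    return pd.read_csv(data_path("cpmd_donor_possession.tsv"), sep="\t")
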