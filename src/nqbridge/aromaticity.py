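"""HOMA — the Harmonic Oscillator Model of Aromaticity.

The index scores a carbocycle by how far its CC bond lengths deviate from
the optimal aromatic length::

    HOMA = 1 - (alpha / n) * sum_i (d_opt - d_i)**2

with the standard CC parameterization alpha = 257.7 and d_opt = 1.388 Å.
HOMA = 1 for perfectly equalized aromatic bonds, 0 for a hypothetical
non-aromatic (Kekulé-localized) ring, and negative for strongly localized
or antiaromatic rings such as the quinoid ring of 1,4-naphthoquinone.

Bond lengths can come from a geometry plus a :class:`RingDefinition`, or
from delimited bond-length tables (the format used for published X-ray/DFT
bond tables of the parent quinones).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import MolecularGeometry, RingDefinition, bond_length

__all__ = [
    "HomaParameters",
    "BondLengthSet",
    "homa",
    "homa_from_geometry",
    "read_bond_table",
]

#: cells marking an absent bond in published tables (ASCII and typographic)
_MISSING_MARKS = {"-", "–", "—", ""}


@dataclass(frozen=True)
class HomaParameters:
    """CC parameterization of the HOMA model."""

    alpha: float = 257.7  # empirical normalization constant
    d_opt: float = 1.388  # optimal aromatic CC length, Å

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.d_opt <= 0:
            raise ValueError("alpha and d_opt must be positive")


@dataclass(frozen=True)
class BondLengthSet:
    """An ordered set of bond lengths (Å) with optional labels."""

    lengths: tuple[float, ...]
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "lengths", tuple(float(d) for d in self.lengths))
        if any(d <= 0 for d in self.lengths):
            raise ValueError("bond lengths must be positive")
        if self.labels is not None and len(self.labels) != len(self.lengths):
            raise ValueError("labels and lengths length mismatch")

    def __len__(self) -> int:
        return len(self.lengths)

    def subset(self, labels: Sequence[str]) -> "BondLengthSet":
        """Select bonds by label (order of ``labels``); KeyError if absent."""
        if self.labels is None:
            raise ValueError("bond set carries no labels")
        lut = dict(zip(self.labels, self.lengths))
        missing = [l for l in labels if l not in lut]
        if missing:
            raise KeyError(f"bond labels not in table: {missing}")
        return BondLengthSet(
            lengths=tuple(lut[l] for l in labels), labels=tuple(labels)
        )


def homa(bonds: BondLengthSet, params: HomaParameters = HomaParameters()) -> float:
    """HOMA score of a bond-length set; 1 means ideal aromatic equalization."""
    n = len(bonds)
    if n < 3:
        raise ValueError("HOMA needs at least 3 bonds (a closed ring)")
    d = np.asarray(bonds.lengths)
    return float(1.0 - params.alpha / n * np.sum((params.d_opt - d) ** 2))


def homa_from_geometry(
    geom: MolecularGeometry,
    ring: RingDefinition,
    params: HomaParameters = HomaParameters(),
) -> float:
    """HOMA of a ring measured on a geometry.

    The CC parameterization is only valid for carbocycles, so any
    non-carbon ring atom is rejected rather than silently approximated.
    """
    for idx in ring.atoms:
        sym = geom.elements[idx - 1]
        if sym != "C":
            raise ValueError(
                f"ring {ring.label!r}: atom {idx} is {sym}, not C — "
                "HOMA here is parameterized for CC bonds only"
            )
    lengths = tuple(bond_length(geom, i, j) for i, j in ring.bonds)
    labels = tuple(f"{i}-{j}" for i, j in ring.bonds)
    return homa(BondLengthSet(lengths=lengths, labels=labels), params)


def read_bond_table(path: str | Path) -> dict[str, BondLengthSet]:
    """Read a delimited bond-length table into per-compound bond sets.

    First column: bond label (e.g. ``C5-C6``); remaining columns: one
    compound each, lengths in Å; ``–`` marks a bond absent in that
    compound (dropped from its set).  Tab- or comma-delimited.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path}: empty bond table")
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need a label column plus >=1 compound column")
    label_col = df.columns[0]
    out: dict[str, BondLengthSet] = {}
    for col in df.columns[1:]:
        labels: list[str] = []
        lengths: list[float] = []
        for row, (lbl, cell) in enumerate(zip(df[label_col], df[col])):
            cell = "" if pd.isna(cell) else str(cell).strip()
            if cell in _MISSING_MARKS:
                continue
            try:
                val = float(cell)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: non-numeric cell {cell!r} at row {row + 2}, "
                    f"column {col!r}"
                ) from exc
            labels.append(str(lbl).strip())
            lengths.append(val)
        out[str(col)] = BondLengthSet(lengths=tuple(lengths), labels=tuple(labels))
    return out
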