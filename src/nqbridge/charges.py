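"""cSAR — charge of the Substituent Active Region.

For a substituent X attached at the ipso carbon::

    cSAR(X) = q(X) + q(C_ipso)

where q(X) sums the partial atomic charges of the substituent's atoms.
The descriptor is partial-charge-scheme agnostic (Hirshfeld charges are
the usual choice for this family); the table records the scheme name as
metadata only.  Unsubstituted ring positions are handled as one-atom
hydrogen "substituents" so a profile can cover all positions 1–8.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "ChargeTable",
    "SubstituentGroup",
    "csar",
    "csar_profile",
    "read_charge_table",
    "write_charge_table",
]


@dataclass(frozen=True)
class ChargeTable:
    """Per-atom partial charges (e), keyed by 1-based atom index."""

    charges: dict[int, float]
    element: dict[int, str]
    compound: str = ""
    scheme: str = ""  # e.g. "hirshfeld"; informational only

    def __post_init__(self) -> None:
        for idx, q in self.charges.items():
            if not (q == q and abs(q) != float("inf")):
                raise ValueError(f"non-finite charge at atom {idx}")

    @property
    def total_charge(self) -> float:
        """Sum of all partial charges (diagnostic; ~molecular charge)."""
        return float(sum(self.charges.values()))


@dataclass(frozen=True)
class SubstituentGroup:
    """A substituent's atoms plus its ipso carbon, at one ring position."""

    ipso: int
    substituent_atoms: frozenset[int]
    position_label: str

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "substituent_atoms", frozenset(int(a) for a in self.substituent_atoms)
        )
        if not self.substituent_atoms:
            raise ValueError("substituent needs at least one atom")
        if self.ipso in self.substituent_atoms:
            raise ValueError("ipso carbon cannot be part of the substituent")


def _charge(table: ChargeTable, idx: int) -> float:
    try:
        return table.charges[idx]
    except KeyError:
        raise KeyError(f"atom index {idx} missing from charge table") from None


def csar(table: ChargeTable, group: SubstituentGroup) -> float:
    """cSAR(X) = q(X) + q(C_ipso), in e."""
    q_x = sum(_charge(table, a) for a in sorted(group.substituent_atoms))
    return float(q_x + _charge(table, group.ipso))


def csar_profile(
    table: ChargeTable, groups: Sequence[SubstituentGroup]
) -> dict[str, float]:
    """Per-position cSAR values, ordered by position label."""
    labels = [g.position_label for g in groups]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate position labels: {dupes}")
    return {
        g.position_label: csar(table, g)
        for g in sorted(groups, key=lambda g: g.position_label)
    }


def read_charge_table(path: str | Path) -> ChargeTable:
    """Read a delimited charge table: columns index, element, charge."""
    path = Path(path)
    sep = "\t" if "\t" in path.read_text().splitlines()[0] else ","
    df = pd.read_csv(path, sep=sep)
    if df.shape[1] < 3:
        raise ValueError(f"{path}: need columns index, element, charge")
    charges: dict[int, float] = {}
    element: dict[int, str] = {}
    for row in range(len(df)):
        try:
            idx = int(df.iloc[row, 0])
            q = float(df.iloc[row, 2])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: bad value at row {row + 2}") from exc
        if idx in charges:
            raise ValueError(f"{path}: duplicate atom index {idx} at row {row + 2}")
        charges[idx] = q
        element[idx] = str(df.iloc[row, 1]).strip()
    return ChargeTable(charges=charges, element=element, compound=path.stem)


def write_charge_table(table: ChargeTable, path: str | Path) -> Path:
    """Write a charge table as TSV (index, element, charge)."""
    path = Path(path)
    rows = sorted(table.charges)
    df = pd.DataFrame(
        {
            "index": rows,
            "element": [table.element.get(i, "X") for i in rows],
            "charge": [table.charges[i] for i in rows],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    return path
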