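"""Proton-transfer energy profiles from relaxed O–H scans.

A profile is a 1-D relaxed scan of the bridging proton along the O–H
coordinate (typical increment 0.05 Å).  The analysis locates the grid
minima and reports the two energetics that characterize the bridge: the
transfer barrier height and the energy of the second minimum (the PT
tautomer), both relative to the global minimum.  Grid extrema are
reported as-is by default — scan energetics are conventionally quoted on
the scan grid — with an optional 3-point parabolic refinement.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "HARTREE_TO_KCAL",
    "PTProfile",
    "ProfileAnalysis",
    "analyze_profile",
    "read_profile",
    "compare_series",
]

HARTREE_TO_KCAL = 627.5095


@dataclass(frozen=True)
class PTProfile:
    """(O–H distance, relative energy) points of one scan."""

    r: tuple[float, ...]  # Å, strictly increasing
    E: tuple[float, ...]  # kcal/mol, arbitrary reference
    compound: str = ""
    bridge: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "r", tuple(float(x) for x in self.r))
        object.__setattr__(self, "E", tuple(float(x) for x in self.E))
        if len(self.r) != len(self.E):
            raise ValueError("r and E length mismatch")
        if len(self.r) < 5:
            raise ValueError("profile needs at least 5 points")
        if any(b <= a for a, b in zip(self.r, self.r[1:])):
            raise ValueError("r must be strictly increasing")


@dataclass(frozen=True)
class ProfileAnalysis:
    """Stationary-point summary of one PT profile.

    Energies are relative to the global minimum; ``r_min1`` is the
    left-hand well.  When no second minimum exists, the barrier fields
    are None.
    """

    r_min1: float
    r_barrier: float | None
    r_min2: float | None
    E_barrier: float | None
    E_min2: float | None
    has_second_minimum: bool


def _local_minima(E: np.ndarray) -> list[int]:
    """Grid indices of local minima; plateaus collapse to their leftmost
    index; endpoints count when below their single neighbor."""
    n = len(E)
    minima: list[int] = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and E[j + 1] == E[i]:
            j += 1  # plateau [i..j]
        left_up = i == 0 or E[i - 1] > E[i]
        right_up = j == n - 1 or E[j + 1] > E[i]
        if left_up and right_up and not (i == 0 and j == n - 1):
            minima.append(i)
        i = j + 1
    return minima


def _parabolic(r: np.ndarray, E: np.ndarray, k: int) -> tuple[float, float]:
    """3-point parabolic refinement of the stationary point at index k."""
    if k == 0 or k == len(r) - 1:
        return float(r[k]), float(E[k])
    x0, x1, x2 = r[k - 1 : k + 2]
    y0, y1, y2 = E[k - 1 : k + 2]
    denom = (y0 - 2 * y1 + y2)
    if denom == 0:
        return float(r[k]), float(E[k])
    h = x1 - x0
    delta = 0.5 * (y0 - y2) / denom
    return float(x1 + delta * h), float(y1 - 0.25 * (y0 - y2) * delta)


def analyze_profile(profile: PTProfile, refine: bool = False) -> ProfileAnalysis:
    """Locate wells and barrier of a PT scan.

    The two lowest grid minima define the wells; the barrier is the
    maximum strictly between them.  All energies are re-referenced to the
    global minimum.  ``refine=True`` applies 3-point parabolic
    interpolation to interior stationary points.
    """
    r = np.asarray(profile.r)
    E = np.asarray(profile.E, dtype=float)
    minima = _local_minima(E)
    if not minima:  # strictly monotonic profile: endpoint rule guarantees >=1
        minima = [int(np.argmin(E))]
    order = sorted(minima, key=lambda k: (E[k], r[k]))
    k_glob = order[0]
    E0 = E[k_glob]
    if len(order) < 2:
        return ProfileAnalysis(
            r_min1=float(r[k_glob]),
            r_barrier=None,
            r_min2=None,
            E_barrier=None,
            E_min2=None,
            has_second_minimum=False,
        )
    k_sec = order[1]
    k_left, k_right = sorted((k_glob, k_sec))
    seg = slice(k_left + 1, k_right)
    k_bar = k_left + 1 + int(np.argmax(E[seg]))
    r_min1, e_min1 = float(r[k_left]), float(E[k_left] - E0)
    r_min2, e_min2 = float(r[k_right]), float(E[k_right] - E0)
    r_bar, e_bar = float(r[k_bar]), float(E[k_bar] - E0)
    if refine:
        r_min1, e1 = _parabolic(r, E - E0, k_left)
        r_min2, e2 = _parabolic(r, E - E0, k_right)
        r_bar, e_bar = _parabolic(r, E - E0, k_bar)
        shift = min(e1, e2)
        e_bar -= shift
        e_min1, e_min2 = e1 - shift, e2 - shift
    # E_min2 is the higher well (>= 0 relative to the global minimum)
    return ProfileAnalysis(
        r_min1=r_min1,
        r_barrier=r_bar,
        r_min2=r_min2,
        E_barrier=e_bar,
        E_min2=max(e_min1, e_min2),
        has_second_minimum=True,
    )


def read_profile(
    path: str | Path,
    units: str = "kcal",
    compound: str = "",
    bridge: str = "",
) -> PTProfile:
    """Read a two-column (r, E) profile; ``units`` is 'kcal' or 'hartree'.

    Energies are converted to kcal/mol and re-referenced to the profile
    minimum.
    """
    if units not in ("kcal", "hartree"):
        raise ValueError("units must be 'kcal' or 'hartree'")
    path = Path(path)
    first = path.read_text().splitlines()[0] if path.read_text().strip() else ""
    sep = "\t" if "\t" in first else None
    df = pd.read_csv(path, sep=sep or r"[,\s]+", engine="python", header=None,
                     comment="#")
    # tolerate a header row of non-numeric labels
    try:
        float(df.iloc[0, 0])
    except (TypeError, ValueError):
        df = df.iloc[1:].reset_index(drop=True)
    r = df.iloc[:, 0].astype(float).to_numpy()
    E = df.iloc[:, 1].astype(float).to_numpy()
    if len(r) < 5:
        raise ValueError(f"{path}: fewer than 5 scan points")
    if len(np.unique(r)) != len(r):
        raise ValueError(f"{path}: duplicated r value")
    order = np.argsort(r)
    r, E = r[order], E[order]
    if units == "hartree":
        E = E * HARTREE_TO_KCAL
    E = E - E.min()
    return PTProfile(r=tuple(r), E=tuple(E), compound=compound, bridge=bridge)


def _pattern_key(label: str) -> str | None:
    """Substitution-pattern key shared across groups: '3b' -> 'b', '2d(M)'
    -> 'd(M)'; None when the label does not follow the series grammar."""
    import re

    m = re.fullmatch(r"([123])([a-g])(\(M\))?", label)
    if not m:
        return None
    return m.group(2) + (m.group(3) or "")


def compare_series(analyses: Mapping[str, ProfileAnalysis]) -> pd.DataFrame:
    """Tabulate barrier/second-minimum energetics and matched-pair deltas.

    Compounds sharing a substitution pattern across groups (e.g. 2b vs
    3b) are matched; the delta rows report E(group m) − E(group n) for
    each matched pair.  Missing matches are simply absent.
    """
    if len(analyses) < 2:
        rows = [
            {
                "compound": c,
                "E_barrier": a.E_barrier,
                "E_min2": a.E_min2,
            }
            for c, a in analyses.items()
        ]
        return pd.DataFrame(rows)
    rows = []
    for c in sorted(analyses):
        a = analyses[c]
        rows.append({"compound": c, "E_barrier": a.E_barrier, "E_min2": a.E_min2})
    by_pattern: dict[str, list[str]] = {}
    for c in sorted(analyses):
        key = _pattern_key(c)
        if key is not None:
            by_pattern.setdefault(key, []).append(c)
    for key, members in sorted(by_pattern.items()):
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = analyses[members[i]], analyses[members[j]]
                rows.append(
                    {
                        "compound": f"{members[i]} vs {members[j]}",
                        "E_barrier": _delta(a.E_barrier, b.E_barrier),
                        "E_min2": _delta(a.E_min2, b.E_min2),
                    }
                )
    return pd.DataFrame(rows)


def _delta(x: float | None, y: float | None) -> float | None:
    if x is None or y is None:
        return None
    return x - y
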