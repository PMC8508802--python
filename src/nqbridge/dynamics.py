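"""Trajectory analytics for twin intramolecular O–H...O bridges.

The central observable is the signed asymmetry of each bridge,
``delta(t) = d(donor,H) - d(H,acceptor)``: negative while the proton sits
on the donor side, positive after a proton transfer (PT).  From it the
module derives

* per-frame proton possession (the proton belongs to the closer oxygen;
  exact ties go to the donor),
* discrete PT events via a hysteresis filter that ignores barrier-top
  chatter, and
* inter-bridge synchrony statistics from greedy nearest-time event
  matching — the twin bridges of naphthazarin-like compounds transfer
  almost simultaneously, with sub-0.1 ps delays.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import BridgeSpec, Trajectory

__all__ = [
    "BridgeSeries",
    "PossessionStats",
    "PTEventList",
    "SynchronyStats",
    "extract_bridge_series",
    "possession",
    "detect_pt_events",
    "bridge_synchrony",
    "possession_report",
]

#: default hysteresis (Å) for event confirmation; below the ~0.05 Å O–H
#: displacement scale of the transfer coordinate, so real transfers always
#: clear it while barrier-top recrossings do not.
DEFAULT_HYSTERESIS = 0.05

#: default synchrony matching window (fs); comfortably above the <100 fs
#: inter-bridge delays seen in coupled double-bridge systems.
DEFAULT_WINDOW = 500.0


@dataclass(frozen=True)
class BridgeSeries:
    """Per-frame donor–H and H–acceptor distances for one bridge."""

    t: np.ndarray  # fs
    d_donor_H: np.ndarray  # Å
    d_H_acceptor: np.ndarray  # Å
    bridge: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        d1 = np.asarray(self.d_donor_H, dtype=float)
        d2 = np.asarray(self.d_H_acceptor, dtype=float)
        if not (len(t) == len(d1) == len(d2)):
            raise ValueError("series arrays must have equal length")
        if len(t) == 0:
            raise ValueError("empty bridge series")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "d_donor_H", d1)
        object.__setattr__(self, "d_H_acceptor", d2)

    @property
    def delta(self) -> np.ndarray:
        """Signed asymmetry d(donor,H) − d(H,acceptor); <0 on the donor side."""
        return self.d_donor_H - self.d_H_acceptor


@dataclass(frozen=True)
class PossessionStats:
    donor_fraction: float
    acceptor_fraction: float
    n_frames: int


@dataclass(frozen=True)
class PTEventList:
    """Confirmed transfer events; directions alternate by construction."""

    times: tuple[float, ...]  # fs
    directions: tuple[str, ...]  # "donor->acceptor" | "acceptor->donor"

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class SynchronyStats:
    delays: tuple[float, ...]  # fs, |t1 - t2| of matched pairs
    match_fraction: float
    max_delay: float | None
    n_matched: int


def extract_bridge_series(traj: Trajectory, bridge: BridgeSpec) -> BridgeSeries:
    """Donor–H / H–acceptor distance time series, equilibration removed."""
    mask = traj.production_mask()
    if not mask.any():
        raise ValueError("equilibration window covers the whole trajectory")
    pos = traj.positions[mask]
    t = traj.times[mask]
    d = pos[:, bridge.donor - 1]
    h = pos[:, bridge.proton - 1]
    a = pos[:, bridge.acceptor - 1]
    return BridgeSeries(
        t=t,
        d_donor_H=np.linalg.norm(d - h, axis=1),
        d_H_acceptor=np.linalg.norm(h - a, axis=1),
        bridge=bridge.label,
    )


def possession(series: BridgeSeries) -> PossessionStats:
    """Frame-wise proton possession; the proton belongs to the closer
    oxygen, exact ties assigned to the donor."""
    donor = series.d_donor_H <= series.d_H_acceptor
    n = len(donor)
    f = float(np.count_nonzero(donor)) / n
    return PossessionStats(donor_fraction=f, acceptor_fraction=1.0 - f, n_frames=n)


def detect_pt_events(
    series: BridgeSeries, hysteresis: float = DEFAULT_HYSTERESIS
) -> PTEventList:
    """Discrete PT events from the sign of delta with a hysteresis filter.

    An event is recorded at the first frame where delta changes sign
    relative to the confirmed state, but only once |delta| exceeds the
    hysteresis on the new side before recrossing; chatter inside the
    ±hysteresis band never produces events.
    """
    if hysteresis < 0:
        raise ValueError("hysteresis must be >= 0")
    delta = series.delta
    t = series.t
    # confirmed side: -1 donor, +1 acceptor; ties start on the donor side
    state = -1 if delta[0] <= 0 else 1
    times: list[float] = []
    directions: list[str] = []
    pending: float | None = None
    for k in range(1, len(delta)):
        d = delta[k]
        opposite = (d > 0) if state == -1 else (d <= 0)
        if not opposite:
            pending = None  # recrossed before confirmation
            continue
        if pending is None:
            pending = float(t[k])
        if abs(d) >= hysteresis:
            times.append(pending)
            directions.append(
                "donor->acceptor" if state == -1 else "acceptor->donor"
            )
            state = -state
            pending = None
    return PTEventList(times=tuple(times), directions=tuple(directions))


def bridge_synchrony(
    events1: PTEventList,
    events2: PTEventList,
    window: float = DEFAULT_WINDOW,
) -> SynchronyStats:
    """Greedy nearest-time matching of PT events across the two bridges.

    Candidate pairs within ``window`` fs are accepted smallest-delay
    first, each event used at most once.  The match fraction is
    n_matched / max(n1, n2); two empty trains match vacuously.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    t1 = np.asarray(events1.times)
    t2 = np.asarray(events2.times)
    n1, n2 = len(t1), len(t2)
    if max(n1, n2) == 0:
        return SynchronyStats(delays=(), match_fraction=1.0, max_delay=None,
                              n_matched=0)
    pairs = [
        (abs(a - b), i, j)
        for i, a in enumerate(t1)
        for j, b in enumerate(t2)
        if abs(a - b) <= window
    ]
    pairs.sort()
    used1: set[int] = set()
    used2: set[int] = set()
    delays: list[float] = []
    for d, i, j in pairs:
        if i in used1 or j in used2:
            continue
        used1.add(i)
        used2.add(j)
        delays.append(float(d))
    frac = len(delays) / max(n1, n2)
    return SynchronyStats(
        delays=tuple(delays),
        match_fraction=frac,
        max_delay=max(delays) if delays else None,
        n_matched=len(delays),
    )


def possession_report(
    traj: Trajectory, bridges: Sequence[BridgeSpec]
) -> pd.DataFrame:
    """Donor-possession percentages (1 decimal) for each bridge."""
    rows = []
    for b in bridges:
        stats = possession(extract_bridge_series(traj, b))
        rows.append(
            {
                "bridge": b.label or f"{b.donor}-{b.proton}-{b.acceptor}",
                "donor_percent": round(100.0 * stats.donor_fraction, 1),
                "acceptor_percent": round(100.0 * stats.acceptor_fraction, 1),
                "n_frames": stats.n_frames,
            }
        )
    return pd.DataFrame(rows)
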