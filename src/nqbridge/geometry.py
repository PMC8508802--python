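"""Molecular geometries, XYZ trajectories and hydrogen-bridge metrics.

Atom indexing follows the crystallographic numbering convention used for
1,4-naphthoquinone derivatives (C1..C10, O1..O4, bridge protons H1/H2):
all public interfaces take **1-based** atom indices.  Coordinates are in
Ångström, times in femtoseconds, velocities in Å/fs.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

__all__ = [
    "MolecularGeometry",
    "Trajectory",
    "RingDefinition",
    "BridgeSpec",
    "BridgeMetrics",
    "read_xyz",
    "write_xyz",
    "bond_length",
    "bridge_metrics",
    "load_compound_config",
    "XYZParseError",
]

# IUPAC element symbols (Z = 1..118); used to reject misparsed atom lines.
ELEMENT_SYMBOLS = frozenset(
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe Co "
    "Ni Cu Zn Ga Ge As Se Br Kr Rb Sr Y Zr Nb Mo Tc Ru Rh Pd Ag Cd In Sn Sb "
    "Te I Xe Cs Ba La Ce Pr Nd Pm Sm Eu Gd Tb Dy Ho Er Tm Yb Lu Hf Ta W Re "
    "Os Ir Pt Au Hg Tl Pb Bi Po At Rn Fr Ra Ac Th Pa U Np Pu Am Cm Bk Cf Es "
    "Fm Md No Lr Rf Db Sg Bh Hs Mt Ds Rg Cn Nh Fl Mc Lv Ts Og".split()
)

#: atomic-unit velocity (Bohr per a.u. of time) expressed in Å/fs
AU_VELOCITY_IN_ANG_PER_FS = 0.529177210903 / 2.4188843265857e-2


class XYZParseError(ValueError):
    """Raised when an XYZ file cannot be parsed."""


@dataclass(frozen=True)
class MolecularGeometry:
    """One frame: element symbols plus Cartesian coordinates in Å."""

    elements: tuple[str, ...]
    coords: np.ndarray
    frame_time: float | None = None  # fs; None for static structures

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "elements", tuple(self.elements))
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_atoms, 3)")
        if len(self.elements) != coords.shape[0]:
            raise ValueError("elements and coords length mismatch")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        for sym in self.elements:
            if sym not in ELEMENT_SYMBOLS:
                raise ValueError(f"unknown element symbol {sym!r}")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)


@dataclass
class Trajectory:
    """Time-ordered frames with a constant sampling interval.

    velocities, when present, has shape (n_frames, n_atoms, 3) in Å/fs.
    equilibration_time (fs) marks an initial window excluded from analyses.
    """

    frames: list[MolecularGeometry]
    dt: float  # fs
    velocities: np.ndarray | None = None
    equilibration_time: float = 0.0

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("trajectory needs at least one frame")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        first = self.frames[0]
        for k, fr in enumerate(self.frames[1:], start=1):
            if fr.elements != first.elements:
                raise ValueError(
                    f"frame {k}: atom count/element ordering differs from frame 0"
                )
        if self.velocities is not None:
            v = np.asarray(self.velocities, dtype=float)
            if v.shape != (self.n_frames, first.n_atoms, 3):
                raise ValueError("velocities must have shape (n_frames, n_atoms, 3)")
            self.velocities = v
        if self.equilibration_time < 0:
            raise ValueError("equilibration_time must be >= 0")
        if self.n_frames > 1 and self.equilibration_time >= self.duration:
            raise ValueError("equilibration_time exceeds trajectory duration")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return self.frames[0].n_atoms

    @property
    def duration(self) -> float:
        """Total span in fs (frame 0 to last frame)."""
        return (self.n_frames - 1) * self.dt

    @property
    def times(self) -> np.ndarray:
        """Frame times in fs; from per-frame metadata when available."""
        if all(fr.frame_time is not None for fr in self.frames):
            return np.array([fr.frame_time for fr in self.frames], dtype=float)
        return np.arange(self.n_frames) * self.dt

    @property
    def positions(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) coordinate array."""
        return np.stack([fr.coords for fr in self.frames])

    def production_mask(self) -> np.ndarray:
        """Boolean mask of frames past the equilibration window."""
        t = self.times
        return (t - t[0]) >= self.equilibration_time


@dataclass(frozen=True)
class RingDefinition:
    """Ordered 1-based atom indices closing a cycle (ring I, ring II...)."""

    label: str
    atoms: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "atoms", tuple(int(a) for a in self.atoms))
        if len(self.atoms) < 3:
            raise ValueError("a ring needs at least 3 atoms")
        if len(set(self.atoms)) != len(self.atoms):
            raise ValueError("ring atoms must be distinct")

    @property
    def bonds(self) -> tuple[tuple[int, int], ...]:
        """Consecutive (cyclic) index pairs; one bond per ring atom."""
        n = len(self.atoms)
        return tuple((self.atoms[i], self.atoms[(i + 1) % n]) for i in range(n))


@dataclass(frozen=True)
class BridgeSpec:
    """Donor O — bridging H — acceptor O, by 1-based atom index."""

    donor: int
    proton: int
    acceptor: int
    label: str = ""

    def __post_init__(self) -> None:
        if len({self.donor, self.proton, self.acceptor}) != 3:
            raise ValueError("bridge indices must be distinct")


@dataclass(frozen=True)
class BridgeMetrics:
    """Geometric descriptors of one O–H...O bridge."""

    d_OO: float  # Å
    d_OH: float  # Å, donor–proton
    d_HO: float  # Å, proton–acceptor
    angle_OHO: float  # degrees, at the proton vertex


def _check_index(geom: MolecularGeometry, i: int) -> int:
    if not 1 <= i <= geom.n_atoms:
        raise IndexError(f"atom index {i} out of range 1..{geom.n_atoms}")
    return i - 1


def bond_length(geom: MolecularGeometry, i: int, j: int) -> float:
    """Euclidean distance in Å between atoms i and j (1-based)."""
    if i == j:
        raise ValueError("bond requires two distinct atoms")
    a = geom.coords[_check_index(geom, i)]
    b = geom.coords[_check_index(geom, j)]
    return float(np.linalg.norm(a - b))


def bridge_metrics(geom: MolecularGeometry, bridge: BridgeSpec) -> BridgeMetrics:
    """Distances and the O–H...O valence angle for one hydrogen bridge."""
    o_d = geom.coords[_check_index(geom, bridge.donor)]
    h = geom.coords[_check_index(geom, bridge.proton)]
    o_a = geom.coords[_check_index(geom, bridge.acceptor)]
    d_oh = float(np.linalg.norm(o_d - h))
    d_ho = float(np.linalg.norm(h - o_a))
    d_oo = float(np.linalg.norm(o_d - o_a))
    if d_oh == 0.0 or d_ho == 0.0 or d_oo == 0.0:
        raise ValueError("coincident atoms in bridge")
    u = (o_d - h) / d_oh
    v = (o_a - h) / d_ho
    cosang = float(np.clip(np.dot(u, v), -1.0, 1.0))
    return BridgeMetrics(
        d_OO=d_oo, d_OH=d_oh, d_HO=d_ho, angle_OHO=math.degrees(math.acos(cosang))
    )


# ---------------------------------------------------------------------------
# XYZ I/O
# ---------------------------------------------------------------------------

_TIME_RE = re.compile(r"\bt\s*=\s*([-+0-9.eE]+)")


def read_xyz(path: str | Path, dt: float | None = None) -> Trajectory:
    """Read a (multi-frame) XYZ file into a Trajectory.

    Atom lines are ``element x y z [vx vy vz]``; velocity columns are in
    Å/fs unless the comment line declares ``vel_units=au`` (converted on
    read).  The comment line may carry ``t= <fs>`` frame times; if it does
    not and the file holds more than one frame, ``dt`` must be given —
    there is no silent default sampling interval.
    """
    lines = Path(path).read_text().splitlines()
    frames: list[MolecularGeometry] = []
    vels: list[np.ndarray] = []
    have_vel: bool | None = None
    pos = 0
    frame_idx = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            natoms = int(lines[pos].strip())
        except ValueError as exc:
            raise XYZParseError(
                f"frame {frame_idx}: malformed atom-count header {lines[pos]!r}"
            ) from exc
        if natoms <= 0:
            raise XYZParseError(f"frame {frame_idx}: non-positive atom count")
        comment = lines[pos + 1] if pos + 1 < len(lines) else ""
        m = _TIME_RE.search(comment)
        frame_time = float(m.group(1)) if m else None
        vel_au = "vel_units=au" in comment
        elements: list[str] = []
        coords = np.empty((natoms, 3))
        vel = np.empty((natoms, 3))
        for a in range(natoms):
            lineno = pos + 2 + a
            if lineno >= len(lines):
                raise XYZParseError(
                    f"frame {frame_idx}: declared {natoms} atoms but file ends early"
                )
            parts = lines[lineno].split()
            if len(parts) not in (4, 7):
                raise XYZParseError(
                    f"frame {frame_idx}, atom {a + 1}: expected 4 or 7 columns, "
                    f"got {len(parts)}"
                )
            try:
                coords[a] = [float(x) for x in parts[1:4]]
                if len(parts) == 7:
                    vel[a] = [float(x) for x in parts[4:7]]
            except ValueError as exc:
                raise XYZParseError(
                    f"frame {frame_idx}, atom {a + 1}: non-numeric field"
                ) from exc
            elements.append(parts[0])
        frame_has_vel = len(parts) == 7
        if have_vel is None:
            have_vel = frame_has_vel
        elif have_vel != frame_has_vel:
            raise XYZParseError("inconsistent velocity columns across frames")
        frames.append(
            MolecularGeometry(tuple(elements), coords, frame_time=frame_time)
        )
        if frame_has_vel:
            vels.append(vel * (AU_VELOCITY_IN_ANG_PER_FS if vel_au else 1.0))
        pos += 2 + natoms
        frame_idx += 1
    if not frames:
        raise XYZParseError("empty XYZ file")
    n0 = frames[0].n_atoms
    for k, fr in enumerate(frames):
        if fr.n_atoms != n0:
            raise XYZParseError(f"frame {k}: atom count {fr.n_atoms} != {n0}")
    if dt is None:
        ts = [fr.frame_time for fr in frames]
        if len(frames) == 1:
            dt = 1.0  # nominal; irrelevant for a static structure
        elif all(t is not None for t in ts):
            dt = float(ts[1] - ts[0])
        else:
            raise ValueError(
                "multi-frame XYZ without time metadata: dt must be supplied"
            )
    velocities = np.stack(vels) if have_vel else None
    return Trajectory(frames=frames, dt=dt, velocities=velocities)


def write_xyz(traj: Trajectory, path: str | Path) -> Path:
    """Write a Trajectory as standard multi-frame XYZ (6-decimal fixed).

    Velocities, when present, are appended as columns 5–7 in Å/fs.
    """
    if not isinstance(traj, Trajectory) or traj.n_frames == 0:
        raise ValueError("cannot write an empty trajectory")
    path = Path(path)
    out: list[str] = []
    times = traj.times
    for k, fr in enumerate(traj.frames):
        out.append(str(fr.n_atoms))
        out.append(f"t= {times[k]:.6f} fs")
        for a in range(fr.n_atoms):
            row = f"{fr.elements[a]:<2s} " + " ".join(
                f"{x:14.6f}" for x in fr.coords[a]
            )
            if traj.velocities is not None:
                row += " " + " ".join(f"{v:14.6f}" for v in traj.velocities[k, a])
            out.append(row)
    path.write_text("\n".join(out) + "\n")
    return path


# ---------------------------------------------------------------------------
# Compound configuration (rings + bridges)
# ---------------------------------------------------------------------------


def load_compound_config(
    path: str | Path,
) -> tuple[str, dict[str, RingDefinition], dict[str, BridgeSpec]]:
    """Load a YAML compound config: label, ring definitions, bridge specs.

    Expected layout::

        compound: 3a
        rings:
          I: [1, 2, 3, 4, 10, 9]
          II: [10, 5, 6, 7, 8, 9]
        bridges:
          O1-H1-O3: {donor: 11, proton: 15, acceptor: 13}
    """
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError("config must be a mapping")
    compound = str(data.get("compound", ""))
    rings = {
        str(lbl): RingDefinition(label=str(lbl), atoms=tuple(atoms))
        for lbl, atoms in (data.get("rings") or {}).items()
    }
    bridges = {}
    for lbl, spec in (data.get("bridges") or {}).items():
        bridges[str(lbl)] = BridgeSpec(
            donor=int(spec["donor"]),
            proton=int(spec["proton"]),
            acceptor=int(spec["acceptor"]),
            label=str(lbl),
        )
    return compound, rings, bridges
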