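"""Synthetic coupled-bridge trajectories, PT profiles and charge tables.

No public trajectories exist for the doubly hydrogen-bridged
naphthoquinones, so every trajectory-consuming analysis is validated
against a generator with analytically known ground truth.

The trajectory model is Markov-switching plus deterministic oscillation:
the joint proton configuration of the twin bridges evolves as a 4-state
continuous-time Markov chain over {DD, DA, AD, AA} (D = proton on the
donor oxygen, A = transferred).  Each bridge has forward/backward hopping
rates, and a single coupling knob gamma >= 1 multiplies the rate of any
transition that creates a concordant joint state (DD or AA) and divides
the rate of any transition that creates a discordant one — gamma -> inf
locks the protons together, reproducing the heavily correlated transfer
dynamics such compounds display.  On top of the current-holder side each
proton carries a deterministic O–H stretching oscillation (default
2750 cm^-1, amplitude 0.05 Å) plus optional Gaussian jitter; velocities
are emitted analytically.  Stationary possession fractions and the
concordance probability are computed from the generator matrix, not
simulated, and returned as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import null_space

from .charges import ChargeTable, SubstituentGroup
from .geometry import BridgeSpec, MolecularGeometry, Trajectory
from .ptprofile import PTProfile
from .spectra import SPEED_OF_LIGHT_CM_PER_FS

__all__ = [
    "CoupledBridgeModel",
    "GroundTruth",
    "generate_bridge_trajectory",
    "generate_pt_profile",
    "generate_charge_table",
]

# joint states of (bridge1, bridge2); D = donor side, A = acceptor side
_STATES = ("DD", "DA", "AD", "AA")
_CONCORDANT = {0, 3}


@dataclass(frozen=True)
class CoupledBridgeModel:
    """Parameters of the twin-bridge generator.

    Geometry mirrors the DFT bridges of this family (O...O ~2.585 Å,
    equilibrium O–H ~1.0 Å); the sampling stride and duration mirror
    typical Car–Parrinello production settings (1.452 fs stride, ~25 ps).
    Rates are in ps^-1; ``nu_OH`` may be a single wavenumber or one per
    bridge.
    """

    R_OO: float = 2.585  # Å
    d_eq: float = 1.00  # Å
    k_fwd: float = 0.8  # ps^-1, D -> A per bridge
    k_rev: float = 1.6  # ps^-1, A -> D per bridge
    coupling: float = 1.0  # gamma >= 1
    nu_OH: float | tuple[float, float] = 2750.0  # cm^-1
    amplitude: float = 0.05  # Å
    noise_sigma: float = 0.0  # Å, positional jitter on the protons
    dt: float = 1.452  # fs
    duration: float = 25.0  # ps
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_fwd <= 0 or self.k_rev <= 0:
            raise ValueError("hopping rates must be positive")
        if self.coupling < 1.0:
            raise ValueError("coupling gamma must be >= 1")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not 0 < self.d_eq < self.R_OO:
            raise ValueError("need 0 < d_eq < R_OO")

    @property
    def nu_pair(self) -> tuple[float, float]:
        if isinstance(self.nu_OH, (tuple, list)):
            return float(self.nu_OH[0]), float(self.nu_OH[1])
        return float(self.nu_OH), float(self.nu_OH)

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * 1000.0 / self.dt))

    def bridge_specs(self) -> tuple[BridgeSpec, BridgeSpec]:
        """Atom numbering of the generated frames (1-based)."""
        return (
            BridgeSpec(donor=1, proton=3, acceptor=2, label="O1-H1-O3"),
            BridgeSpec(donor=4, proton=6, acceptor=5, label="O2-H2-O4"),
        )

    def generator_matrix(self) -> np.ndarray:
        """4x4 CTMC generator over (DD, DA, AD, AA), rates in ps^-1."""
        g = self.coupling
        Q = np.zeros((4, 4))
        for s in range(4):
            b1, b2 = s >> 1, s & 1  # 0 = D, 1 = A
            for bridge, occ in ((0, b1), (1, b2)):
                target = s ^ (2 if bridge == 0 else 1)
                base = self.k_fwd if occ == 0 else self.k_rev
                rate = base * (g if target in _CONCORDANT else 1.0 / g)
                Q[s, target] = rate
            Q[s, s] = -Q[s].sum()
        return Q

    def stationary_distribution(self) -> np.ndarray:
        """Stationary probabilities of (DD, DA, AD, AA)."""
        ns = null_space(self.generator_matrix().T)
        pi = np.abs(ns[:, 0])
        return pi / pi.sum()


@dataclass(frozen=True)
class GroundTruth:
    """Analytic properties of a generated trajectory (not simulated)."""

    donor_fraction: tuple[float, float]  # stationary, per bridge
    concordance: float  # P(both protons on the same side)
    nu_OH: tuple[float, float]  # injected wavenumbers, cm^-1


def _simulate_ctmc(
    Q: np.ndarray, pi: np.ndarray, t_end_ps: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Gillespie simulation; returns jump times (ps) and the state after
    each jump, with the initial state drawn from the stationary law."""
    times = [0.0]
    states = [int(rng.choice(4, p=pi))]
    t = 0.0
    s = states[0]
    while True:
        rate = -Q[s, s]
        t += rng.exponential(1.0 / rate)
        if t >= t_end_ps:
            break
        probs = Q[s].clip(min=0.0)
        probs = probs / probs.sum()
        s = int(rng.choice(4, p=probs))
        times.append(t)
        states.append(s)
    return np.asarray(times), np.asarray(states)


def generate_bridge_trajectory(
    model: CoupledBridgeModel,
) -> tuple[Trajectory, GroundTruth]:
    """Generate a twin-bridge trajectory with velocities and ground truth.

    Atoms per frame: O1, O3, H1 (bridge 1) and O2, O4, H2 (bridge 2);
    the two bridges sit on parallel axes 8 Å apart, oxygens fixed.
    Deterministic for a fixed ``model.seed``.
    """
    n = model.n_frames
    if n < 100:
        raise ValueError("duration too short: need at least 100 frames")
    rng = np.random.default_rng(model.seed)
    Q = model.generator_matrix()
    pi = model.stationary_distribution()
    jump_t, jump_s = _simulate_ctmc(Q, pi, model.duration, rng)

    t_fs = np.arange(n) * model.dt
    t_ps = t_fs / 1000.0
    idx = np.searchsorted(jump_t, t_ps, side="right") - 1
    state = jump_s[idx]
    side = np.stack([(state >> 1) & 1, state & 1], axis=1)  # 0 = D, 1 = A

    nu = model.nu_pair
    offsets = (0.0, 8.0)  # y-offset of each bridge axis, Å
    positions = np.zeros((n, 6, 3))
    velocities = np.zeros((n, 6, 3))
    elements = ("O", "O", "H", "O", "O", "H")
    for b in (0, 1):
        o_donor = np.array([0.0, offsets[b], 0.0])
        o_acc = np.array([model.R_OO, offsets[b], 0.0])
        io, ia, ih = 3 * b, 3 * b + 1, 3 * b + 2
        positions[:, io] = o_donor
        positions[:, ia] = o_acc
        omega = 2.0 * np.pi * SPEED_OF_LIGHT_CM_PER_FS * nu[b]  # rad/fs
        phase = rng.uniform(0.0, 2.0 * np.pi)
        osc = model.amplitude * np.cos(omega * t_fs + phase)
        dosc = -model.amplitude * omega * np.sin(omega * t_fs + phase)
        on_acceptor = side[:, b] == 1
        x = np.where(on_acceptor, model.R_OO - model.d_eq - osc, model.d_eq + osc)
        vx = np.where(on_acceptor, -dosc, dosc)
        if model.noise_sigma > 0:
            x = x + rng.normal(0.0, model.noise_sigma, size=n)
            vx = vx + rng.normal(0.0, model.noise_sigma * omega, size=n)
        positions[:, ih, 0] = x
        positions[:, ih, 1] = offsets[b]
        velocities[:, ih, 0] = vx

    frames = [
        MolecularGeometry(elements, positions[k], frame_time=float(t_fs[k]))
        for k in range(n)
    ]
    traj = Trajectory(frames=frames, dt=model.dt, velocities=velocities)
    truth = GroundTruth(
        donor_fraction=(float(pi[0] + pi[1]), float(pi[0] + pi[2])),
        concordance=float(pi[0] + pi[3]),
        nu_OH=nu,
    )
    return traj, truth


def generate_pt_profile(
    barrier: float,
    asymmetry: float = 0.0,
    increment: float = 0.05,
    r_min1: float = 1.00,
    half_width: float = 0.30,
    compound: str = "",
) -> PTProfile:
    """Analytic double-well PT profile sampled on the scan grid.

    The well is a C1 piecewise quartic: the left half rises from 0 at
    ``r_min1`` to ``barrier`` at the midpoint, the right half descends to
    ``asymmetry`` at the second well.  With ``half_width`` and the well
    positions commensurate with ``increment`` the grid extrema equal the
    analytic barrier and second-minimum energies exactly.
    """
    if barrier <= 0:
        raise ValueError("barrier must be positive")
    if increment <= 0:
        raise ValueError("increment must be positive")
    if asymmetry < 0:
        raise ValueError("asymmetry must be >= 0")
    if asymmetry >= barrier:
        raise ValueError("asymmetry >= barrier: the second minimum vanishes")
    w = half_width
    r_bar = r_min1 + w
    n_lo = int(round(w / increment)) + 6  # margin beyond each well
    r = r_bar + increment * np.arange(-n_lo, n_lo + 1)
    x = r - r_bar
    quartic = ((x**2 - w**2) ** 2) / w**4
    E = np.where(x <= 0, barrier * quartic, asymmetry + (barrier - asymmetry) * quartic)
    return PTProfile(r=tuple(r), E=tuple(E), compound=compound, bridge="synthetic")


def generate_charge_table(
    n_atoms: int,
    substitutions: dict[str, tuple[int, dict[int, float]]],
    seed: int = 0,
    noise_sigma: float = 0.0,
    ipso_charge: float = 0.0,
) -> tuple[ChargeTable, dict[str, float]]:
    """Charge table with injected substituent charges and known cSAR.

    ``substitutions`` maps a position label to ``(ipso_index, {atom:
    charge})``; every other atom gets a baseline charge of 0 plus
    N(0, noise_sigma) jitter.  ``ipso_charge`` is added to each ipso
    carbon.  Returns the table and the exact expected cSAR per position
    (noise excluded — it is the recovery target, not part of the truth).
    """
    rng = np.random.default_rng(seed)
    charges = dict(
        zip(range(1, n_atoms + 1), rng.normal(0.0, noise_sigma, n_atoms))
        if noise_sigma > 0
        else zip(range(1, n_atoms + 1), np.zeros(n_atoms))
    )
    element = {i: "C" for i in charges}
    seen: set[int] = set()
    expected: dict[str, float] = {}
    for pos, (ipso, atom_charges) in substitutions.items():
        atoms = set(atom_charges)
        if atoms & seen:
            raise ValueError(f"position {pos}: substituent atoms overlap")
        seen |= atoms
        for a, q in atom_charges.items():
            if not 1 <= a <= n_atoms:
                raise ValueError(f"position {pos}: atom {a} out of range")
            charges[a] += q
            element[a] = "X"
        charges[ipso] += ipso_charge
        element[ipso] = "C"
        expected[pos] = ipso_charge + sum(atom_charges.values())
    table = ChargeTable(
        charges=charges, element=element, compound="synthetic", scheme="synthetic"
    )
    return table, expected
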