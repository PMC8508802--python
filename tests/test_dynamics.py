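"""Bridge dynamics: possession, event detection, synchrony."""

import numpy as np
import pytest

from nqbridge.dynamics import (
    BridgeSeries,
    PTEventList,
    bridge_synchrony,
    detect_pt_events,
    extract_bridge_series,
    possession,
    possession_report,
)
from nqbridge.geometry import BridgeSpec, MolecularGeometry, Trajectory
from nqbridge.synthetic import CoupledBridgeModel, generate_bridge_trajectory


def series(delta, dt=1.0):
    """BridgeSeries with the requested signed asymmetry around d_OO=2.6."""
    delta = np.asarray(delta, dtype=float)
    d1 = 1.3 + delta / 2
    d2 = 1.3 - delta / 2
    return BridgeSeries(t=dt * np.arange(len(delta)), d_donor_H=d1, d_H_acceptor=d2)


def static_traj(d_oh=1.0, d_ho=1.6, n=10):
    coords = np.array([[0, 0, 0], [d_oh, 0, 0], [d_oh + d_ho, 0, 0]])
    frames = [
        MolecularGeometry(("O", "H", "O"), coords, frame_time=float(k))
        for k in range(n)
    ]
    return Trajectory(frames=frames, dt=1.0)


BRIDGE = BridgeSpec(donor=1, proton=2, acceptor=3, label="O1-H1-O3")


class TestExtractSeries:
    def test_static_constant_series(self):
        s = extract_bridge_series(static_traj(), BRIDGE)
        np.testing.assert_allclose(s.d_donor_H, 1.0)
        np.testing.assert_allclose(s.d_H_acceptor, 1.6)
        assert len(s.t) == 10

    def test_equilibration_drops_frames(self):
        traj = static_traj(n=10)
        traj.equilibration_time = 5.0
        s = extract_bridge_series(traj, BRIDGE)
        assert len(s.t) == 5

    def test_full_equilibration_rejected(self):
        traj = static_traj(n=10)
        with pytest.raises(ValueError):
            traj.equilibration_time = 100.0
            traj.__post_init__()

    def test_matches_generator_construction(self):
        """Series agrees with the generator's piecewise proton placement."""
        m = CoupledBridgeModel(duration=1.0, seed=5, amplitude=0.0)
        traj, _ = generate_bridge_trajectory(m)
        b1 = m.bridge_specs()[0]
        s = extract_bridge_series(traj, b1)
        on_donor = s.d_donor_H <= s.d_H_acceptor
        np.testing.assert_allclose(
            np.where(on_donor, s.d_donor_H, s.d_H_acceptor), m.d_eq, atol=1e-9
        )
        np.testing.assert_allclose(s.d_donor_H + s.d_H_acceptor, m.R_OO, atol=1e-9)


class TestPossession:
    def test_always_donor(self):
        p = possession(series(-0.5 * np.ones(100)))
        assert p.donor_fraction == 1.0

    def test_tie_goes_to_donor(self):
        p = possession(series(np.zeros(50)))
        assert p.donor_fraction == 1.0

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(0)
        p = possession(series(rng.normal(size=1000)))
        assert p.donor_fraction + p.acceptor_fraction == 1.0

    def test_complementarity_swap(self):
        """Donor/acceptor swap maps possession p to exactly 1 - p."""
        rng = np.random.default_rng(1)
        delta = rng.normal(size=2000)
        s = series(delta)
        swapped = BridgeSeries(
            t=s.t, d_donor_H=s.d_H_acceptor, d_H_acceptor=s.d_donor_H
        )
        p = possession(s).donor_fraction
        q = possession(swapped).donor_fraction
        assert p + q == pytest.approx(1.0, abs=0.0)

    def test_markov_stationary_recovery(self):
        """Long two-state trajectory recovers the analytic 0.75 donor
        fraction within 3 binomial-style SEs of the sojourn count."""
        m = CoupledBridgeModel(
            k_fwd=1.0, k_rev=3.0, coupling=1.0, duration=25.0, seed=11
        )
        traj, gt = generate_bridge_trajectory(m)
        assert gt.donor_fraction[0] == pytest.approx(0.75)
        b1 = m.bridge_specs()[0]
        s = extract_bridge_series(traj, b1)
        p = possession(s).donor_fraction
        n_sojourn = len(detect_pt_events(s)) + 1
        se = np.sqrt(0.75 * 0.25 / n_sojourn)
        assert abs(p - 0.75) <= 3 * se


class TestDetectEvents:
    def test_single_crossing(self):
        ev = detect_pt_events(series(np.linspace(-0.5, 0.5, 50)))
        assert len(ev) == 1
        assert ev.directions == ("donor->acceptor",)

    def test_no_crossing(self):
        assert len(detect_pt_events(series(-0.4 * np.ones(20)))) == 0

    def test_chatter_within_hysteresis_ignored(self):
        """Rapid small-amplitude sign flips never count as events."""
        chatter = np.tile([-0.02, 0.02], 50)
        assert len(detect_pt_events(series(chatter), hysteresis=0.05)) == 0

    def test_chatter_then_commit(self):
        """Chatter followed by a real transfer yields exactly one event."""
        delta = np.concatenate([np.tile([-0.02, 0.02], 20), np.full(20, 0.4)])
        ev = detect_pt_events(series(delta), hysteresis=0.05)
        assert len(ev) == 1

    def test_directions_alternate(self):
        m = CoupledBridgeModel(duration=25.0, seed=3)
        traj, _ = generate_bridge_trajectory(m)
        ev = detect_pt_events(extract_bridge_series(traj, m.bridge_specs()[0]))
        assert len(ev) > 2
        for a, b in zip(ev.directions, ev.directions[1:]):
            assert a != b
        assert all(t2 > t1 for t1, t2 in zip(ev.times, ev.times[1:]))

    def test_zero_hysteresis_matches_framewise_possession(self):
        """Event-segment decomposition reproduces frame-wise possession."""
        rng = np.random.default_rng(2)
        delta = np.cumsum(rng.normal(0, 0.2, 500))
        s = series(delta)
        ev = detect_pt_events(s, hysteresis=0.0)
        # reconstruct per-frame side from alternating events
        side = np.empty(len(delta), dtype=int)  # +1 donor, -1 acceptor
        current = 1 if delta[0] <= 0 else -1
        times = list(ev.times) + [np.inf]
        j = 0
        for k, t in enumerate(s.t):
            while t >= times[j]:
                current = -current
                j += 1
            side[k] = current
        assert np.mean(side == 1) == possession(s).donor_fraction


class TestSynchrony:
    def test_identical_trains(self):
        ev = PTEventList(times=(10.0, 50.0, 90.0),
                         directions=("donor->acceptor", "acceptor->donor",
                                     "donor->acceptor"))
        s = bridge_synchrony(ev, ev)
        assert s.match_fraction == 1.0
        assert s.delays == (0.0, 0.0, 0.0)
        assert s.max_delay == 0.0

    def test_constant_shift(self):
        t1 = (100.0, 600.0, 1500.0)
        dirs = ("donor->acceptor", "acceptor->donor", "donor->acceptor")
        e1 = PTEventList(times=t1, directions=dirs)
        e2 = PTEventList(times=tuple(t + 30.0 for t in t1), directions=dirs)
        s = bridge_synchrony(e1, e2, window=500.0)
        assert s.match_fraction == 1.0
        assert all(d == pytest.approx(30.0) for d in s.delays)

    def test_disjoint_trains(self):
        e1 = PTEventList(times=(0.0,), directions=("donor->acceptor",))
        e2 = PTEventList(times=(10000.0,), directions=("donor->acceptor",))
        assert bridge_synchrony(e1, e2, window=500.0).match_fraction == 0.0

    def test_empty_trains_vacuous(self):
        e = PTEventList(times=(), directions=())
        assert bridge_synchrony(e, e).match_fraction == 1.0


class TestPossessionReport:
    def test_symmetric_compound_near_equal(self):
        """Equal-rate strongly coupled bridges give near-equal donor
        percentages, the pattern of symmetric twin-bridge compounds."""
        m = CoupledBridgeModel(coupling=10.0, duration=25.0, seed=4)
        traj, _ = generate_bridge_trajectory(m)
        rep = possession_report(traj, m.bridge_specs())
        assert len(rep) == 2
        diff = abs(rep.donor_percent.iloc[0] - rep.donor_percent.iloc[1])
        assert diff <= 12.0  # within sojourn-count sampling error

    def test_extreme_bias_limits(self):
        strong_acceptor = CoupledBridgeModel(
            k_fwd=50.0, k_rev=0.05, duration=5.0, seed=6
        )
        traj, _ = generate_bridge_trajectory(strong_acceptor)
        rep = possession_report(traj, strong_acceptor.bridge_specs())
        assert (rep.donor_percent < 5.0).all()
        strong_donor = CoupledBridgeModel(
            k_fwd=0.05, k_rev=50.0, duration=5.0, seed=6
        )
        traj, _ = generate_bridge_trajectory(strong_donor)
        rep = possession_report(traj, strong_donor.bridge_specs())
        assert (rep.donor_percent > 95.0).all()
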