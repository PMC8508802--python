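"""Velocity power spectra: peak recovery, Parseval, barycenters."""

import numpy as np
import pytest

from nqbridge.geometry import MolecularGeometry, Trajectory
from nqbridge.spectra import (
    SPEED_OF_LIGHT_CM_PER_FS,
    PowerSpectrum,
    barycenter,
    compare_bridges,
    finite_difference_velocities,
    nyquist_wavenumber,
    power_spectrum,
)
from nqbridge.synthetic import CoupledBridgeModel, generate_bridge_trajectory

DT = 1.452  # fs


def tone_trajectory(wavenumbers, n_frames=16384, amplitude=0.05, dt=DT):
    """Single-H trajectory whose velocity is a sum of pure cosines."""
    t = dt * np.arange(n_frames)
    v = np.zeros(n_frames)
    for nu in wavenumbers:
        omega = 2 * np.pi * SPEED_OF_LIGHT_CM_PER_FS * nu
        v += amplitude * omega * np.cos(omega * t)
    coords = np.zeros((1, 3))
    frames = [
        MolecularGeometry(("H",), coords, frame_time=float(tk)) for tk in t
    ]
    velocities = np.zeros((n_frames, 1, 3))
    velocities[:, 0, 0] = v
    return Trajectory(frames=frames, dt=dt, velocities=velocities)


class TestPowerSpectrum:
    def test_pure_tone_peak_position(self):
        """A 3000 cm^-1 cosine peaks within one bin of 3000 cm^-1."""
        traj = tone_trajectory([3000.0])
        spec = power_spectrum(traj, [1])
        peak = spec.wavenumber[np.argmax(spec.intensity)]
        assert abs(peak - 3000.0) <= spec.resolution

    def test_zero_velocities_zero_spectrum(self):
        traj = tone_trajectory([3000.0])
        traj.velocities[:] = 0.0
        spec = power_spectrum(traj, [1])
        assert np.all(spec.intensity == 0.0)

    def test_two_tones_equal_integrated_intensity(self):
        """Equal-amplitude velocity tones carry equal band power (within
        5%, Parseval on the analytic signal)."""
        traj = tone_trajectory([2600.0, 3000.0], n_frames=16384)
        # equal *velocity* amplitude: scale position amplitudes per tone
        t = DT * np.arange(16384)
        v = np.zeros(16384)
        for nu in (2600.0, 3000.0):
            omega = 2 * np.pi * SPEED_OF_LIGHT_CM_PER_FS * nu
            v += 0.01 * np.cos(omega * t)
        traj.velocities[:, 0, 0] = v
        spec = power_spectrum(traj, [1])
        band1 = spec.intensity[(spec.wavenumber > 2400) & (spec.wavenumber < 2800)]
        band2 = spec.intensity[(spec.wavenumber > 2800) & (spec.wavenumber < 3200)]
        assert band1.sum() == pytest.approx(band2.sum(), rel=0.05)

    def test_parseval(self):
        """Integrated one-sided density equals the mean squared velocity."""
        m = CoupledBridgeModel(duration=25.0, seed=9, noise_sigma=0.01)
        traj, _ = generate_bridge_trajectory(m)
        spec = power_spectrum(traj, [3])
        msv = float((traj.velocities[:, 2, :] ** 2).sum(axis=1).mean())
        integral = float(spec.intensity.sum() * spec.resolution)
        assert integral == pytest.approx(msv, rel=0.02)

    def test_nyquist_guard(self):
        traj = tone_trajectory([3000.0], n_frames=2048)
        spec = power_spectrum(traj, [1])
        limit = nyquist_wavenumber(DT)
        assert limit == pytest.approx(11486.0, rel=1e-3)
        assert spec.wavenumber.max() <= limit + 1e-9

    def test_missing_velocities_rejected(self):
        traj = tone_trajectory([2800.0], n_frames=2048)
        bare = Trajectory(frames=traj.frames, dt=traj.dt)
        with pytest.raises(ValueError, match="velocities"):
            power_spectrum(bare, [1])

    def test_short_trajectory_rejected(self):
        traj = tone_trajectory([2800.0], n_frames=512)
        with pytest.raises(ValueError, match="frames"):
            power_spectrum(traj, [1])

    def test_finite_difference_route(self):
        """Position-only trajectory recovers the tone via central
        differences (behind the explicit flag)."""
        nu = 2750.0
        n = 8192
        t = DT * np.arange(n)
        omega = 2 * np.pi * SPEED_OF_LIGHT_CM_PER_FS * nu
        x = 0.05 * np.cos(omega * t)
        frames = [
            MolecularGeometry(
                ("H",), np.array([[xi, 0.0, 0.0]]), frame_time=float(tk)
            )
            for xi, tk in zip(x, t)
        ]
        traj = Trajectory(frames=frames, dt=DT)
        spec = power_spectrum(traj, [1], use_finite_difference=True)
        peak = spec.wavenumber[np.argmax(spec.intensity)]
        assert abs(peak - nu) <= spec.resolution
        v = finite_difference_velocities(traj)
        assert v.shape == (n, 1, 3)


class TestBarycenter:
    def spectrum(self, wavenumbers, intensities):
        w = np.asarray(wavenumbers, dtype=float)
        return PowerSpectrum(
            wavenumber=w,
            intensity=np.asarray(intensities, dtype=float),
            resolution=float(w[1] - w[0]),
        )

    def test_single_bin(self):
        w = np.arange(0, 4000, 100.0)
        s = np.zeros_like(w)
        s[w == 2700.0] = 5.0
        assert barycenter(self.spectrum(w, s), (2000, 3400)).barycenter == 2700.0

    def test_two_equal_bins_midpoint(self):
        w = np.arange(0, 4000, 100.0)
        s = np.zeros_like(w)
        s[w == 2600.0] = 1.0
        s[w == 2800.0] = 1.0
        assert barycenter(self.spectrum(w, s), (2000, 3400)).barycenter == 2700.0

    def test_weighted_two_to_one(self):
        w = np.arange(0, 4000, 100.0)
        s = np.zeros_like(w)
        s[w == 2600.0] = 2.0
        s[w == 2900.0] = 1.0
        bc = barycenter(self.spectrum(w, s), (2000, 3400)).barycenter
        assert bc == pytest.approx((2 * 2600 + 2900) / 3)

    def test_scale_invariance_and_shift(self):
        w = np.arange(0, 4000, 50.0)
        rng = np.random.default_rng(0)
        s = np.zeros_like(w)
        band = (w > 2300) & (w < 3300)
        s[band] = rng.uniform(0.1, 1.0, band.sum())
        b0 = barycenter(self.spectrum(w, s), (2200, 3400)).barycenter
        b_scaled = barycenter(self.spectrum(w, 7.3 * s), (2200, 3400)).barycenter
        assert b_scaled == pytest.approx(b0, abs=1e-9)
        # translating the whole band by +200 shifts the barycenter by +200
        s2 = np.zeros_like(w)
        s2[4:] = s[:-4]
        b_shift = barycenter(self.spectrum(w, s2), (2400, 3600)).barycenter
        assert b_shift == pytest.approx(b0 + 200.0, abs=1e-9)

    def test_zero_intensity_window_rejected(self):
        w = np.arange(0, 4000, 100.0)
        with pytest.raises(ValueError):
            barycenter(self.spectrum(w, np.zeros_like(w)), (2200, 3400))

    def test_disjoint_window_rejected(self):
        w = np.arange(0, 4000, 100.0)
        with pytest.raises(ValueError):
            barycenter(self.spectrum(w, np.ones_like(w)), (9000, 9100))


class TestCompareBridges:
    def test_injected_frequency_split(self):
        """Lowering bridge-2 frequency by 50 cm^-1 shows up as a ~50 cm^-1
        barycenter split (within one bin width)."""
        m = CoupledBridgeModel(
            nu_OH=(2750.0, 2700.0), duration=25.0, seed=12, coupling=10.0
        )
        traj, _ = generate_bridge_trajectory(m)
        summaries, split = compare_bridges(traj, m.bridge_specs())
        res = 1.0 / (4096 * m.dt * SPEED_OF_LIGHT_CM_PER_FS)
        assert split == pytest.approx(50.0, abs=res)

    def test_identical_series_zero_split(self):
        m = CoupledBridgeModel(duration=25.0, seed=13)
        traj, _ = generate_bridge_trajectory(m)
        b1 = m.bridge_specs()[0]
        _, split = compare_bridges(traj, [b1, b1])
        assert split == 0.0

    def test_symmetric_bridges_small_split(self):
        """Equivalent bridges: split stays within the few-bin convergence
        noise floor seen across repeated seeds."""
        splits = []
        for seed in range(5):
            m = CoupledBridgeModel(duration=25.0, seed=seed, coupling=10.0)
            traj, _ = generate_bridge_trajectory(m)
            _, split = compare_bridges(traj, m.bridge_specs())
            splits.append(split)
        assert np.median(splits) <= 3 * 5.7  # a few bin widths
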