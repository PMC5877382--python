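"""Time synchronization and rigid alignment.

Lag estimation is validated on constructed integer and fractional-sample
shifts (ideal resampling oracle); the Kabsch alignment against exact
constructions and a brute-force quaternion grid search minimizing the
same RMSD.
"""

import numpy as np
import pytest
from scipy import signal as sps

from equigait import quat as Q
from equigait import sync
from equigait.signals import AngVelSignal, QuatSignal, TimeSeries

FS = 200.0


def bandlimited(rng, n=8000, cutoff=10.0):
    sos = sps.butter(4, cutoff, fs=FS, output="sos")
    return sps.sosfiltfilt(sos, rng.normal(size=n))


class TestAngvelMagnitude:
    def test_values(self):
        om = AngVelSignal(np.array([[0.0, 0, 0], [3, 4, 0], [1, 2, 2]]), FS)
        np.testing.assert_allclose(sync.angvel_magnitude(om).data, [0, 5, 3])

    def test_rotation_invariance(self, rng):
        om = rng.normal(size=(500, 3)) * 30
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        rotated = Q.rotate_vector(q, om)
        m1 = sync.angvel_magnitude(AngVelSignal(om, FS)).data
        m2 = sync.angvel_magnitude(AngVelSignal(rotated, FS)).data
        np.testing.assert_allclose(m1, m2, atol=1e-9)

    def test_gap_mask_propagated(self, rng):
        mask = np.zeros(100, dtype=bool)
        mask[10:20] = True
        om = AngVelSignal(rng.normal(size=(100, 3)), FS, gap_mask=mask)
        assert (sync.angvel_magnitude(om).gap_mask == mask).all()


class TestEstimateLag:
    def test_identical_signals(self, rng):
        x = TimeSeries(bandlimited(rng), FS)
        res = sync.estimate_lag(x, x, max_lag=1.0)
        assert res.lag == pytest.approx(0.0, abs=1e-6)
        assert res.peak_corr == pytest.approx(1.0, abs=1e-9)

    def test_integer_shift(self, rng):
        x = bandlimited(rng)
        b = np.roll(x, 25)[500:-500]
        res = sync.estimate_lag(TimeSeries(x[500:-500], FS),
                                TimeSeries(b, FS), max_lag=1.0)
        assert res.lag == pytest.approx(25 / FS, abs=2e-4)

    def test_fractional_shift_submillisecond(self, rng):
        x = bandlimited(rng, n=12000)
        y = sync.fractional_delay(x, 12.3)
        sigma = np.std(x) * 10 ** (-20 / 20)  # SNR 20 dB
        a = x[500:-500] + rng.normal(0, sigma, 11000)
        b = y[500:-500] + rng.normal(0, sigma, 11000)
        res = sync.estimate_lag(TimeSeries(a, FS), TimeSeries(b, FS), max_lag=0.5)
        assert abs(res.lag - 12.3 / FS) < 1e-3

    def test_antisymmetry(self, rng):
        x = bandlimited(rng, n=12000)
        y = sync.fractional_delay(x, 7.4)[500:-500]
        a = TimeSeries(x[500:-500], FS)
        b = TimeSeries(y, FS)
        l1 = sync.estimate_lag(a, b, max_lag=0.5).lag
        l2 = sync.estimate_lag(b, a, max_lag=0.5).lag
        assert abs(l1 + l2) < 1.0 / FS

    def test_start_time_offset_folded_in(self, rng):
        x = bandlimited(rng)
        a = TimeSeries(x, FS, start_time=0.0)
        b = TimeSeries(x, FS, start_time=2.0)
        res = sync.estimate_lag(a, b, max_lag=1.0)
        assert res.lag == pytest.approx(2.0, abs=1e-6)

    def test_low_correlation_warns(self, rng):
        a = TimeSeries(rng.normal(size=4000), FS)
        b = TimeSeries(rng.normal(size=4000), FS)
        with pytest.warns(UserWarning):
            sync.estimate_lag(a, b, max_lag=0.2)

    def test_mismatched_rates_raise(self, rng):
        with pytest.raises(ValueError):
            sync.estimate_lag(TimeSeries(np.ones(100), 200.0),
                              TimeSeries(np.ones(100), 100.0))


class TestResample:
    def test_zero_lag_identity(self, rng):
        sig = TimeSeries(bandlimited(rng), FS)
        out = sync.resample_to_lag(sig, 0.0)
        np.testing.assert_array_equal(out.data, sig.data)

    def test_integer_lag_pure_index_shift(self, rng):
        x = bandlimited(rng)
        out = sync.resample_to_lag(TimeSeries(x, FS), 25 / FS)
        assert np.array_equal(out.data[:-25], x[25:])
        assert out.gap_mask[-25:].all()

    def test_round_trip_bandlimited(self, rng):
        x = bandlimited(rng, n=8000)
        sig = TimeSeries(x, FS)
        once = sync.resample_to_lag(sig, 0.0123)
        back = sync.resample_to_lag(TimeSeries(once.data, FS), -0.0123)
        interior = slice(int(1.5 * FS), -int(1.5 * FS))
        err = np.abs(back.data[interior] - x[interior]).max()
        assert err < 1e-6 * np.ptp(x)

    def test_quaternion_slerp_stays_unit_and_accurate(self):
        t = np.arange(400) / FS
        angles = 0.5 * np.sin(2 * np.pi * 1.0 * t)
        quats = Q.from_axis_angle(np.array([0.0, 0.0, 1.0]), angles)
        qs = QuatSignal(quats, FS)
        out = sync.resample_to_lag(qs, 0.5 / FS)
        np.testing.assert_allclose(np.linalg.norm(out.quats, axis=1), 1.0, atol=1e-12)
        expected = 0.5 * np.sin(2 * np.pi * 1.0 * (t + 0.5 / FS))
        got = 2 * np.arctan2(out.quats[:, 3], out.quats[:, 0])
        valid = ~out.gap_mask
        assert np.abs(got[valid][:-1] - expected[valid][:-1]).max() < 1e-4

    def test_gap_propagation(self, rng):
        mask = np.zeros(2000, dtype=bool)
        mask[100:110] = True
        sig = TimeSeries(bandlimited(rng, n=2000), FS, gap_mask=mask)
        out = sync.resample_to_lag(sig, 1.7 / FS)
        assert out.gap_mask[98:108].any()


class TestVarianceExclusion:
    def test_identical_signals_nothing_excluded(self, rng):
        x = TimeSeries(bandlimited(rng, n=2000), FS)
        assert not sync.variance_exclusion_mask(x, x).any()

    def test_spike_excluded(self, rng):
        x = bandlimited(rng, n=2000) * 1e-4
        y = x.copy()
        y[1000:1003] += 50.0  # deg/s spike in one system only
        mask = sync.variance_exclusion_mask(TimeSeries(x, FS), TimeSeries(y, FS))
        assert mask[995:1008].sum() >= 10

    def test_tiny_equal_variance_noise_mostly_kept(self, rng):
        a = rng.normal(0, np.sqrt(1e-5), 5000)
        b = rng.normal(0, np.sqrt(1e-5), 5000)
        mask = sync.variance_exclusion_mask(TimeSeries(a, FS), TimeSeries(b, FS))
        assert mask.mean() < 0.05


class TestKabsch:
    def make_omegas(self, rng, n=2000):
        sos = sps.butter(4, 10, fs=FS, output="sos")
        return sps.sosfiltfilt(sos, rng.normal(size=(n, 3)), axis=0) * 50

    def test_identity_for_equal_signals(self, rng):
        om = self.make_omegas(rng)
        res = sync.kabsch_align(AngVelSignal(om, FS), AngVelSignal(om, FS))
        assert np.degrees(Q.geodesic_angle(res.rotation, Q.IDENTITY)) < 1e-6
        assert res.residual_rmsd < 1e-9

    def test_recovers_known_rotation_noiseless(self, rng):
        om = self.make_omegas(rng)
        axis = np.array([1.0, 2.0, 3.0]) / np.sqrt(14)
        q_true = Q.from_axis_angle(axis, np.radians(40))
        rotated = Q.rotate_vector(q_true, om)
        res = sync.kabsch_align(AngVelSignal(om, FS), AngVelSignal(rotated, FS))
        assert Q.geodesic_angle(res.rotation, q_true) < 1e-6

    def test_proper_rotation(self, rng):
        om = self.make_omegas(rng)
        noisy = Q.rotate_vector(Q.from_axis_angle(np.array([0, 0, 1.0]), 0.7), om)
        noisy = noisy + rng.normal(0, 2.0, size=noisy.shape)
        res = sync.kabsch_align(AngVelSignal(om, FS), AngVelSignal(noisy, FS))
        m = sync.quat_to_matrix(res.rotation)
        np.testing.assert_allclose(m @ m.T, np.eye(3), atol=1e-10)
        assert np.linalg.det(m) == pytest.approx(1.0, abs=1e-10)

    def test_grid_search_oracle_under_noise(self, rng):
        om = self.make_omegas(rng, n=1500)
        axis = np.array([0.3, -0.5, 0.81])
        axis /= np.linalg.norm(axis)
        q_true = Q.from_axis_angle(axis, np.radians(25))
        target = Q.rotate_vector(q_true, om) + rng.normal(0, 2.0, size=om.shape)
        res = sync.kabsch_align(AngVelSignal(om, FS), AngVelSignal(target, FS))

        def rmsd(qc):
            r = Q.rotate_vector(qc, om) - target
            return np.sqrt(np.mean(np.sum(r ** 2, axis=1)))

        # brute-force search over a quaternion grid around the truth
        best_q, best = None, np.inf
        for _ in range(4000):
            dq = Q.from_axis_angle(
                (lambda a: a / np.linalg.norm(a))(rng.normal(size=3)),
                rng.uniform(0, 0.15))
            qc = Q.multiply(dq, q_true)
            v = rmsd(qc)
            if v < best:
                best, best_q = v, qc
        assert Q.geodesic_angle(res.rotation, best_q) < 0.05
        assert rmsd(res.rotation) <= best + 1e-6

    def test_rank_deficient_raises(self):
        om = np.zeros((500, 3))
        om[:, 2] = np.linspace(0, 10, 500)  # all angular velocity along z
        with pytest.raises(ValueError, match="rank-deficient|coplanar"):
            sync.kabsch_align(AngVelSignal(om, FS), AngVelSignal(om, FS))

    def test_too_few_samples_raise(self, rng):
        om = self.make_omegas(rng, n=120)
        mask = np.ones(120, dtype=bool)
        mask[:50] = False
        with pytest.raises(ValueError, match="paired samples"):
            sync.kabsch_align(AngVelSignal(om, FS), AngVelSignal(om, FS), mask)


class TestEndToEnd:
    def test_simulated_lag_and_rotation_recovery(self, walk_noisy):
        trial = walk_noisy
        s = trial.sensor_config
        om_imu = trial.imu["RF"].gyro
        om_omc = Q.differentiate_quats(trial.omc["RF"].quats)
        res = sync.estimate_lag(sync.angvel_magnitude(om_imu),
                                sync.angvel_magnitude(om_omc), max_lag=0.5)
        assert abs(res.lag - s.lag) < 1e-3  # within 1 ms
        ts = sync.resample_to_lag(
            TimeSeries(om_omc.omega, FS, gap_mask=om_omc.gap_mask), res.lag)
        om_al = AngVelSignal(ts.data, FS, gap_mask=ts.gap_mask)
        align = sync.kabsch_align(om_imu, om_al)
        err_deg = np.degrees(Q.geodesic_angle(align.rotation, s.relative_rotation))
        assert err_deg < 1.0
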