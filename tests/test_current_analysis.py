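"""Displacement-sum current, slab counting, filtering, histograms, COM."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from porepass import (
    CurrentTrace,
    DipoleTrace,
    FilterSpec,
    IonTrajectory,
    com_track,
    count_pore_ions,
    current_histogram,
    dipole_conditioned_histograms,
    instantaneous_current,
    lowpass,
)
from porepass.synthetic import gen_ion_trajectory
from porepass.units import E_PER_PS_IN_NA


def _traj_from_z(z_per_frame, charges, lz=36.0, dt=1.0, box_z=None):
    """Build a trajectory from an (F, n) z matrix; x = y = 0."""
    z = np.asarray(z_per_frame, dtype=float)
    F, n = z.shape
    q = np.asarray(charges, dtype=int)
    ids = [np.arange(n) for _ in range(F)]
    ch = [q.copy() for _ in range(F)]
    pos = [np.column_stack([np.zeros(n), np.zeros(n), z[k]]) for k in range(F)]
    return IonTrajectory(dt * np.arange(F), ids, ch, pos, lz=lz, box_z=box_z)


class TestInstantaneousCurrent:
    def test_single_ion_full_pore_hop_is_one_e_per_ps(self):
        traj = _traj_from_z([[0.0], [36.0]], [+1])
        trace = instantaneous_current(traj)
        assert trace.current[0] == pytest.approx(E_PER_PS_IN_NA, rel=1e-12)

    def test_opposite_charges_opposite_drift_add(self):
        v = 2.0
        traj = _traj_from_z([[0.0, 1.0], [v, 1.0 - v]], [+1, -1])
        trace = instantaneous_current(traj)
        assert trace.current[0] == pytest.approx(2 * v / 36.0 * E_PER_PS_IN_NA,
                                                 rel=1e-12)

    def test_membership_judged_at_earlier_frame(self):
        # ion outside the slab at frame 0 contributes nothing even if inside later
        traj = _traj_from_z([[20.0], [10.0]], [+1])
        assert instantaneous_current(traj).current[0] == 0.0

    def test_vanishing_ion_skipped_with_warning(self):
        ids = [np.array([0, 1]), np.array([0])]
        ch = [np.array([1, 1]), np.array([1])]
        pos = [np.array([[0, 0, 0.0], [0, 0, 1.0]]), np.array([[0, 0, 2.0]])]
        traj = IonTrajectory(np.array([0.0, 1.0]), ids, ch, pos)
        with pytest.warns(UserWarning, match="skipped 1"):
            trace = instantaneous_current(traj)
        assert trace.skipped_ions == 1
        assert trace.current[0] == pytest.approx(2.0 / 36.0 * E_PER_PS_IN_NA)

    def test_minimum_image_corrects_wrapped_step(self):
        # ion at z=17, steps +2 but is stored wrapped at -61 in an 80 Å box
        traj = _traj_from_z([[17.0], [-61.0]], [+1], box_z=80.0)
        trace = instantaneous_current(traj)
        assert trace.current[0] == pytest.approx(2.0 / 36.0 * E_PER_PS_IN_NA,
                                                 rel=1e-12)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_charge_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        z = rng.uniform(-20, 20, size=(5, 8))
        q = np.where(rng.random(8) < 0.5, 1, -1)
        a = instantaneous_current(_traj_from_z(z, q)).current
        b = instantaneous_current(_traj_from_z(z, -q)).current
        np.testing.assert_allclose(a, -b, atol=1e-12)

    def test_frame_reversal_negates_integrated_current(self):
        rng = np.random.default_rng(3)
        # keep ions well inside the slab so membership is frame-symmetric
        z = np.cumsum(rng.normal(0, 0.5, size=(10, 6)), axis=0)
        q = np.array([1, -1, 1, -1, 1, -1])
        fwd = instantaneous_current(_traj_from_z(z, q)).current.sum()
        rev = instantaneous_current(_traj_from_z(z[::-1], q)).current.sum()
        assert fwd == pytest.approx(-rev, abs=1e-9)

    def test_drift_diffusion_estimator_unbiased(self):
        """Time-averaged current within 3 SE of n q v_d / l_z across seeds."""
        means, expected = [], None
        for seed in range(12):
            traj, meta = gen_ion_trajectory(frames=600, seed=seed)
            means.append(instantaneous_current(traj).current.mean())
            expected = meta["expected_current_na"]
        means = np.array(means)
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean() - expected) < 3 * se


class TestCountPoreIons:
    def test_boundary_convention(self):
        traj = _traj_from_z([[0.0, 18.0, -18.0, 17.999]], [1, 1, -1, -1])
        assert count_pore_ions(traj).tolist() == [2]  # z=0 and 17.999 only

    def test_uniform_occupancy(self):
        traj, meta = gen_ion_trajectory(n_ions=60, drift=0.0, diffusion=1.0,
                                        frames=400, seed=4)
        counts = count_pore_ions(traj)
        p = 36.0 / 80.0
        se = np.sqrt(60 * p * (1 - p))  # per-frame binomial spread
        assert abs(counts.mean() - 60 * p) < 3 * se / np.sqrt(40)  # ~correlated frames


class TestLowpass:
    def test_dc_preserved(self):
        y = np.full(4000, 7.25)
        out = lowpass(y, FilterSpec(cutoff_ghz=5.0), delta_t_ps=1.0)
        np.testing.assert_allclose(out, y, rtol=1e-9)

    def test_mean_of_stationary_series_preserved(self):
        rng = np.random.default_rng(0)
        y = 100.0 + rng.normal(0, 10, 50_000)
        out = lowpass(y, FilterSpec(cutoff_ghz=5.0), delta_t_ps=1.0)
        assert out.mean() == pytest.approx(y.mean(), rel=1e-3)

    def test_gain_at_cutoff_is_half_for_two_passes(self):
        dt = 1.0  # ps -> fs = 1 THz
        f_c = 5.0  # GHz
        t = np.arange(200_000) * dt
        y = np.sin(2 * np.pi * f_c * 1e-3 * t)  # cutoff-frequency tone
        out = lowpass(y, FilterSpec(cutoff_ghz=f_c), delta_t_ps=dt)
        core = slice(20_000, -20_000)  # ignore edge transients
        gain = out[core].std() / y[core].std()
        assert gain == pytest.approx(0.5, rel=0.02)

    def test_white_noise_variance_reduced(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=20_000)
        out = lowpass(y, FilterSpec(cutoff_ghz=5.0), delta_t_ps=1.0)
        assert out.var() < y.var()

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            lowpass(np.zeros(100), FilterSpec(cutoff_ghz=500.0), delta_t_ps=1.0)

    def test_trace_roundtrip_keeps_metadata(self):
        trace = CurrentTrace(times=np.arange(5000.0), current=np.ones(5000),
                             delta_t=1.0)
        out = lowpass(trace, FilterSpec(cutoff_ghz=1.0))
        assert out.filter_applied.cutoff_ghz == 1.0
        assert out.delta_t == 1.0


class TestHistograms:
    def _trace(self, values):
        v = np.asarray(values, dtype=float)
        return CurrentTrace(times=np.arange(len(v), dtype=float), current=v,
                            delta_t=1.0)

    def test_constant_trace_single_bin(self):
        counts, edges = current_histogram(self._trace(np.full(100, 3.0)), bins=10)
        assert (counts > 0).sum() == 1
        assert counts.sum() == 100

    def test_two_level_trace_bimodal(self):
        v = np.where(np.arange(2000) % 100 < 50, 100.0, 220.0)
        counts, edges = current_histogram(self._trace(v), bins=30)
        centers = 0.5 * (edges[:-1] + edges[1:])
        occupied = centers[counts > 0]
        width = edges[1] - edges[0]
        assert np.any(np.abs(occupied - 100.0) < width)
        assert np.any(np.abs(occupied - 220.0) < width)
        assert (counts > 0).sum() == 2

    def test_filter_then_histogram_preserves_modes(self):
        # slow two-level blockade: filtering must not move the mode locations
        v = np.where((np.arange(40_000) // 2000) % 2 == 0, 100.0, 220.0)
        filtered = lowpass(v, FilterSpec(cutoff_ghz=5.0), delta_t_ps=1.0)
        counts, edges = current_histogram(self._trace(filtered), bins=40)
        width = edges[1] - edges[0]
        centers = 0.5 * (edges[:-1] + edges[1:])
        top_two = centers[np.argsort(counts)[-2:]]
        assert min(abs(top_two - 100.0).min(), abs(top_two - 220.0).min()) < width
        assert abs(sorted(top_two)[0] - 100.0) < width
        assert abs(sorted(top_two)[1] - 220.0) < width

    def test_exclusion_window_masks_frames(self):
        v = np.concatenate([np.full(50, 1.0), np.full(50, 9.0)])
        counts, edges = current_histogram(self._trace(v), bins=2,
                                          exclude_windows=[(50.0, 100.0)])
        assert counts.sum() == 50

    def test_masking_everything_is_an_error(self):
        with pytest.raises(ValueError, match="excluded"):
            current_histogram(self._trace(np.ones(10)), bins=2,
                              exclude_windows=[(0.0, 10.0)])


class TestDipoleConditioning:
    def test_always_aligned_empties_anti_histogram(self):
        trace = CurrentTrace(times=np.arange(100.0), current=np.ones(100), delta_t=1.0)
        dip = DipoleTrace(times=np.arange(100.0),
                          dipoles=np.tile([0.0, 0.0, 2.0], (100, 1)))
        al, anti, _ = dipole_conditioned_histograms(trace, dip, bins=5)
        assert al.sum() == 100 and anti.sum() == 0

    def test_two_point_charge_dipole_alignment(self):
        # +q at z=+1, -q at z=-1: dipole along +z, aligned with a +z field
        times = np.array([0.0])
        dip = DipoleTrace.from_point_charges(
            times, [[+1.0, -1.0]], [[[0, 0, 1.0], [0, 0, -1.0]]])
        np.testing.assert_allclose(dip.dipoles[0], [0, 0, 2.0])
        assert dip.aligned[0]

    def test_random_flags_on_constant_current(self):
        rng = np.random.default_rng(0)
        n = 200
        trace = CurrentTrace(times=np.arange(float(n)), current=np.full(n, 5.0),
                             delta_t=1.0)
        dipz = np.where(rng.random(n) < 0.5, 1.0, -1.0)
        dip = DipoleTrace(times=np.arange(float(n)),
                          dipoles=np.column_stack([np.zeros(n), np.zeros(n), dipz]))
        al, anti, edges = dipole_conditioned_histograms(trace, dip, bins=5)
        assert (al > 0).sum() == 1 and (anti > 0).sum() == 1
        assert np.argmax(al) == np.argmax(anti)

    def test_misaligned_time_axes_rejected(self):
        trace = CurrentTrace(times=np.arange(10.0), current=np.ones(10), delta_t=1.0)
        dip = DipoleTrace(times=np.arange(9.0), dipoles=np.zeros((9, 3)))
        with pytest.raises(ValueError, match="time axes"):
            dipole_conditioned_histograms(trace, dip)


class TestComTrack:
    def test_two_equal_masses_cancel(self):
        z = np.array([[5.0, -5.0], [6.0, -6.0]])
        np.testing.assert_allclose(com_track([0, 1], [2.0, 2.0], z), [0.0, 0.0])

    def test_single_atom_passthrough(self):
        z = np.array([[1.5], [2.5], [3.5]])
        np.testing.assert_allclose(com_track([0, 1, 2], [12.0], z), [1.5, 2.5, 3.5])

    def test_weighted_mean_matches_hand_computation(self):
        rng = np.random.default_rng(2)
        m = rng.uniform(1, 16, 7)
        z = rng.normal(size=(5, 7))
        expected = (z * m).sum(axis=1) / m.sum()
        np.testing.assert_allclose(com_track(np.arange(5), m, z), expected)

    def test_zero_total_mass_rejected(self):
        with pytest.raises(ValueError, match="mass"):
            com_track([0], [0.0], np.zeros((1, 1)))


def test_trajectory_tsv_roundtrip(tmp_path):
    traj, _ = gen_ion_trajectory(n_ions=5, frames=4, seed=1)
    p = tmp_path / "ions.tsv"
    traj.to_tsv(p)
    back = IonTrajectory.from_tsv(p, lz=traj.lz, box_z=traj.box_z)
    assert back.n_frames == traj.n_frames
    np.testing.assert_allclose(back.times, traj.times)
    for k in range(traj.n_frames):
        np.testing.assert_allclose(back.positions[k], traj.positions[k], atol=1e-6)
        np.testing.assert_array_equal(back.charges[k], traj.charges[k])


def test_nonuniform_times_rejected():
    with pytest.raises(ValueError, match="uniform"):
        IonTrajectory(np.array([0.0, 1.0, 3.0]),
                      [np.array([0])] * 3, [np.array([1])] * 3,
                      [np.zeros((1, 3))] * 3)
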