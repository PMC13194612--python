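"""Trajectory metrics: closed forms, rigid-motion invariance, cumulants."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from probiotarget import synthetic
from probiotarget.trajectory import (
    HBondCriteria,
    MetricSeries,
    Trajectory,
    equilibration_time,
    flexibility_threshold,
    hbond_count,
    radius_of_gyration,
    rmsd_series,
    rmsf_per_residue,
    series_statistics,
)


def toy_traj(frames, masses=None, residues=None):
    frames = np.asarray(frames, dtype=float)
    n_atoms = frames.shape[1]
    return Trajectory(
        times=np.arange(frames.shape[0]) * 0.01,
        coords=frames,
        masses=np.ones(n_atoms) if masses is None else np.asarray(masses, float),
        residue_index=np.arange(1, n_atoms + 1) if residues is None else residues,
    )


def random_structure(n_atoms=12, seed=0):
    return np.random.default_rng(seed).normal(0.0, 0.5, (n_atoms, 3))


class TestRmsd:
    def test_reference_frame_has_zero_rmsd(self):
        ref = random_structure()
        traj = toy_traj([ref, ref])
        assert rmsd_series(traj).values == pytest.approx([0.0, 0.0], abs=1e-12)

    def test_rigid_translation_removed_by_superposition(self):
        ref = random_structure()
        traj = toy_traj([ref, ref + np.array([1.0, -2.0, 0.5])])
        out = rmsd_series(traj, superpose=True)
        assert out.values[1] == pytest.approx(0.0, abs=1e-9)

    def test_two_atom_closed_form_without_superposition(self):
        ref = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        moved = ref + np.array([0.1, 0.0, 0.0])  # both atoms displaced 0.1 nm
        traj = toy_traj([ref, moved])
        out = rmsd_series(traj, superpose=False)
        assert out.values[1] == pytest.approx(0.1)

    def test_rigid_rotation_translation_invariance(self):
        rng = np.random.default_rng(5)
        ref = random_structure(20, seed=2)
        frames = [ref]
        for _ in range(4):
            rot = Rotation.random(rng=rng)
            frames.append(rot.apply(ref) + rng.normal(size=3))
        traj = toy_traj(frames, masses=rng.uniform(1, 20, 20))
        out = rmsd_series(traj, superpose=True)
        assert np.allclose(out.values, 0.0, atol=1e-8)

    def test_degenerate_superposition_falls_back_with_warning(self):
        ref = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])  # collinear pair
        traj = toy_traj([ref, ref + 0.2])
        with pytest.warns(UserWarning, match="degenerate"):
            rmsd_series(traj, superpose=True)


class TestRmsf:
    def test_static_trajectory_all_zero_no_flags(self):
        ref = random_structure()
        traj = toy_traj([ref] * 5)
        res = rmsf_per_residue(traj)
        assert np.allclose(res.rmsf, 0.0)
        assert len(res.flexible_residues) == 0

    def test_flexibility_threshold_arithmetic(self):
        # residue RMSFs with mean 0.12 nm and SD 0.073 nm
        values = np.array([0.047, 0.12, 0.193])
        assert values.mean() == pytest.approx(0.12)
        assert values.std(ddof=1) == pytest.approx(0.073)
        assert round(flexibility_threshold(values), 2) == 0.19

    def test_high_amplitude_residue_is_flagged(self):
        n_res = 30
        amps = np.full(n_res, 0.02)
        amps[17] = 0.2  # one residue 10x floppier
        ref, masses, res_idx = synthetic.make_reference_structure(n_res, seed=1)
        spec = synthetic.SyntheticSpec(seed=3, n_frames=400, traj_amplitudes=amps)
        traj = synthetic.generate_trajectory(spec, ref, masses, res_idx)
        res = rmsf_per_residue(traj)
        assert list(res.flexible_residues) == [18]  # 1-based
        assert res.flexible_runs == [(18, 18)]

    def test_requires_two_frames(self):
        traj = toy_traj([random_structure()])
        with pytest.raises(ValueError):
            rmsf_per_residue(traj)


class TestRadiusOfGyration:
    def test_single_atom_zero(self):
        traj = toy_traj(np.zeros((2, 1, 3)))
        assert radius_of_gyration(traj).values == pytest.approx([0.0, 0.0])

    def test_two_unit_masses_closed_form(self):
        frame = np.array([[1.0, 0.0, 0.0], [-1.0, 0.0, 0.0]])
        traj = toy_traj([frame, frame])
        assert radius_of_gyration(traj).values == pytest.approx([1.0, 1.0])

    def test_homogeneity_under_scaling(self):
        ref = random_structure(8, seed=4)
        traj_1 = toy_traj([ref, ref])
        traj_k = toy_traj([2.5 * ref, 2.5 * ref])
        assert radius_of_gyration(traj_k).values == pytest.approx(
            2.5 * radius_of_gyration(traj_1).values
        )

    def test_mass_weighting(self):
        frame = np.array([[1.0, 0.0, 0.0], [-1.0, 0.0, 0.0]])
        traj = toy_traj([frame, frame], masses=[3.0, 1.0])
        # com at x=0.5; rg = sqrt((3*0.25 + 1*2.25)/4) = sqrt(0.75)
        assert radius_of_gyration(traj).values[0] == pytest.approx(np.sqrt(0.75))


class TestHbonds:
    def _traj(self, acceptor_xyz):
        # atom 0 = donor, atom 1 = its hydrogen, atom 2 = acceptor
        frame = np.array([[0.0, 0.0, 0.0], [0.1, 0.0, 0.0], acceptor_xyz])
        return toy_traj([frame, frame], residues=np.array([1, 1, 2]))

    def test_close_pair_with_good_angle_counts_in_both(self):
        traj = self._traj([0.30, 0.0, 0.0])  # angle H-D-A = 0 deg
        hb, pairs = hbond_count(traj, [0], [1], [2])
        assert hb.values[0] == 1 and pairs.values[0] == 1

    def test_distant_pair_counts_in_neither(self):
        traj = self._traj([0.40, 0.0, 0.0])
        hb, pairs = hbond_count(traj, [0], [1], [2])
        assert hb.values[0] == 0 and pairs.values[0] == 0

    def test_bad_angle_keeps_pair_count_only(self):
        # acceptor at 0.3 nm, 60 degrees off the D-H axis
        traj = self._traj([0.30 * np.cos(np.deg2rad(60)), 0.30 * np.sin(np.deg2rad(60)), 0.0])
        hb, pairs = hbond_count(traj, [0], [1], [2])
        assert hb.values[0] == 0 and pairs.values[0] == 1

    def test_hbond_never_exceeds_pairs(self):
        rng = np.random.default_rng(8)
        frames = rng.uniform(-0.4, 0.4, (6, 9, 3))
        traj = toy_traj(frames, residues=np.arange(1, 10))
        hb, pairs = hbond_count(traj, [0, 3], [1, 4], [2, 5, 8])
        assert np.all(hb.values <= pairs.values)

    def test_empty_acceptors_warn_zero_series(self):
        traj = self._traj([0.3, 0.0, 0.0])
        with pytest.warns(UserWarning):
            hb, pairs = hbond_count(traj, [0], [1], [])
        assert np.all(hb.values == 0) and np.all(pairs.values == 0)


class TestSeriesStatistics:
    def test_brute_force_moment_oracle(self):
        rng = np.random.default_rng(12)
        values = rng.gamma(2.0, 1.5, size=500)
        stats = series_statistics(values)
        n = len(values)
        mean = sum(values) / n
        sd = (sum((v - mean) ** 2 for v in values) / (n - 1)) ** 0.5
        m2 = sum((v - mean) ** 2 for v in values) / n
        m3 = sum((v - mean) ** 3 for v in values) / n
        m4 = sum((v - mean) ** 4 for v in values) / n
        assert stats["mean"] == pytest.approx(mean, rel=1e-12)
        assert stats["sd"] == pytest.approx(sd, rel=1e-12)
        assert stats["se"] == pytest.approx(sd / n**0.5, rel=1e-12)
        assert stats["cum3"] == pytest.approx(m3 / m2**1.5, rel=1e-12)
        assert stats["cum4"] == pytest.approx(m4 / m2**2 - 3.0, rel=1e-12)

    def test_constant_series_undefined_cumulants(self):
        stats = series_statistics(np.full(10, 3.3))
        assert stats["sd"] == 0.0
        assert stats["cum3"] is None and stats["cum4"] is None

    def test_symmetric_series_zero_skewness(self):
        assert series_statistics(np.array([-1.0, 0.0, 1.0]))["cum3"] == pytest.approx(0.0)

    def test_gaussian_sample_near_zero_cumulants(self):
        rng = np.random.default_rng(99)
        x = rng.standard_normal(100_000)
        stats = series_statistics(x)
        n = len(x)
        se_skew = np.sqrt(6.0 / n)
        se_kurt = np.sqrt(24.0 / n)
        assert abs(stats["cum3"]) < 5 * se_skew
        assert abs(stats["cum4"]) < 5 * se_kurt

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            series_statistics(np.array([1.0]))


class TestEquilibrationTime:
    def _series(self, values, dt=0.01):
        values = np.asarray(values, dtype=float)
        times = np.arange(len(values)) * dt
        return MetricSeries("rmsd", times, values, {})

    def test_constant_series_equilibrated_from_start(self):
        series = self._series(np.full(2000, 0.3))
        assert equilibration_time(series, min_plateau_ns=5.0) == 0.0

    def test_step_function_detects_the_jump(self):
        values = np.concatenate([np.zeros(1000), np.ones(4000)])
        series = self._series(values)  # jumps at t = 10 ns, dt = 0.01
        assert equilibration_time(series, min_plateau_ns=5.0) == pytest.approx(10.0)

    def test_monotone_ramp_never_equilibrates(self):
        series = self._series(np.linspace(0.0, 1.0, 5000))
        assert equilibration_time(series, min_plateau_ns=5.0) is None


class TestTrajectoryValidation:
    def test_nonuniform_spacing_rejected(self):
        coords = np.zeros((3, 2, 3))
        with pytest.raises(ValueError):
            Trajectory(np.array([0.0, 0.01, 0.5]), coords, np.ones(2), np.array([1, 2]))

    def test_nonpositive_masses_rejected(self):
        coords = np.zeros((2, 2, 3))
        with pytest.raises(ValueError):
            Trajectory(np.array([0.0, 0.01]), coords, np.array([1.0, 0.0]), np.array([1, 2]))
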