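"""Phase schedules and running forecast moments."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from voxelda.ensemble import (
    PhaseSchedule,
    RunningMoments,
    phase_average_samples,
    reynolds_decompose,
)
from voxelda.observation import ObservationSample, VoxelGrid


# -- schedules ---------------------------------------------------------------

def test_schedule_invariants():
    with pytest.raises(ValueError):
        PhaseSchedule(1.0, (0.5, 0.4))
    with pytest.raises(ValueError):
        PhaseSchedule(1.0, (0.0, 0.5))
    with pytest.raises(ValueError):
        PhaseSchedule(1.0, (0.5, 1.5))
    s = PhaseSchedule.uniform(2.0, 4)
    assert s.phase_times == (0.5, 1.0, 1.5, 2.0)
    assert s.time_of(1, 0) == 0.5
    assert np.isclose(s.time_of(3, 1), 1.0 + 2 * 2.0)


def test_steady_schedule_is_single_phase():
    s = PhaseSchedule.steady(0.5)
    assert s.is_steady and s.n_phases == 1
    assert np.isclose(s.time_of(7, 0), 7 * 0.5)


def test_schedule_refinement_triples_intervals():
    coarse = PhaseSchedule(1.0, (0.2, 0.5, 1.0))
    fine = coarse.refined(3)
    assert fine.n_phases == 9
    assert np.isclose(fine.phase_times[-1], 1.0)
    # original times survive as every third entry
    assert np.allclose(fine.phase_times[2::3], coarse.phase_times)


# -- running moments ---------------------------------------------------------

def test_single_sample_moments():
    m = RunningMoments((2, 1, 1), 1, d_diag=10.0)
    x = np.arange(6.0).reshape(2, 1, 1, 3)
    m.update(0, x)
    assert np.allclose(m.mean_field(0), x)
    # s = 1: the covariance equals D exactly
    assert np.allclose(m.covariance(0), np.tile(10.0 * np.eye(3), (2, 1, 1, 1, 1)))


@pytest.mark.parametrize("d", [10.0, 1000.0])
def test_covariance_equals_d_at_first_pulse(d):
    m = RunningMoments((1, 1, 1), 1, d_diag=d)
    m.update(0, np.ones((1, 1, 1, 3)))
    assert np.allclose(m.covariance(0), d * np.eye(3))


def test_two_scalar_samples_mean_and_deviation_sum():
    m = RunningMoments((1, 1, 1), 1, d_diag=0.0)
    for val in (1.0, 3.0):
        x = np.zeros((1, 1, 1, 3))
        x[..., 0] = val
        m.update(0, x)
    assert np.isclose(m.mean[0][0, 0], 2.0)
    # sum of squared deviations (1-2)^2 + (3-2)^2 = 2; covariance 2/2 = 1
    assert np.isclose(m.m2[0][0, 0, 0], 2.0)
    assert np.isclose(m.covariance(0)[0, 0, 0, 0, 0], 1.0)


def test_identical_samples_covariance_decays_as_d_over_s():
    d = 50.0
    m = RunningMoments((1, 1, 1), 1, d_diag=d)
    x = np.full((1, 1, 1, 3), 2.5)
    for s in range(1, 21):
        m.update(0, x)
        assert np.allclose(m.covariance(0), d / s * np.eye(3), atol=1e-12)


def test_moments_match_batch_oracle(rng):
    # 50 random 3-vectors: one-pass result equals the batch formula
    d = 10.0
    xs = rng.standard_normal((50, 4, 1, 1, 3))
    m = RunningMoments((4, 1, 1), 1, d_diag=d)
    for x in xs:
        m.update(0, x)
    mean = xs.mean(axis=0)
    dev = (xs - mean).reshape(50, 4, 3)
    batch = (np.einsum("sgi,sgj->gij", dev, dev) + d * np.eye(3)) / 50
    assert np.abs(m.mean_field(0) - mean).max() < 1e-12
    assert np.abs(m.covariance_flat(0) - batch).max() < 1e-10


def test_moments_permutation_invariant(rng):
    xs = rng.standard_normal((12, 2, 1, 1, 3))
    m1 = RunningMoments((2, 1, 1), 1, 1.0)
    m2 = RunningMoments((2, 1, 1), 1, 1.0)
    for x in xs:
        m1.update(0, x)
    for x in xs[::-1]:
        m2.update(0, x)
    assert np.abs(m1.mean - m2.mean).max() < 1e-12
    assert np.abs(m1.covariance(0) - m2.covariance(0)).max() < 1e-12


def test_one_pass_conditioning_against_two_pass(rng):
    # large offset stresses cancellation; Welford stays at relative 1e-10
    xs = 1e6 + rng.standard_normal((10_000, 1, 1, 1, 3))
    m = RunningMoments((1, 1, 1), 1, 0.0)
    for x in xs:
        m.update(0, x)
    dev = xs.reshape(-1, 3) - xs.reshape(-1, 3).mean(axis=0)
    batch = dev.T @ dev / len(dev)
    rel = np.abs(m.covariance_flat(0)[0] - batch).max() / np.abs(batch).max()
    assert rel < 1e-8


def test_covariance_requires_samples():
    m = RunningMoments((1, 1, 1), 1, 1.0)
    with pytest.raises(ValueError):
        m.covariance(0)
    with pytest.raises(IndexError):
        m.update(3, np.zeros((1, 1, 1, 3)))


def test_moments_hdf5_roundtrip(tmp_path, rng):
    import h5py

    m = RunningMoments((2, 2, 1), 2, 10.0)
    for _ in range(3):
        m.update(0, rng.standard_normal((2, 2, 1, 3)))
        m.update(1, rng.standard_normal((2, 2, 1, 3)))
    with h5py.File(tmp_path / "m.h5", "w") as f:
        m.to_hdf5(f.create_group("moments"))
    with h5py.File(tmp_path / "m.h5", "r") as f:
        back = RunningMoments.from_hdf5(f["moments"])
    assert np.array_equal(back.count, m.count)
    assert np.allclose(back.covariance(0), m.covariance(0))


# -- phase averaging of observation samples ----------------------------------

def _vox():
    return VoxelGrid((0.0, 0.0, 0.0), (1.0, 1.0, 1.0), (2, 1, 1))


def test_single_pulse_covariance_is_zero(rng):
    s = ObservationSample(1, 0, rng.standard_normal((2, 3)))
    obs = phase_average_samples([s], _vox(), [1.0], 1.0)
    assert np.abs(obs.cov).max() == 0.0
    assert np.allclose(obs.mean[0], s.values)


def test_antisymmetric_pair_gives_outer_product(rng):
    d = rng.standard_normal((2, 3))
    s1 = ObservationSample(1, 0, d)
    s2 = ObservationSample(2, 0, -d)
    obs = phase_average_samples([s1, s2], _vox(), [1.0], 1.0)
    assert np.abs(obs.mean).max() < 1e-15
    expected = np.einsum("vi,vj->vij", d, d)
    assert np.allclose(obs.cov[0], expected)


def test_empty_phase_group_rejected(rng):
    s = ObservationSample(1, 0, rng.standard_normal((2, 3)))
    with pytest.raises(ValueError, match="without samples"):
        phase_average_samples([s], _vox(), [0.5, 1.0], 1.0)


# -- Reynolds decomposition ---------------------------------------------------

def test_fluctuations_have_zero_ensemble_mean(rng):
    m = RunningMoments((3, 1, 1), 1, 0.0)
    xs = rng.standard_normal((7, 3, 1, 1, 3))
    for x in xs:
        m.update(0, x)
    flucts = np.stack([reynolds_decompose(x, m, 0) for x in xs])
    assert np.abs(flucts.mean(axis=0)).max() < 1e-12
    # two-member ensemble: fluctuations are +/- half the difference
    m2 = RunningMoments((1, 1, 1), 1, 0.0)
    a, b = np.zeros((1, 1, 1, 3)), np.ones((1, 1, 1, 3))
    m2.update(0, a)
    m2.update(0, b)
    assert np.allclose(reynolds_decompose(a, m2, 0), -0.5)
    assert np.allclose(reynolds_decompose(b, m2, 0), 0.5)
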