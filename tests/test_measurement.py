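"""Observation model, GMFI summaries, quench-efficiency estimation, IO."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from endokin.dynamics import CompartmentState, KineticParams, solve
from endokin.measurement import (
    AutofluorescenceSample,
    Dataset,
    MeasurementParams,
    Snapshot,
    estimate_quench_efficiency,
    gmfi,
    observe_cell,
    observe_signals,
)
from endokin.population import CellProperties
from endokin.synthetic_data import (
    StudyDesign,
    default_measurement,
    default_population,
    generate_dataset,
)


def _state(T=0.3, S=0.3, E=0.25, F=0.15):
    return CompartmentState(T=T, S=S, E=E, F=F)


def _cell(R=1.3):
    return CellProperties(R=R, k=KineticParams(0.1, 0.05, 0.05))


class TestObserveCell:
    def test_noise_free_unquenched(self):
        mp = MeasurementParams(alpha1=100.0, alpha2=50.0, eta=0.9)
        st_ = _state()
        q, u = observe_cell(_cell(), st_, mp, "unquenched", (0.0, 0.0), (0.0, 0.0))
        A = st_.S + st_.E + st_.F
        assert q == pytest.approx(100.0 * A * 1.3)
        assert u == pytest.approx(50.0 * A * 1.3)

    def test_perfect_quenching_removes_surface_signal(self):
        mp = MeasurementParams(alpha1=100.0, alpha2=50.0, eta=1.0)
        st_ = _state()
        q, _ = observe_cell(_cell(), st_, mp, "quenched", (0.0, 0.0), (0.0, 0.0))
        assert q == pytest.approx(100.0 * (st_.E + st_.F) * 1.3)

    def test_quenched_ratio_at_equilibrium(self):
        # at t=0 no antibody is internal, so the quenched/unquenched
        # true-signal ratio is exactly 1 - eta
        mp = MeasurementParams(alpha1=100.0, alpha2=50.0, eta=0.94)
        st_ = CompartmentState(T=0.7, S=0.3, E=0.0, F=0.0)
        q_q, _ = observe_cell(_cell(), st_, mp, "quenched", (0.0, 0.0), (0.0, 0.0))
        q_u, _ = observe_cell(_cell(), st_, mp, "unquenched", (0.0, 0.0), (0.0, 0.0))
        assert q_q / q_u == pytest.approx(0.06)

    def test_autofluorescence_added_jointly(self):
        mp = MeasurementParams(alpha1=10.0, alpha2=10.0, eta=0.9)
        q, u = observe_cell(_cell(), _state(), mp, "unquenched", (5.0, 7.0), (0.0, 0.0))
        q0, u0 = observe_cell(_cell(), _state(), mp, "unquenched", (0.0, 0.0), (0.0, 0.0))
        assert q - q0 == pytest.approx(5.0)
        assert u - u0 == pytest.approx(7.0)

    def test_mean_preserving_noise(self):
        mp = MeasurementParams(alpha1=100.0, alpha2=100.0, eta=0.9,
                               sigma1=0.2, sigma2=0.2)
        rng = np.random.default_rng(0)
        n = 200_000
        A = np.full(n, 0.7); I = np.full(n, 0.4); S = np.full(n, 0.3)
        R = np.ones(n)
        q, u = observe_signals(A, I, S, R, mp, "unquenched",
                               np.zeros(n), np.zeros(n),
                               rng.standard_normal(n), rng.standard_normal(n))
        true_q = 100.0 * 0.7
        assert q.mean() == pytest.approx(true_q, rel=3 * 0.2 / np.sqrt(n))

    def test_sqrt_noise_mode_variance_scales_with_signal(self):
        mp = MeasurementParams(alpha1=100.0, alpha2=100.0, eta=0.9,
                               sigma1=2.0, sigma2=2.0, noise_mode="sqrt")
        rng = np.random.default_rng(1)
        n = 100_000
        for a in (0.25, 1.0):
            A = np.full(n, a); R = np.ones(n)
            q, _ = observe_signals(A, A, A * 0, R, mp, "unquenched",
                                   np.zeros(n), np.zeros(n),
                                   rng.standard_normal(n), rng.standard_normal(n))
            assert q.var() == pytest.approx(4.0 * 100.0 * a, rel=0.05)

    def test_perfect_channel_correlation_without_noise(self):
        # unquenched, sigma=0, af=0: both channels proportional to A*R
        mp = MeasurementParams(alpha1=80.0, alpha2=30.0, eta=0.9)
        k = KineticParams(0.1, 0.05, 0.05)
        rng = np.random.default_rng(2)
        R = rng.lognormal(0, 0.4, 500)
        traj = solve(k, np.array([30.0]))
        A = np.full(500, traj.A[0]); I = np.full(500, traj.I[0])
        S = np.full(500, traj.S[0])
        q, u = observe_signals(A, I, S, R, mp, "unquenched",
                               np.zeros(500), np.zeros(500),
                               np.zeros(500), np.zeros(500))
        assert np.corrcoef(q, u)[0, 1] == pytest.approx(1.0)


class TestGmfi:
    def test_examples(self):
        assert gmfi([3.0, 3.0, 3.0]) == pytest.approx(3.0)
        assert gmfi([1.0, 10.0, 100.0]) == pytest.approx(10.0)

    def test_lognormal_geometric_mean(self):
        rng = np.random.default_rng(3)
        v = rng.lognormal(mean=2.0, sigma=1.0, size=10**6)
        assert gmfi(v) == pytest.approx(np.exp(2.0), rel=0.01)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(c=st.floats(0.01, 100.0))
    def test_scale_equivariance(self, c):
        v = np.array([0.5, 2.0, 7.0, 11.0])
        assert gmfi(c * v) == pytest.approx(c * gmfi(v), rel=1e-9)

    def test_nonpositive_excluded_and_counted(self):
        g, excluded = gmfi([-1.0, 0.0, 4.0, 9.0], return_excluded=True)
        assert g == pytest.approx(6.0)
        assert excluded == 2

    def test_all_nonpositive_errors(self):
        with pytest.raises(ValueError):
            gmfi([-1.0, 0.0])


class TestQuenchEfficiency:
    def test_boundary_cases(self):
        assert estimate_quench_efficiency(10.0, 100.0, 10.0) == 1.0
        assert estimate_quench_efficiency(100.0, 100.0, 10.0) == 0.0

    def test_precondition(self):
        with pytest.raises(ValueError):
            estimate_quench_efficiency(5.0, 10.0, 20.0)

    def test_round_trip_recovery(self):
        # synthetic 4C control generated with true eta = 0.94
        ds = generate_dataset(
            default_population(), default_measurement(),
            StudyDesign(seed=31, n_per_sample=2000),
        )
        eta = estimate_quench_efficiency(
            ds.quench_control[0], ds.quench_control[1],
            ds.autofluorescence.gmfi_Q(),
        )
        assert eta == pytest.approx(0.94, abs=0.01)


class TestContainersAndIO:
    def test_snapshot_validation(self):
        with pytest.raises(ValueError):
            Snapshot(time=-1.0, condition="quenched", Q=np.ones(3), U=np.ones(3))
        with pytest.raises(ValueError):
            Snapshot(time=0.0, condition="quenched", Q=np.ones(3), U=np.ones(4))

    def test_dataset_requires_both_conditions(self):
        s = Snapshot(time=0.0, condition="quenched", Q=np.ones(3), U=np.ones(3))
        with pytest.raises(ValueError):
            Dataset(snapshots=[s])

    def test_csv_round_trip(self, small_dataset, tmp_path):
        path = tmp_path / "snap.csv"
        small_dataset.to_csv(path)
        back = Dataset.from_csv(path)
        assert back.structure() is not None
        assert set(back.times) == set(small_dataset.times)
        s0 = small_dataset.snapshot(10.0, "quenched")
        s1 = back.snapshot(10.0, "quenched")
        assert np.allclose(np.sort(s0.Q), np.sort(s1.Q))

    def test_autofluorescence_validation(self):
        with pytest.raises(ValueError):
            AutofluorescenceSample(EQ=np.ones(10), EU=np.ones(10))  # too few
        af = AutofluorescenceSample(EQ=np.arange(200.0), EU=np.arange(200.0))
        a, b = af.resample(50, np.random.default_rng(0))
        assert np.array_equal(a, b)  # pairs drawn jointly
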