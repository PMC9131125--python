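"""Distribution-matching discrepancy and the ABC samplers (desk scale)."""

import numpy as np
import pytest

from endokin.abc import (
    ABCProblem,
    DiscrepancyConfig,
    ad_distance,
    abc_mcmc,
    abc_smc,
    calibrate_weights,
    default_prior_box,
    discrepancy,
    select_best_fit,
)
from endokin.measurement import Dataset, Snapshot
from endokin.synthetic_data import StudyDesign, default_measurement, \
    default_population, generate_dataset

from conftest import reduced_problem


def _brute_force_ad(x, y):
    """Independent rank-based evaluation of the two-sample A2 statistic
    (continuous Scholz-Stephens formula, standardized)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    nx, ny = x.size, y.size
    N = nx + ny
    pooled = np.sort(np.concatenate([x, y]))
    a2 = 0.0
    for sample, n_i in ((x, nx), (y, ny)):
        inner = 0.0
        for j in range(1, N):
            M_ij = np.sum(sample <= pooled[j - 1])
            inner += (N * M_ij - j * n_i) ** 2 / (j * (N - j))
        a2 += inner / n_i
    a2 /= N
    # standardization constants (k = 2 samples)
    H = 1.0 / nx + 1.0 / ny
    h = sum(1.0 / j for j in range(1, N))
    g = sum(
        1.0 / ((N - i) * j)
        for i in range(1, N - 1)
        for j in range(i + 1, N)
    )
    k = 2
    a = (4 * g - 6) * (k - 1) + (10 - 6 * g) * H
    b = (2 * g - 4) * k**2 + 8 * h * k + (2 * g - 14 * h - 4) * H - 8 * h + 4 * g - 6
    c = (6 * h + 2 * g - 2) * k**2 + (4 * h - 4 * g + 6) * k + (2 * h - 6) * H + 4 * h
    d = (2 * h + 6) * k**2 - 4 * h * k
    var = (a * N**3 + b * N**2 + c * N + d) / ((N - 1) * (N - 2) * (N - 3))
    return (a2 - (k - 1)) / np.sqrt(var)


class TestAndersonDarling:
    def test_matches_brute_force_formula(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([1.5, 2.5])
        assert ad_distance(x, y) == pytest.approx(_brute_force_ad(x, y), rel=1e-12)
        rng = np.random.default_rng(8)
        for nx, ny in [(5, 5), (20, 13), (40, 40)]:
            a = rng.normal(size=nx)
            b = rng.normal(0.5, 1.3, size=ny)
            assert ad_distance(a, b) == pytest.approx(
                _brute_force_ad(a, b), rel=1e-10
            )

    def test_symmetry(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(size=30), rng.normal(1, 2, size=40)
        assert ad_distance(a, b) == pytest.approx(ad_distance(b, a))

    def test_self_comparison_minimality(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=100)
        base = ad_distance(x, x)
        for shift in (0.5, 1.0, 3.0):
            assert base <= ad_distance(x, x + shift)

    def test_monotone_in_separation(self):
        rng = np.random.default_rng(11)
        medians = []
        for delta in (0.0, 0.5, 1.0, 2.0):
            vals = [
                ad_distance(rng.normal(size=500), rng.normal(delta, 1, size=500))
                for _ in range(25)
            ]
            medians.append(np.median(vals))
        assert np.all(np.diff(medians) > 0)

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            ad_distance(np.array([]), np.array([1.0]))


class TestDiscrepancy:
    def test_self_distance_components(self, small_dataset):
        cfg = DiscrepancyConfig()
        d_self = discrepancy(small_dataset, small_dataset, cfg)
        # correlation term is exactly 0; AD terms at their self-comparison
        # minimum for each snapshot configuration
        expected = sum(
            ad_distance(s.Q, s.Q) + ad_distance(s.U, s.U)
            for s in small_dataset.snapshots
        )
        assert d_self == pytest.approx(expected, rel=1e-9)

    def test_structure_mismatch_errors(self, small_dataset):
        other = Dataset(
            snapshots=[
                Snapshot(time=1.0, condition=c, Q=np.ones(5), U=np.ones(5))
                for c in ("quenched", "unquenched")
            ]
        )
        with pytest.raises(ValueError):
            discrepancy(small_dataset, other, DiscrepancyConfig())

    def test_shifted_p_exceeds_replicate_floor(self, study_dataset, study_eta):
        problem, theta_truth = reduced_problem(study_dataset, study_eta, n_sim=500)
        rng = np.random.default_rng(12)
        floor = np.median(
            [problem.distance(theta_truth, rng) for _ in range(15)]
        )
        shifted = theta_truth.copy()
        shifted[list(problem.free).index("p")] = 0.15
        d_shift = np.median(
            [problem.distance(shifted, rng) for _ in range(15)]
        )
        assert d_shift > floor

    def test_weight_calibration_ratio_rule(self, study_dataset, study_eta):
        problem, _ = reduced_problem(study_dataset, study_eta, n_sim=400)
        cfg = calibrate_weights(problem, n_pilot=25, seed=13)
        assert cfg.w_ad == 1.0
        assert cfg.w_corr > 0
        # self-consistency: on a fresh pilot the weighted medians are of the
        # same order (the calibration is itself a median over random draws)
        rng = np.random.default_rng(14)
        ad_tot, corr_tot = [], []
        for _ in range(25):
            theta = problem.sample_prior(rng)
            sim = problem.simulate(theta, rng)
            a, c = problem._summary.contributions(sim)
            ad_tot.append(a)
            corr_tot.append(c * cfg.w_corr)
        ratio = np.median(ad_tot) / np.median(corr_tot)
        assert 0.4 < ratio < 2.5


@pytest.fixture(scope="module")
def tiny_problem():
    """Very small inference problem for sampler mechanics."""
    ds = generate_dataset(
        default_population(), default_measurement(),
        StudyDesign(times=(0.0, 10.0, 60.0), n_per_sample=150,
                    n_autofluorescence=400, seed=20),
    )
    truth = {**ds.truth["population"], **ds.truth["measurement"]}
    truth.pop("eta")
    free = ("mu_lam", "p")
    fixed = {k: v for k, v in truth.items() if k not in free}
    problem = ABCProblem(
        obs=ds, prior=default_prior_box(10000.0), fixed=fixed, eta=0.94,
        cfg=DiscrepancyConfig(n_sim=150),
    )
    return problem, np.array([truth[n] for n in free])


class TestSMC:
    def test_point_prior_degenerates_to_replicate_floor(self, tiny_problem):
        problem, theta_truth = tiny_problem
        point = ABCProblem(
            obs=problem.obs,
            prior={n: (v, v) for n, v in zip(problem.free, theta_truth)},
            fixed=problem.fixed, eta=problem.eta, cfg=problem.cfg,
        )
        res = abc_smc(point, n_particles=50, seed=21, max_generations=3)
        assert np.unique(res.particles, axis=0).shape[0] == 1
        rng = np.random.default_rng(22)
        floor = np.array([point.distance(theta_truth, rng) for _ in range(40)])
        # epsilon is a quantile of replicate-floor draws (the standardized
        # AD statistics centre near zero at a perfect match, so the floor
        # may even be slightly negative)
        assert abs(res.epsilon - np.median(floor)) < 3 * floor.std()

    def test_determinism(self, tiny_problem):
        problem, _ = tiny_problem
        a = abc_smc(problem, n_particles=50, seed=23, max_generations=3)
        b = abc_smc(problem, n_particles=50, seed=23, max_generations=3)
        assert np.array_equal(a.particles, b.particles)
        assert a.epsilon == b.epsilon

    def test_particle_count_validated(self, tiny_problem):
        problem, _ = tiny_problem
        with pytest.raises(ValueError):
            abc_smc(problem, n_particles=10, seed=0)


class TestMCMC:
    def test_infinite_epsilon_free_walk(self, tiny_problem):
        problem, theta_truth = tiny_problem
        cov = np.diag((1e-6 * np.abs(theta_truth) + 1e-9) ** 2)
        chain = abc_mcmc(
            problem, np.inf, theta_truth, cov,
            n_chains=1, n_steps=400, thin=10, seed=24, n_tune=0,
        )
        # with epsilon = inf and tiny steps the walk accepts almost always
        assert chain.acceptance_rate > 0.95

    def test_retained_samples_satisfy_threshold_and_box(self, tiny_problem):
        problem, theta_truth = tiny_problem
        rng = np.random.default_rng(25)
        eps = np.quantile(
            [problem.distance(theta_truth, rng) for _ in range(20)], 0.9
        )
        cov = np.diag((0.05 * np.abs(theta_truth)) ** 2)
        chain = abc_mcmc(
            problem, eps, theta_truth, cov,
            n_chains=2, n_steps=300, thin=10, seed=26, n_tune=100,
        )
        assert np.all(chain.discrepancies < eps)
        lo = np.array([problem.prior[n][0] for n in problem.free])
        hi = np.array([problem.prior[n][1] for n in problem.free])
        assert np.all(chain.samples >= lo) and np.all(chain.samples <= hi)
        assert set(chain.ess) == set(problem.free)

    def test_initialization_failure_raises(self, tiny_problem):
        problem, theta_truth = tiny_problem
        with pytest.raises(RuntimeError, match="initialize"):
            abc_mcmc(
                problem, -1e9, theta_truth, np.eye(2),
                n_chains=1, n_steps=10, thin=1, seed=27, init_retries=3,
            )


class TestBestFit:
    def test_separation_and_determinism(self, tiny_problem):
        from endokin.abc import PosteriorChain

        problem, theta_truth = tiny_problem
        wrong1 = theta_truth * np.array([3.0, 2.5])
        wrong2 = theta_truth * np.array([0.1, 2.9])
        samples = np.vstack([wrong1, theta_truth, wrong2])
        chain = PosteriorChain(
            samples=samples,
            discrepancies=np.zeros(3),
            chain_id=np.zeros(3, int),
            free=problem.free, epsilon=np.inf, acceptance_rate=1.0,
            thin=1, ess={}, rhat={},
        )
        best = select_best_fit(problem, chain, n_candidates=3, n_reps=10, seed=28)
        assert np.array_equal(best, theta_truth)
        best2 = select_best_fit(problem, chain, n_candidates=3, n_reps=10, seed=28)
        assert np.array_equal(best, best2)

    def test_single_state_chain_returns_it(self, tiny_problem):
        from endokin.abc import PosteriorChain

        problem, theta_truth = tiny_problem
        chain = PosteriorChain(
            samples=np.tile(theta_truth, (5, 1)),
            discrepancies=np.zeros(5),
            chain_id=np.zeros(5, int),
            free=problem.free, epsilon=np.inf, acceptance_rate=1.0,
            thin=1, ess={}, rhat={},
        )
        best = select_best_fit(problem, chain, n_candidates=5, n_reps=2, seed=29)
        assert np.array_equal(best, theta_truth)
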