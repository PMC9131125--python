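"""Posterior predictions of unobservable quantities."""

import numpy as np
import pytest
from scipy import stats

from endokin.abc import PosteriorChain
from endokin.population import PopulationParams
from endokin.predict import (
    between_time_dependence,
    conditional_posterior,
    internal_fraction_distribution,
    posterior_fraction,
    predictive_band,
    surface_fraction_distribution,
)
from endokin.synthetic_data import default_population


def _pp(**over):
    base = default_population().to_dict()
    base.update(over)
    return PopulationParams.from_dict(base)


def _degenerate(lam=0.106, beta=0.047, p=0.068):
    return _pp(
        sigma_R=0.0, sigma_lam=0.0, sigma_beta=0.0,
        mu_lam=lam, mu_beta=beta, p=p,
        rho_Rlam=0.0, rho_lambeta=0.0, rho_tilde_Rbeta=0.0,
    )


class TestInternalFraction:
    def test_vanishes_at_early_time(self):
        out = internal_fraction_distribution(_pp(), [1e-6], n_cells=500, seed=0)
        assert np.all(out["samples"][1e-6] < 1e-4)

    def test_zero_heterogeneity_is_point_mass(self):
        from endokin.dynamics import KineticParams, solve

        out = internal_fraction_distribution(
            _degenerate(), [60.0], n_cells=200, seed=1
        )
        s = out["samples"][60.0]
        assert np.ptp(s) < 1e-12
        traj = solve(KineticParams(0.106, 0.047, 0.068), np.array([60.0]))
        assert s[0] == pytest.approx(traj.I[0] / traj.A[0])
        # with a single cell type the GMFI ratio equals the common fraction
        assert out["gmfi_ratio"][60.0] == pytest.approx(s[0])

    def test_gmfi_ratio_inside_percell_support(self):
        out = internal_fraction_distribution(
            _pp(), [10.0, 60.0, 120.0], n_cells=5000, seed=2
        )
        for t in (10.0, 60.0, 120.0):
            s = out["samples"][t]
            assert s.min() < out["gmfi_ratio"][t] < s.max()


class TestSurfaceFraction:
    def test_degenerate_at_reference_rates(self):
        s0, R = surface_fraction_distribution(_degenerate(), n_cells=100, seed=3)
        assert np.allclose(s0, 0.047 / 0.153)
        assert round(float(s0[0]), 2) == 0.31

    def test_mass_near_zero_when_beta_can_vanish(self):
        pp = _pp(mu_beta=0.02, sigma_beta=0.02, omega_beta=0.0)
        s0, _ = surface_fraction_distribution(pp, n_cells=20000, seed=4)
        assert (s0 < 0.05).mean() > 0.01

    def test_negative_receptor_recycling_dependence_propagates(self):
        pp = _pp(rho_Rlam=0.0, rho_lambeta=0.0, rho_tilde_Rbeta=-0.5)
        s0, R = surface_fraction_distribution(pp, n_cells=10**5, seed=5)
        assert stats.spearmanr(R, s0).statistic < 0


class TestBetweenTimeDependence:
    def test_receptor_only_heterogeneity_gives_unit_correlation(self):
        pp = _pp(sigma_lam=0.0, sigma_beta=0.0)
        dep = between_time_dependence(pp, 10.0, 120.0, n_cells=500, seed=6,
                                      alpha1=7840.0)
        assert not dep.degenerate
        assert dep.copula_rho == pytest.approx(1.0, abs=1e-9)

    def test_zero_heterogeneity_degenerate(self):
        dep = between_time_dependence(_degenerate(), 10.0, 120.0,
                                      n_cells=100, seed=7)
        assert dep.degenerate
        assert np.isnan(dep.copula_rho)

    def test_stability_across_seeds(self):
        rhos = [
            between_time_dependence(_pp(), 10.0, 120.0, n_cells=1000,
                                    seed=s, alpha1=7840.0).copula_rho
            for s in range(5)
        ]
        assert np.ptp(rhos) < 0.06  # +-0.03 around the central value

    def test_time_order_validated(self):
        with pytest.raises(ValueError):
            between_time_dependence(_pp(), 120.0, 10.0)


def _toy_chain():
    free = ("mu_beta", "sigma_beta", "rho_Rlam", "rho_lambeta", "rho_tilde_Rbeta")
    samples = np.array(
        [
            [0.05, 0.01, 0.1, 0.2, -0.5],
            [0.04, 0.02, 0.0, 0.0, -0.3],
            [0.06, 0.03, 0.0, 0.0, 0.4],
            [0.05, 0.05, 0.2, 0.1, -0.2],
        ]
    )
    return PosteriorChain(
        samples=samples,
        discrepancies=np.zeros(4),
        chain_id=np.zeros(4, int),
        free=free, epsilon=np.inf, acceptance_rate=1.0, thin=1,
        ess={}, rhat={},
    )


class TestChainConditioning:
    def test_always_true_predicate_keeps_everything(self):
        chain = _toy_chain()
        filtered, frac = conditional_posterior(chain, lambda s: True)
        assert frac == 1.0
        assert np.array_equal(filtered.samples, chain.samples)

    def test_component_predicate_bookkeeping(self):
        chain = _toy_chain()
        filtered, frac = conditional_posterior(
            chain, lambda s: s["sigma_beta"] <= 0.02
        )
        assert frac == 0.5
        assert filtered.samples.shape[0] == 2

    def test_empty_subset_errors(self):
        with pytest.raises(ValueError):
            conditional_posterior(_toy_chain(), lambda s: False)

    def test_posterior_fraction_counts(self):
        chain = _toy_chain()
        assert posterior_fraction(chain, lambda s: False) == 0.0
        assert posterior_fraction(chain, lambda s: s["mu_beta"] >= 0.05) == 0.75

    def test_implied_receptor_recycling_correlation_available(self):
        chain = _toy_chain()
        frac = posterior_fraction(chain, lambda s: s["rho_Rbeta"] < 0)
        assert frac == 0.75  # three of four rows imply a negative value

    def test_conditioning_narrows_recycling_spread(self):
        # rows with high implied between-time order have smaller sigma_beta
        chain = _toy_chain()
        filtered, _ = conditional_posterior(
            chain, lambda s: s["sigma_beta"] <= 0.02
        )
        i = chain.free.index("sigma_beta")
        assert filtered.samples[:, i].max() < chain.samples[:, i].max()


class TestPredictiveBand:
    def test_band_envelopes_and_nonnegative(self):
        rng = np.random.default_rng(11)

        def sample_fn(theta):
            return rng.normal(theta["mu"], theta["sd"], size=400)

        grid = np.linspace(-4, 4, 81)
        band = predictive_band(
            sample_fn, {"mu": 0.0, "sd": 1.0},
            [{"mu": m, "sd": 1.0} for m in np.linspace(-0.3, 0.3, 20)],
            grid,
        )
        assert np.all(band.band_lo >= 0)
        assert np.all(band.band_hi >= band.band_lo)

    def test_band_widens_with_posterior_spread(self):
        rng = np.random.default_rng(12)

        def sample_fn(theta):
            return rng.normal(theta["mu"], 1.0, size=400)

        grid = np.linspace(-5, 5, 51)
        widths = []
        for spread in (0.1, 1.0):
            band = predictive_band(
                sample_fn, {"mu": 0.0},
                [{"mu": m} for m in np.linspace(-spread, spread, 25)],
                grid,
            )
            widths.append(np.trapezoid(band.band_hi - band.band_lo, grid))
        assert widths[1] > widths[0]
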