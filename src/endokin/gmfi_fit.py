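"""Maximum-likelihood calibration of the homogeneous model to GMFI series.

The homogeneous model ignores cell-to-cell variability: one (lam, beta, p)
for the whole population.  Q-channel GMFI summaries then follow

    GMFI_unquenched(t) = alpha1 * A(t)                     + E_Q + kappa1
    GMFI_quenched(t)   = alpha1 * (I(t) + (1-eta)*S(t))    + E_Q + kappa2

with independent Normal(0, sigma^2) measurement errors kappa per time point
and condition.  The quench efficiency eta is pre-estimated from the 4 C
control and the mean autofluorescence E_Q from the unstained control; the
remaining parameters theta = (lam, beta, p, alpha1, sigma) are estimated by
multi-start bounded maximum likelihood.  Confidence intervals come from the
observed Fisher information (the negative Hessian of the log-likelihood at
the optimum, by central differences).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import qmc

from . import dynamics
from .dynamics import KineticParams
from .measurement import Dataset, gmfi

__all__ = ["GmfiSeries", "HomogeneousFit", "homogeneous_loglik", "fit_homogeneous"]

PARAM_NAMES = ("lam", "beta", "p", "alpha1", "sigma")


@dataclass(frozen=True)
class GmfiSeries:
    """Q-channel GMFI observations: one value per time per condition."""

    times: np.ndarray
    unquenched: np.ndarray
    quenched: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        u = np.asarray(self.unquenched, dtype=float)
        q = np.asarray(self.quenched, dtype=float)
        if not (t.shape == u.shape == q.shape) or t.ndim != 1:
            raise ValueError("times, unquenched and quenched must match in shape")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "unquenched", u)
        object.__setattr__(self, "quenched", q)

    @classmethod
    def from_dataset(cls, ds: Dataset) -> "GmfiSeries":
        times = ds.times
        unq = [gmfi(ds.snapshot(t, "unquenched").Q) for t in times]
        qnc = [gmfi(ds.snapshot(t, "quenched").Q) for t in times]
        return cls(np.asarray(times), np.asarray(unq), np.asarray(qnc))


@dataclass(frozen=True)
class HomogeneousFit:
    """MLE result with Fisher-information uncertainty."""

    estimates: dict[str, float]
    covariance: np.ndarray
    ci95: dict[str, tuple[float, float]]
    loglik: float
    n_starts: int

    @property
    def kinetics(self) -> KineticParams:
        return KineticParams(
            self.estimates["lam"], self.estimates["beta"], self.estimates["p"]
        )

    def surface_fraction(self) -> float:
        """Equilibrium surface fraction S(0) = beta / (lam + beta) implied
        by the estimated rates."""
        return self.estimates["beta"] / (
            self.estimates["lam"] + self.estimates["beta"]
        )

    def to_frame(self) -> pd.DataFrame:
        units = {"lam": "min^-1", "beta": "min^-1", "p": "-",
                 "alpha1": "fluorescence units", "sigma": "fluorescence units"}
        rows = [
            {
                "parameter": name,
                "estimate": self.estimates[name],
                "ci_lo": self.ci95[name][0],
                "ci_hi": self.ci95[name][1],
                "units": units[name],
            }
            for name in PARAM_NAMES
        ]
        return pd.DataFrame(rows)


def _model_curves(
    lam: float, beta: float, p: float, alpha1: float,
    times: np.ndarray, E_Q: float, eta: float,
) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(times)  # data may arrive in any time order
    inv = np.argsort(order)
    traj = dynamics.solve(KineticParams(lam, beta, p), times[order])
    unq = (alpha1 * traj.A + E_Q)[inv]
    qnc = (alpha1 * (traj.I + (1.0 - eta) * traj.S) + E_Q)[inv]
    return unq, qnc


def homogeneous_loglik(
    theta, data: GmfiSeries, E_Q: float, eta: float = 0.94
) -> float:
    """Gaussian log-likelihood of a GMFI series under the homogeneous model.

    ``theta = (lam, beta, p, alpha1, sigma)``.  Invalid parameter values
    return ``-inf`` so that optimizers treat them as infeasible.
    """
    lam, beta, p, alpha1, sigma = (float(v) for v in theta)
    if sigma <= 0 or lam < 0 or beta < 0 or not 0 <= p <= 1 or alpha1 <= 0:
        return -np.inf
    if lam + beta <= 0:
        return -np.inf
    unq, qnc = _model_curves(lam, beta, p, alpha1, data.times, E_Q, eta)
    resid = np.concatenate([data.unquenched - unq, data.quenched - qnc])
    n = resid.size
    return float(
        -0.5 * n * np.log(2.0 * np.pi * sigma**2)
        - 0.5 * np.sum(resid**2) / sigma**2
    )


def _central_hessian(f, x: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian of scalar function ``f`` at ``x``."""
    d = x.size
    h = rel_step * np.maximum(np.abs(x), 1e-8)
    H = np.empty((d, d))
    f0 = f(x)
    for i in range(d):
        ei = np.zeros(d); ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h[i] ** 2
        for j in range(i + 1, d):
            ej = np.zeros(d); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def fit_homogeneous(
    data: GmfiSeries,
    E_Q: float,
    eta: float = 0.94,
    starts: int = 20,
    seed: int | np.random.Generator | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
    compute_ci: bool = True,
) -> HomogeneousFit:
    """Multi-start bounded MLE of the homogeneous model.

    Starting points are a Latin-hypercube sample of the bound box; the best
    converged optimum wins (ties by first found).  Raises if no start
    converges or if the observed Fisher information at the optimum is not
    positive definite (in which case the reported intervals would be
    meaningless).
    """
    if data.times.size < 2:
        raise ValueError("need at least 2 time points")
    gmax = float(max(data.unquenched.max(), data.quenched.max()))
    default_bounds = {
        "lam": (1e-4, 1.0),
        "beta": (1e-4, 1.0),
        "p": (1e-6, 1.0),
        "alpha1": (gmax * 0.05, gmax * 5.0),
        "sigma": (gmax * 1e-5, gmax),
    }
    if bounds:
        default_bounds.update(bounds)
    lo = np.array([default_bounds[n][0] for n in PARAM_NAMES])
    hi = np.array([default_bounds[n][1] for n in PARAM_NAMES])

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sampler = qmc.LatinHypercube(d=len(PARAM_NAMES), seed=rng)
    x0s = lo + sampler.random(starts) * (hi - lo)

    def nll(x):
        ll = homogeneous_loglik(x, data, E_Q, eta)
        return np.inf if not np.isfinite(ll) else -ll

    best = None
    diagnostics = []
    for x0 in x0s:
        res = minimize(
            nll, x0, method="L-BFGS-B",
            bounds=list(zip(lo, hi)),
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-10},
        )
        diagnostics.append((res.success, res.fun))
        if res.success and np.isfinite(res.fun):
            if best is None or res.fun < best.fun:
                best = res
    if best is None:
        raise RuntimeError(
            f"no optimizer start converged; diagnostics: {diagnostics}"
        )

    xhat = best.x
    estimates = dict(zip(PARAM_NAMES, (float(v) for v in xhat)))
    if compute_ci:
        # Small-sample correction: the MLE of sigma divides the residual sum
        # of squares by n rather than n - 4 (four mean-function parameters),
        # which would shrink every interval.  The information matrix is
        # evaluated at the degrees-of-freedom-corrected noise scale.
        n_obs = 2 * data.times.size
        x_info = xhat.copy()
        x_info[PARAM_NAMES.index("sigma")] *= np.sqrt(n_obs / max(n_obs - 4, 1))
        H = _central_hessian(
            lambda x: homogeneous_loglik(x, data, E_Q, eta), x_info
        )
        info = -H  # observed Fisher information
        try:
            np.linalg.cholesky(info)
        except np.linalg.LinAlgError as err:
            raise RuntimeError(
                "observed Fisher information is not positive definite at the "
                f"optimum {estimates}"
            ) from err
        cov = np.linalg.inv(info)
        se = np.sqrt(np.diag(cov))
        ci95 = {
            name: (float(xhat[i] - 1.96 * se[i]), float(xhat[i] + 1.96 * se[i]))
            for i, name in enumerate(PARAM_NAMES)
        }
    else:
        # degenerate request (e.g. noise-free fixtures where sigma -> 0):
        # intervals collapse to the point estimate
        cov = np.full((len(PARAM_NAMES),) * 2, np.nan)
        ci95 = {name: (estimates[name], estimates[name]) for name in PARAM_NAMES}
    return HomogeneousFit(
        estimates=estimates,
        covariance=cov,
        ci95=ci95,
        loglik=float(-best.fun),
        n_starts=starts,
    )
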