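"""Cell-to-cell variability model: marginals plus a Gaussian copula.

Each cell i is characterized by xi_i = (R_i, lam_i, beta_i): its relative
receptor count and its internalization and recycling rates.  Marginally,

* R is shifted log-normal with the shift fixed so that E(R) = 1 (receptor
  counts are expressed relative to the population mean), and
* lam and beta are shifted Gamma variables parametrized by mean, standard
  deviation and skewness (mu, sigma, omega), recovering a normal
  distribution in the limit omega -> 0.

Dependence is modelled by a Gaussian copula whose 3x3 correlation matrix is
parametrized by (rho_Rlam, rho_lambeta, rho_tilde_Rbeta), the last being a
partial-correlation-style parameter that keeps the matrix positive definite
for any values in the open cube (-1, 1)^3.  Sampled triples with any
negative component are rejected and redrawn, so accepted cells always have
non-negative receptor counts and rates.

The disassociation probability p is a chemical property shared by all cells.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
from scipy.special import gammaincinv, ndtr, ndtri

from .dynamics import KineticParams

__all__ = [
    "PopulationParams",
    "CellProperties",
    "shifted_gamma_quantile",
    "receptor_quantile",
    "build_correlation_matrix",
    "implied_rho_Rbeta",
    "sample_cell_arrays",
    "sample_cells",
]

#: below this |omega| the shifted-Gamma quantile switches to its normal limit
#: (the Gamma shape 4/omega^2 would otherwise overflow)
SKEWNESS_NORMAL_THRESHOLD = 1e-3


@dataclass(frozen=True)
class PopulationParams:
    """Hyperparameters of the cell-property distribution.

    ``mu_R``/``sigma_R`` are the log-scale parameters of the shifted
    log-normal receptor-count marginal; ``mu_*``/``sigma_*``/``omega_*`` are
    mean (min^-1), SD (min^-1) and skewness of the rate marginals; the three
    ``rho`` parameters determine the copula correlation matrix; ``p`` is the
    shared disassociation probability.
    """

    mu_R: float
    sigma_R: float
    mu_lam: float
    sigma_lam: float
    omega_lam: float
    mu_beta: float
    sigma_beta: float
    omega_beta: float
    rho_Rlam: float = 0.0
    rho_lambeta: float = 0.0
    rho_tilde_Rbeta: float = 0.0
    p: float = 0.0

    def __post_init__(self) -> None:
        if min(self.sigma_R, self.sigma_lam, self.sigma_beta) < 0:
            raise ValueError("standard deviations must be non-negative")
        for name in ("rho_Rlam", "rho_lambeta", "rho_tilde_Rbeta"):
            if not -1.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie in the open interval (-1, 1)")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must lie in [0, 1]")

    def correlation_matrix(self) -> np.ndarray:
        return build_correlation_matrix(
            self.rho_Rlam, self.rho_lambeta, self.rho_tilde_Rbeta
        )

    def to_dict(self) -> dict[str, float]:
        """Flat key-value form for configs and manifests."""
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "PopulationParams":
        names = {f.name for f in fields(cls)}
        return cls(**{k: float(v) for k, v in d.items() if k in names})


@dataclass(frozen=True)
class CellProperties:
    """Sampled properties of one cell."""

    R: float
    k: KineticParams


def shifted_gamma_quantile(
    u: np.ndarray, mu: float, sigma: float, omega: float
) -> np.ndarray:
    """Quantile of the shifted Gamma distribution with mean ``mu``, SD
    ``sigma`` and skewness ``omega``.

    A Gamma with shape k = 4/omega^2 and scale theta = sigma*|omega|/2 has SD
    ``sigma`` and skewness ``|omega|``; shifting by its mean k*theta and, for
    omega < 0, mirroring, gives the stated three first moments.  For
    |omega| below :data:`SKEWNESS_NORMAL_THRESHOLD` the Normal(mu, sigma)
    quantile is returned (the omega -> 0 limit).
    """
    u = np.asarray(u, dtype=float)
    if np.any((u <= 0) | (u >= 1)):
        raise ValueError("u must lie strictly between 0 and 1")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return np.full_like(u, mu)
    if abs(omega) < SKEWNESS_NORMAL_THRESHOLD:
        return mu + sigma * ndtri(u)
    shape = 4.0 / omega**2
    scale = sigma * abs(omega) / 2.0
    u_eff = u if omega > 0 else 1.0 - u
    g = gammaincinv(shape, u_eff) * scale
    return mu + np.sign(omega) * (g - shape * scale)


def receptor_quantile(u: np.ndarray, mu_R: float, sigma_R: float) -> np.ndarray:
    """Quantile of the shifted log-normal receptor-count distribution.

    The shift ``s = 1 - exp(mu_R + sigma_R^2/2)`` pins the untruncated mean
    at exactly 1, so receptor counts are relative to the population average.
    """
    u = np.asarray(u, dtype=float)
    if np.any((u <= 0) | (u >= 1)):
        raise ValueError("u must lie strictly between 0 and 1")
    if sigma_R < 0:
        raise ValueError("sigma_R must be non-negative")
    shift = 1.0 - np.exp(mu_R + 0.5 * sigma_R**2)
    return shift + np.exp(mu_R + sigma_R * ndtri(u))


def implied_rho_Rbeta(
    rho_Rlam: float, rho_lambeta: float, rho_tilde_Rbeta: float
) -> float:
    """Receptor-recycling correlation implied by the partial-correlation
    parametrization of the copula matrix."""
    return float(
        rho_Rlam * rho_lambeta
        + rho_tilde_Rbeta * np.sqrt((1.0 - rho_Rlam**2) * (1.0 - rho_lambeta**2))
    )


def build_correlation_matrix(
    rho_Rlam: float, rho_lambeta: float, rho_tilde_Rbeta: float
) -> np.ndarray:
    """Copula correlation matrix for (R, lam, beta).

    The receptor-recycling entry is derived from the partial-correlation
    parametrization

        rho_Rbeta = rho_Rlam*rho_lambeta
                    + rho_tilde_Rbeta*sqrt((1-rho_Rlam^2)*(1-rho_lambeta^2)),

    which guarantees positive definiteness over the whole open cube.
    """
    for name, val in (
        ("rho_Rlam", rho_Rlam),
        ("rho_lambeta", rho_lambeta),
        ("rho_tilde_Rbeta", rho_tilde_Rbeta),
    ):
        if not -1.0 < val < 1.0:
            raise ValueError(f"{name} must lie in the open interval (-1, 1)")
    rho_Rbeta = implied_rho_Rbeta(rho_Rlam, rho_lambeta, rho_tilde_Rbeta)
    return np.array(
        [
            [1.0, rho_Rlam, rho_Rbeta],
            [rho_Rlam, 1.0, rho_lambeta],
            [rho_Rbeta, rho_lambeta, 1.0],
        ]
    )


def _marginal_from_scores(
    z: np.ndarray, mu: float, sigma: float, omega: float
) -> np.ndarray:
    """Rate marginal evaluated at standard-normal copula scores ``z``.

    In the normal-limit branch the quantile transform
    ``F^{-1}(Phi(z)) = mu + sigma*z`` is applied directly, avoiding the
    CDF/quantile round trip (this is the hot path of the ABC simulator).
    """
    if sigma == 0:
        return np.full_like(z, mu)
    if abs(omega) < SKEWNESS_NORMAL_THRESHOLD:
        return mu + sigma * z
    return shifted_gamma_quantile(_scores_to_uniform(z), mu, sigma, omega)


def _scores_to_uniform(z: np.ndarray) -> np.ndarray:
    u = ndtr(z)
    tiny = np.finfo(float).tiny
    return np.clip(u, tiny, 1.0 - np.finfo(float).epsneg)


def sample_cell_arrays(
    pp: PopulationParams,
    n: int,
    rng: np.random.Generator,
    min_acceptance: float = 1e-3,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw ``n`` accepted cells; returns arrays ``(R, lam, beta)``.

    Correlated standard-normal triples are transformed through the marginal
    quantile functions; any triple with a negative component is rejected and
    the whole triple redrawn, preserving the copula dependence among
    accepted cells.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    chol = np.linalg.cholesky(pp.correlation_matrix())
    out_R = np.empty(n)
    out_lam = np.empty(n)
    out_beta = np.empty(n)
    filled = 0
    drawn = 0
    while filled < n:
        # 25% headroom so mild truncation is absorbed in a single pass
        m = max(int((n - filled) * 1.25) + 32, 128)
        z = chol @ rng.standard_normal((3, m))
        drawn += m
        if pp.sigma_R == 0:
            R = np.ones(m)
        else:
            shift = 1.0 - np.exp(pp.mu_R + 0.5 * pp.sigma_R**2)
            R = shift + np.exp(pp.mu_R + pp.sigma_R * z[0])
        lam = _marginal_from_scores(z[1], pp.mu_lam, pp.sigma_lam, pp.omega_lam)
        beta = _marginal_from_scores(z[2], pp.mu_beta, pp.sigma_beta, pp.omega_beta)
        ok = (R >= 0) & (lam >= 0) & (beta >= 0)
        k = int(ok.sum())
        take = min(k, n - filled)
        idx = np.flatnonzero(ok)[:take]
        out_R[filled : filled + take] = R[idx]
        out_lam[filled : filled + take] = lam[idx]
        out_beta[filled : filled + take] = beta[idx]
        filled += take
        if drawn >= 2000 and filled / drawn < min_acceptance:
            raise RuntimeError(
                "truncation acceptance rate below "
                f"{min_acceptance:g}; pathological population parameters"
            )
    return out_R, out_lam, out_beta


def sample_cells(
    pp: PopulationParams, n: int, seed: int | np.random.Generator | None = None
) -> list[CellProperties]:
    """Sample ``n`` cells as :class:`CellProperties` (reproducible under seed)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    R, lam, beta = sample_cell_arrays(pp, n, rng)
    return [
        CellProperties(R=float(r), k=KineticParams(float(l), float(b), pp.p))
        for r, l, b in zip(R, lam, beta)
    ]
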