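"""Flow-cytometry observation model and GMFI summaries.

A cell in state (T, S, E, F) with relative receptor count R produces a true
signal in two channels:

* Q-channel (quenchable probe): ``alpha1 * A * R`` in unquenched samples, or
  ``alpha1 * (I + (1 - eta) * S) * R`` in quenched samples, where ``eta`` is
  the quench efficiency (the fraction of surface-probe fluorescence removed
  by the quencher dye);
* U-channel (unquenchable probe): ``alpha2 * A * R`` in both conditions.

Observed fluorescence adds photomultiplier shot noise — multiplicative,
mean-zero Gaussian with constant coefficient of variation — and a cellular
autofluorescence background drawn jointly (per cell, both channels at once)
from an empirical control sample of cells never exposed to labelled
antibody.  Observed values can legitimately dip below zero, as real
cytometry output does after amplification.

The geometric mean fluorescence intensity (GMFI) is the field's standard
scalar summary; non-positive values are excluded from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd

__all__ = [
    "MeasurementParams",
    "AutofluorescenceSample",
    "Snapshot",
    "Dataset",
    "observe_cell",
    "observe_signals",
    "true_signals",
    "gmfi",
    "estimate_quench_efficiency",
]

Condition = Literal["quenched", "unquenched"]


@dataclass(frozen=True)
class MeasurementParams:
    """Channel scalings, quench efficiency and noise magnitudes.

    ``alpha1``/``alpha2`` convert antibody-per-receptor units into
    fluorescence units for the Q- and U-channels; ``eta`` in [0, 1] is the
    quench efficiency; ``sigma1``/``sigma2`` are the channel noise
    coefficients of variation.  ``noise_mode`` selects the shot-noise law:
    ``"cv"`` (default) keeps the squared coefficient of variation constant
    (observed = true*(1 + eps)); ``"sqrt"`` makes the noise variance
    proportional to the true signal (observed = true + eps*sqrt(true)).
    """

    alpha1: float
    alpha2: float
    eta: float
    sigma1: float = 0.0
    sigma2: float = 0.0
    noise_mode: Literal["cv", "sqrt"] = "cv"

    def __post_init__(self) -> None:
        if self.alpha1 <= 0 or self.alpha2 <= 0:
            raise ValueError("channel scales alpha1, alpha2 must be positive")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("quench efficiency eta must lie in [0, 1]")
        if self.sigma1 < 0 or self.sigma2 < 0:
            raise ValueError("noise magnitudes must be non-negative")
        if self.noise_mode not in ("cv", "sqrt"):
            raise ValueError("noise_mode must be 'cv' or 'sqrt'")


@dataclass(frozen=True)
class AutofluorescenceSample:
    """Paired (E_Q, E_U) background fluorescence from an unstained control."""

    EQ: np.ndarray
    EU: np.ndarray

    def __post_init__(self) -> None:
        EQ = np.asarray(self.EQ, dtype=float)
        EU = np.asarray(self.EU, dtype=float)
        if EQ.shape != EU.shape or EQ.ndim != 1:
            raise ValueError("EQ and EU must be 1-d arrays of equal length")
        if not (np.all(np.isfinite(EQ)) and np.all(np.isfinite(EU))):
            raise ValueError("autofluorescence values must be finite")
        if EQ.size < 100:
            raise ValueError("need at least 100 control cells for resampling")
        object.__setattr__(self, "EQ", EQ)
        object.__setattr__(self, "EU", EU)

    @property
    def n(self) -> int:
        return self.EQ.size

    def resample(self, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """Draw ``n`` whole (E_Q, E_U) pairs with replacement, preserving the
        empirical between-channel dependence."""
        idx = rng.integers(0, self.n, size=n)
        return self.EQ[idx], self.EU[idx]

    def gmfi_Q(self) -> float:
        return gmfi(self.EQ)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"EQ": self.EQ, "EU": self.EU})

    @classmethod
    def from_csv(cls, path: str | Path) -> "AutofluorescenceSample":
        df = pd.read_csv(path)
        return cls(EQ=df["EQ"].to_numpy(), EU=df["EU"].to_numpy())


@dataclass(frozen=True)
class Snapshot:
    """Paired two-channel fluorescence of one (time, condition) sample."""

    time: float
    condition: Condition
    Q: np.ndarray
    U: np.ndarray

    def __post_init__(self) -> None:
        Q = np.asarray(self.Q, dtype=float)
        U = np.asarray(self.U, dtype=float)
        if Q.shape != U.shape or Q.ndim != 1:
            raise ValueError("Q and U must be 1-d arrays of equal length")
        if self.time < 0:
            raise ValueError("time must be non-negative")
        object.__setattr__(self, "Q", Q)
        object.__setattr__(self, "U", U)

    @property
    def n(self) -> int:
        return self.Q.size


@dataclass
class Dataset:
    """All snapshots of one experiment plus its control samples.

    ``quench_control`` holds the (quenched GMFI, unquenched GMFI) pair from
    the 4 C control in the Q-channel.  ``truth`` optionally records the
    generating parameters and per-cell latents of a synthetic dataset.
    """

    snapshots: list[Snapshot]
    autofluorescence: AutofluorescenceSample | None = None
    quench_control: tuple[float, float] | None = None
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = self.times
        for t in times:
            conds = {s.condition for s in self.snapshots if s.time == t}
            if conds != {"quenched", "unquenched"}:
                raise ValueError(f"both conditions required at time {t}")

    @property
    def times(self) -> list[float]:
        return sorted({s.time for s in self.snapshots})

    def snapshot(self, time: float, condition: Condition) -> Snapshot:
        for s in self.snapshots:
            if s.time == time and s.condition == condition:
                return s
        raise KeyError(f"no snapshot at ({time}, {condition})")

    def structure(self) -> list[tuple[float, str]]:
        return [(s.time, s.condition) for s in self.snapshots]

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per cell (columns time_min, condition, Q, U)."""
        parts = [
            pd.DataFrame(
                {
                    "time_min": s.time,
                    "condition": s.condition,
                    "Q": s.Q,
                    "U": s.U,
                }
            )
            for s in self.snapshots
        ]
        return pd.concat(parts, ignore_index=True)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        autofluorescence: AutofluorescenceSample | None = None,
        quench_control: tuple[float, float] | None = None,
    ) -> "Dataset":
        snaps = []
        for (t, cond), grp in df.groupby(["time_min", "condition"], sort=True):
            snaps.append(
                Snapshot(
                    time=float(t),
                    condition=str(cond),
                    Q=grp["Q"].to_numpy(),
                    U=grp["U"].to_numpy(),
                )
            )
        return cls(snaps, autofluorescence, quench_control)

    @classmethod
    def from_csv(
        cls,
        path: str | Path,
        autofluorescence: AutofluorescenceSample | None = None,
        quench_control: tuple[float, float] | None = None,
    ) -> "Dataset":
        return cls.from_frame(pd.read_csv(path), autofluorescence, quench_control)


def true_signals(
    A: np.ndarray,
    I: np.ndarray,
    S: np.ndarray,
    R: np.ndarray,
    mp: MeasurementParams,
    condition: Condition,
) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free (Q, U) signals for cells with the given state and R."""
    if condition == "unquenched":
        q_sig = mp.alpha1 * A * R
    elif condition == "quenched":
        q_sig = mp.alpha1 * (I + (1.0 - mp.eta) * S) * R
    else:
        raise ValueError(f"unknown condition {condition!r}")
    u_sig = mp.alpha2 * A * R
    return q_sig, u_sig


def observe_signals(
    A: np.ndarray,
    I: np.ndarray,
    S: np.ndarray,
    R: np.ndarray,
    mp: MeasurementParams,
    condition: Condition,
    af_Q: np.ndarray,
    af_U: np.ndarray,
    eps1: np.ndarray,
    eps2: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized observation: shot noise plus autofluorescence.

    ``eps1``/``eps2`` are standard-normal draws (one per cell per channel);
    they are scaled by ``sigma1``/``sigma2`` here so that callers can manage
    the random stream in bulk.
    """
    q_sig, u_sig = true_signals(A, I, S, R, mp, condition)
    if mp.noise_mode == "cv":
        Q = q_sig * (1.0 + mp.sigma1 * eps1) + af_Q
        U = u_sig * (1.0 + mp.sigma2 * eps2) + af_U
    else:  # variance proportional to the true signal
        Q = q_sig + mp.sigma1 * np.sqrt(np.maximum(q_sig, 0.0)) * eps1 + af_Q
        U = u_sig + mp.sigma2 * np.sqrt(np.maximum(u_sig, 0.0)) * eps2 + af_U
    return Q, U


def observe_cell(
    cell,
    state,
    mp: MeasurementParams,
    condition: Condition,
    af_pair: tuple[float, float],
    noise_draws: tuple[float, float],
) -> tuple[float, float]:
    """Observe a single cell (scalar convenience wrapper).

    ``state`` is a :class:`~endokin.dynamics.CompartmentState` solved for
    this cell's kinetic parameters; ``af_pair`` is one jointly drawn
    autofluorescence pair; ``noise_draws`` are standard-normal draws.
    """
    A = state.S + state.E + state.F
    I = state.E + state.F
    Q, U = observe_signals(
        np.asarray(A), np.asarray(I), np.asarray(state.S), np.asarray(cell.R),
        mp, condition,
        np.asarray(af_pair[0]), np.asarray(af_pair[1]),
        np.asarray(noise_draws[0]), np.asarray(noise_draws[1]),
    )
    return float(Q), float(U)


def gmfi(values: Iterable[float], return_excluded: bool = False):
    """Geometric mean fluorescence intensity of the positive values.

    Non-positive values (possible after noise and background subtraction)
    are excluded; ``return_excluded=True`` additionally reports how many
    were dropped.
    """
    v = np.asarray(values, dtype=float)
    pos = v[v > 0]
    if pos.size == 0:
        raise ValueError("no positive values; GMFI undefined")
    g = float(np.exp(np.mean(np.log(pos))))
    if return_excluded:
        return g, int(v.size - pos.size)
    return g


def estimate_quench_efficiency(
    q_gmfi_4C: float, u_gmfi_4C: float, af_gmfi: float
) -> float:
    """Quench efficiency from the 4 C control.

    With internalization inhibited all antibody is surface-bound, so after
    background correction the quenched/unquenched GMFI ratio estimates the
    unquenched fraction 1 - eta:

        eta = 1 - (Q_4C - af) / (U_4C - af),

    clamped to [0, 1].  ``u_gmfi_4C`` is the unquenched Q-channel GMFI and
    ``af_gmfi`` the Q-channel autofluorescence GMFI.
    """
    if u_gmfi_4C <= af_gmfi:
        raise ValueError("unquenched 4C GMFI must exceed the autofluorescence GMFI")
    eta = 1.0 - (q_gmfi_4C - af_gmfi) / (u_gmfi_4C - af_gmfi)
    return float(min(1.0, max(0.0, eta)))
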