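"""Core domain types, the exponential (Boltzmann) basis, and objective functions.

A composite physical signal measured at times ``t_1 < ... < t_M`` is modelled
as a non-negative combination of exponential decays::

    I_j = sum_r h_r * exp(-t_j / tau_r)

where ``tau_r > 0`` is the time constant of the r-th component (a diffusion or
energy-transfer time) and ``h_r >= 0`` its weight.  A set of N such sequences
forms an M x N matrix factorized as ``I ~ W H`` with the basis columns
constrained to the decay shape ``w_jr = exp(-t_j / tau_r)``.

Two goodness-of-fit objectives are supported: the plain sum of squared errors
(Gaussian noise model) and the generalized Kullback-Leibler (I-) divergence
(Poisson noise model).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

#: Floor applied to divisors and logarithm arguments in the KL objective and
#: the multiplicative update rules.
EPS = 1e-12


class ObjectiveKind(Enum):
    """Which divergence the factorization minimizes."""

    LSE = "lse"
    KL = "kl"


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class TimeGrid:
    """Strictly positive, strictly increasing measurement times ``t_1..t_M``."""

    times: np.ndarray

    def __post_init__(self) -> None:
        times = _as_float_array(self.times, "times")
        if times.ndim != 1:
            raise ValueError("times must be a 1-D vector")
        if times.size < 2:
            raise ValueError("a time grid needs at least two points")
        if np.any(times <= 0):
            raise ValueError("all measurement times must be strictly positive")
        if np.any(np.diff(times) <= 0):
            raise ValueError("measurement times must be strictly increasing")
        object.__setattr__(self, "times", times)

    def __len__(self) -> int:
        return self.times.size

    @property
    def n_times(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class SignalMatrix:
    """M x N matrix of signal intensities on a shared time grid.

    Rows are time points, columns are measured (or simulated) sequences.
    The underlying signal model is non-negative; by default negative entries
    are rejected.  Measured or simulated intensities can dip slightly below
    zero through additive noise, so ``allow_negative=True`` admits them —
    the factorization itself (basis and coefficients) stays non-negative
    either way, and the KL objective treats sub-zero dips as zero counts.
    """

    values: np.ndarray
    grid: TimeGrid
    allow_negative: bool = False

    def __post_init__(self) -> None:
        values = _as_float_array(self.values, "values")
        if values.ndim != 2:
            raise ValueError("signal values must form a 2-D matrix")
        if values.shape[0] != len(self.grid):
            raise ValueError(
                f"matrix has {values.shape[0]} rows but the grid has "
                f"{len(self.grid)} time points"
            )
        if values.shape[1] < 1:
            raise ValueError("at least one signal sequence is required")
        if not self.allow_negative and np.any(values < 0):
            j, i = np.argwhere(values < 0)[0]
            raise ValueError(f"negative intensity at row {j}, column {i}")
        object.__setattr__(self, "values", values)

    @property
    def n_times(self) -> int:
        return self.values.shape[0]

    @property
    def n_sequences(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class Factorization:
    """A rank-R decay model: time constants plus per-sequence coefficients.

    ``coeffs[r, i]`` is the weight of component r in sequence i; the basis is
    derived from ``taus`` and ``grid`` rather than stored.
    """

    taus: np.ndarray
    coeffs: np.ndarray
    grid: TimeGrid

    def __post_init__(self) -> None:
        taus = _as_float_array(self.taus, "taus")
        coeffs = _as_float_array(self.coeffs, "coeffs")
        if taus.ndim != 1 or taus.size < 1:
            raise ValueError("taus must be a non-empty 1-D vector")
        if np.any(taus <= 0):
            raise ValueError("all time constants must be strictly positive")
        if coeffs.ndim != 2 or coeffs.shape[0] != taus.size:
            raise ValueError("coeffs must be an R x N matrix matching taus")
        if np.any(coeffs < 0):
            raise ValueError("coefficients must be non-negative")
        object.__setattr__(self, "taus", taus)
        object.__setattr__(self, "coeffs", coeffs)

    @property
    def rank(self) -> int:
        return self.taus.size

    @property
    def n_sequences(self) -> int:
        return self.coeffs.shape[1]

    @property
    def is_canonical(self) -> bool:
        return bool(np.all(np.diff(self.taus) >= 0))

    def canonical(self) -> "Factorization":
        """Reorder components by ascending tau (ties: descending mean weight).

        Components are conventionally listed fast to slow; the tie-break keeps
        the ordering deterministic when two components collapse onto the same
        time constant.
        """
        order = np.lexsort((-self.coeffs.mean(axis=1), self.taus))
        return Factorization(self.taus[order], self.coeffs[order], self.grid)


def basis_matrix(taus, grid: TimeGrid) -> np.ndarray:
    """Exponential-decay basis ``w_jr = exp(-t_j / tau_r)`` (M x R)."""
    taus = _as_float_array(taus, "taus")
    if taus.ndim != 1 or taus.size < 1:
        raise ValueError("taus must be a non-empty 1-D vector")
    if np.any(taus <= 0):
        raise ValueError("all time constants must be strictly positive")
    return np.exp(-grid.times[:, None] / taus[None, :])


def reconstruct(f: Factorization) -> np.ndarray:
    """Model reconstruction ``W H`` (M x N)."""
    return basis_matrix(f.taus, f.grid) @ f.coeffs


def _check_shapes(I: SignalMatrix, f: Factorization) -> None:
    if I.n_times != len(f.grid) or not np.array_equal(I.grid.times, f.grid.times):
        raise ValueError("signal matrix and factorization use different time grids")
    if f.coeffs.shape[1] != I.n_sequences:
        raise ValueError(
            f"factorization has {f.coeffs.shape[1]} sequences, "
            f"signal matrix has {I.n_sequences}"
        )


def lse_objective(I: SignalMatrix, f: Factorization) -> float:
    """Sum of squared residuals ``sum_ji (I_ji - (WH)_ji)**2``."""
    _check_shapes(I, f)
    resid = I.values - reconstruct(f)
    return float(np.sum(resid * resid))


def kl_objective(I: SignalMatrix, f: Factorization) -> float:
    """Generalized KL (I-) divergence ``sum_ji I ln(I/WH) - I + WH``.

    Uses the convention ``0 * ln(0/x) = 0``; model values are floored at
    :data:`EPS` so zero-coefficient components cannot produce infinities.
    Intensities below zero (noise dips) are treated as zero counts.
    """
    _check_shapes(I, f)
    wh = np.maximum(reconstruct(f), EPS)
    vals = np.maximum(I.values, 0.0)
    log_term = np.zeros_like(vals)
    pos = vals > 0
    log_term[pos] = vals[pos] * np.log(vals[pos] / wh[pos])
    return float(np.sum(log_term - vals + wh))


def objective_value(I: SignalMatrix, f: Factorization, kind: ObjectiveKind) -> float:
    if kind is ObjectiveKind.LSE:
        return lse_objective(I, f)
    return kl_objective(I, f)
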