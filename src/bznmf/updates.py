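"""Multiplicative update rules and the alternating fitting loop.

Both time constants and coefficients are optimized by multiplicative rules:
gradient descent with a per-parameter step width chosen so the update becomes
a non-negative rescaling, exactly as in classic NMF.  For the sum-of-squares
objective the rules are::

    tau_r <- tau_r * [sum_ji I_ji    h_ri t_j w_jr] / [sum_ji (WH)_ji h_ri t_j w_jr]
    h_ri  <- h_ri  * (W^T I)_ri / (W^T W H)_ri

and for the generalized KL divergence::

    tau_r <- tau_r * [sum_ji (I/WH)_ji h_ri t_j w_jr] / [sum_ji h_ri t_j w_jr]
    h_ri  <- h_ri  * [sum_j w_jr I_ji/(WH)_ji] / [sum_j w_jr]

Each rule is a fixed point at an exact fit and preserves positivity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import (
    EPS,
    Factorization,
    ObjectiveKind,
    SignalMatrix,
    basis_matrix,
    objective_value,
)

#: A component whose coefficient row sums below this is considered unused.
DEGENERATE_COEFF_SUM = 1e-12


@dataclass(frozen=True)
class FitConfig:
    """Knobs of the alternating fit.

    tau_floor / tau_ceiling clip the time constants each iteration; when left
    ``None`` they default to ``1e-3 * t_1`` and ``1e3 * t_M``, wide enough to
    never bind for genuine components but preventing unused components from
    drifting to 0 or infinity.
    """

    objective: ObjectiveKind = ObjectiveKind.LSE
    max_iterations: int = 5000
    rel_tolerance: float = 1e-8
    n_restarts: int = 3
    seed: int = 0
    tau_floor: float | None = None
    tau_ceiling: float | None = None

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if not (0 < self.rel_tolerance < 1):
            raise ValueError("rel_tolerance must lie in (0, 1)")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if (
            self.tau_floor is not None
            and self.tau_ceiling is not None
            and not (self.tau_floor < self.tau_ceiling)
        ):
            raise ValueError("tau_floor must be below tau_ceiling")

    def tau_bounds(self, grid) -> tuple[float, float]:
        lo = self.tau_floor if self.tau_floor is not None else 1e-3 * grid.times[0]
        hi = self.tau_ceiling if self.tau_ceiling is not None else 1e3 * grid.times[-1]
        return lo, hi


@dataclass
class FitResult:
    """Converged factorization plus its optimization trace."""

    factorization: Factorization
    objective_value: float
    objective_trace: np.ndarray
    iterations_run: int
    converged: bool
    restart_index: int
    degenerate_components: list[int] = field(default_factory=list)

    @property
    def rank(self) -> int:
        return self.factorization.rank


def update_coeffs_lse(I: SignalMatrix, f: Factorization) -> np.ndarray:
    W = basis_matrix(f.taus, f.grid)
    # numerator floored at 0: noise dips below zero cannot flip a weight's sign
    num = np.maximum(W.T @ I.values, 0.0)
    den = (W.T @ W) @ f.coeffs
    return f.coeffs * num / np.maximum(den, EPS)


def update_coeffs_kl(I: SignalMatrix, f: Factorization) -> np.ndarray:
    W = basis_matrix(f.taus, f.grid)
    wh = np.maximum(W @ f.coeffs, EPS)
    num = W.T @ (np.maximum(I.values, 0.0) / wh)
    den = W.sum(axis=0)[:, None]
    return f.coeffs * num / np.maximum(den, EPS)


def _tau_update(num: np.ndarray, den: np.ndarray, f: Factorization,
                floor: float, ceiling: float) -> np.ndarray:
    ratio = np.ones_like(f.taus)
    ok = den > EPS
    ratio[ok] = num[ok] / den[ok]
    # unused components (den ~ 0) keep their tau unchanged
    return np.clip(f.taus * ratio, floor, ceiling)


def update_taus_lse(
    I: SignalMatrix,
    f: Factorization,
    tau_floor: float = 0.0,
    tau_ceiling: float = np.inf,
) -> np.ndarray:
    """One multiplicative step on every time constant (LSE objective).

    Derived from gradient descent with step width
    ``eta_r = tau_r**3 / (2 sum_ji (WH)_ji h_ri w_jr t_j)`` applied to
    ``dD/dtau_r = -2 sum_ji (I - WH)_ji h_ri w_jr t_j / tau_r**2``.
    """
    W = basis_matrix(f.taus, f.grid)
    A = f.grid.times[:, None] * W  # t_j * w_jr
    num = np.maximum(np.sum(A * (I.values @ f.coeffs.T), axis=0), 0.0)
    den = np.sum(A * ((W @ f.coeffs) @ f.coeffs.T), axis=0)
    return _tau_update(num, den, f, tau_floor, tau_ceiling)


def update_taus_kl(
    I: SignalMatrix,
    f: Factorization,
    tau_floor: float = 0.0,
    tau_ceiling: float = np.inf,
) -> np.ndarray:
    """One multiplicative step on every time constant (KL objective).

    Derived from ``dD/dtau_r = sum_ji (1 - I/WH)_ji h_ri w_jr t_j / tau_r**2``
    with step width ``eta_r = tau_r**3 / sum_ji h_ri w_jr t_j``.
    """
    W = basis_matrix(f.taus, f.grid)
    wh = np.maximum(W @ f.coeffs, EPS)
    A = f.grid.times[:, None] * W
    num = np.sum(A * ((np.maximum(I.values, 0.0) / wh) @ f.coeffs.T), axis=0)
    den = np.sum(A, axis=0) * f.coeffs.sum(axis=1)
    return _tau_update(num, den, f, tau_floor, tau_ceiling)


def lse_tau_gradient(I: SignalMatrix, f: Factorization) -> np.ndarray:
    """Analytic ``dD/dtau_r`` for the sum-of-squares objective."""
    W = basis_matrix(f.taus, f.grid)
    resid = I.values - W @ f.coeffs
    A = f.grid.times[:, None] * W
    return -2.0 * np.sum(A * (resid @ f.coeffs.T), axis=0) / f.taus**2


def kl_tau_gradient(I: SignalMatrix, f: Factorization) -> np.ndarray:
    """Analytic ``dD/dtau_r`` for the generalized KL divergence."""
    W = basis_matrix(f.taus, f.grid)
    wh = np.maximum(W @ f.coeffs, EPS)
    A = f.grid.times[:, None] * W
    vals = np.maximum(I.values, 0.0)
    return np.sum(A * ((1.0 - vals / wh) @ f.coeffs.T), axis=0) / f.taus**2


_UPDATERS = {
    ObjectiveKind.LSE: (update_taus_lse, update_coeffs_lse),
    ObjectiveKind.KL: (update_taus_kl, update_coeffs_kl),
}


def signal_span(I: SignalMatrix, mass_fraction: float = 0.999) -> float:
    """Time by which the mean sequence has accumulated ``mass_fraction`` of
    its total intensity.

    Decaying signals go dark well before the last measurement time on a
    log-spaced grid; time constants initialized beyond this point start in a
    region the signal does not constrain.  Averaging over sequences cancels
    zero-mean noise, so the cumulative mass curve flattens once the true
    components have decayed.
    """
    mean_seq = I.values.mean(axis=1)
    total = mean_seq.sum()
    if total <= 0:
        return float(I.grid.times[-1])
    cum = np.cumsum(mean_seq) / total
    idx = int(np.argmax(cum >= mass_fraction))
    return float(I.grid.times[idx])


def initial_taus(
    I: SignalMatrix, rank: int, rng: np.random.Generator, spaced: bool = True
) -> np.ndarray:
    """Starting time constants confined to the signal-active time range.

    ``spaced=True`` places them log-equidistantly strictly inside
    ``[t_1, t_eff]`` (the interior points of a grid with two extra knots, so
    no component starts pinned to an endpoint); otherwise they are drawn
    log-uniformly over the same range.  Confining the start to where the
    signal actually lives keeps surplus components competing for real
    structure instead of wandering into the pure-noise tail.
    """
    lo = math.log10(I.grid.times[0])
    hi = math.log10(max(signal_span(I), I.grid.times[0] * 10.0))
    if spaced:
        return np.logspace(lo, hi, rank + 2)[1:-1]
    return np.sort(10.0 ** rng.uniform(lo, hi, size=rank))


def initial_factorization(
    I: SignalMatrix, rank: int, rng: np.random.Generator, spaced: bool = True
) -> Factorization:
    """Draw starting taus and uniform coefficients rescaled to the data.

    Coefficients start uniform on (0.1, 1), rescaled per sequence so the
    initial model matches each sequence's summed intensity.
    """
    taus = initial_taus(I, rank, rng, spaced=spaced)
    coeffs = rng.uniform(0.1, 1.0, size=(rank, I.n_sequences))
    model_sums = basis_matrix(taus, I.grid) @ coeffs
    scale = np.maximum(I.values.sum(axis=0), 0.0) / np.maximum(
        model_sums.sum(axis=0), EPS
    )
    return Factorization(taus, coeffs * scale[None, :], I.grid)


def _run_single(
    I: SignalMatrix, f: Factorization, config: FitConfig
) -> tuple[Factorization, list[float], int, bool]:
    tau_step, coeff_step = _UPDATERS[config.objective]
    lo, hi = config.tau_bounds(I.grid)
    d = objective_value(I, f, config.objective)
    trace = [d]
    converged = False
    it = 0
    for it in range(1, config.max_iterations + 1):
        taus = tau_step(I, f, lo, hi)
        f = Factorization(taus, f.coeffs, f.grid)
        f = Factorization(taus, coeff_step(I, f), f.grid)
        d_new = objective_value(I, f, config.objective)
        trace.append(d_new)
        if math.isnan(d_new):
            raise FloatingPointError("objective became NaN")
        if abs(d - d_new) <= config.rel_tolerance * max(abs(d), 1e-300):
            converged = True
            d = d_new
            break
        d = d_new
    return f, trace, it, converged


def fit(I: SignalMatrix, rank: int, config: FitConfig | None = None) -> FitResult:
    """Alternating multiplicative fit with restarts; returns the best run.

    Each restart draws its own initialization (the first restart uses the
    plain log-spaced taus without jitter), runs tau and coefficient updates
    until the relative objective change drops below ``rel_tolerance`` or the
    iteration cap is hit, and the restart with the lowest final objective
    wins.  The returned factorization is ordered fast-to-slow.
    """
    if config is None:
        config = FitConfig()
    if rank < 1:
        raise ValueError("rank must be >= 1")
    if not np.any(I.values > 0):
        raise ValueError("cannot factorize an all-zero signal matrix")

    master = np.random.default_rng(config.seed)
    restart_seeds = master.integers(0, 2**31, size=config.n_restarts)
    best: FitResult | None = None
    failures: list[str] = []
    for idx in range(config.n_restarts):
        rng = np.random.default_rng(restart_seeds[idx])
        f0 = initial_factorization(I, rank, rng, spaced=idx == 0)
        try:
            f, trace, iters, conv = _run_single(I, f0, config)
        except FloatingPointError as exc:  # restart aborted, try the next one
            failures.append(f"restart {idx}: {exc}")
            continue
        result = FitResult(
            factorization=f,
            objective_value=trace[-1],
            objective_trace=np.asarray(trace),
            iterations_run=iters,
            converged=conv,
            restart_index=idx,
        )
        if best is None or result.objective_value < best.objective_value:
            best = result
    if best is None:
        raise RuntimeError("all restarts failed: " + "; ".join(failures))

    f = best.factorization.canonical()
    degenerate = np.flatnonzero(f.coeffs.sum(axis=1) < DEGENERATE_COEFF_SUM)
    best.factorization = f
    best.degenerate_components = degenerate.tolist()
    return best


def fit_coeffs(
    I: SignalMatrix, taus: np.ndarray, config: FitConfig | None = None,
    coeffs0: np.ndarray | None = None,
) -> Factorization:
    """Fit coefficients only, with the time constants held fixed.

    Used by cross-validation to score held-out sequences against bases
    learned on the training fold.
    """
    if config is None:
        config = FitConfig()
    taus = np.asarray(taus, dtype=float)
    _, coeff_step = _UPDATERS[config.objective]
    rng = np.random.default_rng(config.seed)
    if coeffs0 is None:
        coeffs0 = rng.uniform(0.1, 1.0, size=(taus.size, I.n_sequences))
    f = Factorization(taus, coeffs0, I.grid)
    d = objective_value(I, f, config.objective)
    for _ in range(config.max_iterations):
        f = Factorization(taus, coeff_step(I, f), I.grid)
        d_new = objective_value(I, f, config.objective)
        if abs(d - d_new) <= config.rel_tolerance * max(abs(d), 1e-300):
            break
        d = d_new
    return f


@dataclass
class FreeNMFResult:
    """Result of the unconstrained (free-basis) NMF baseline."""

    basis: np.ndarray
    coeffs: np.ndarray
    objective_value: float
    objective_trace: np.ndarray
    iterations_run: int
    converged: bool


def fit_free_nmf_lse(
    I: SignalMatrix, rank: int, config: FitConfig | None = None
) -> FreeNMFResult:
    """Classic multiplicative NMF with a free non-negative basis (LSE).

    Comparison baseline only: without the decay-shape constraint the basis
    columns carry no physical parameters.
    """
    if config is None:
        config = FitConfig()
    if rank < 1:
        raise ValueError("rank must be >= 1")
    if not np.any(I.values > 0):
        raise ValueError("cannot factorize an all-zero signal matrix")
    rng = np.random.default_rng(config.seed)
    V = I.values
    W = rng.uniform(0.1, 1.0, size=(I.n_times, rank))
    H = rng.uniform(0.1, 1.0, size=(rank, I.n_sequences))
    d = float(np.sum((V - W @ H) ** 2))
    trace = [d]
    converged = False
    it = 0
    for it in range(1, config.max_iterations + 1):
        H = H * np.maximum(W.T @ V, 0.0) / np.maximum(W.T @ W @ H, EPS)
        W = W * np.maximum(V @ H.T, 0.0) / np.maximum(W @ (H @ H.T), EPS)
        d_new = float(np.sum((V - W @ H) ** 2))
        trace.append(d_new)
        if abs(d - d_new) <= config.rel_tolerance * max(abs(d), 1e-300):
            converged = True
            d = d_new
            break
        d = d_new
    return FreeNMFResult(W, H, trace[-1], np.asarray(trace), it, converged)
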