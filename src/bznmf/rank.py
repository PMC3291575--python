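"""Rank (component-count) selection by information criteria and k-fold CV.

The number of exponential components is chosen by sweeping candidate ranks,
fitting each, and minimizing a criterion:

* ``AIC_LSE``  — Gaussian-likelihood AIC, ``MN ln(D/MN) + 2K`` with D the sum
  of squared residuals over all ``MN`` matrix elements.
* ``AIC_KL``   — Poisson-likelihood AIC via Stirling's approximation,
  ``2 D_KL + 2K``.
* ``AICC_*``   — finite-sample correction ``+ 2K(K+1)/(n - K - 1)`` with n
  the number of residuals entering the likelihood.
* ``KFOLD_CV`` — held-out reconstruction error with bases refit on training
  sequences only.

R-independent additive constants are dropped throughout: they cannot change
the argmin.  ``K = R(N+1)`` counts every estimated parameter of a rank-R
model: R time constants plus an R x N coefficient matrix.  A rank-R basis is
only R numbers, but each added component also buys N free per-sequence
weights, and it is that capacity — able to absorb roughly one noise degree
of freedom per sequence — that the penalty must price; a penalty linear in R
alone is overwhelmed by it and drifts to large ranks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum

import numpy as np

from .model import ObjectiveKind, SignalMatrix, lse_objective
from .updates import FitConfig, FitResult, fit, fit_coeffs

#: Floor for the residual sum in the Gaussian AIC (noise-free data gives D=0).
_D_FLOOR = 1e-300


class Criterion(Enum):
    AIC_LSE = "aic_lse"
    AICC_LSE = "aicc_lse"
    AIC_KL = "aic_kl"
    AICC_KL = "aicc_kl"
    KFOLD_CV = "kfold_cv"

    @property
    def objective(self) -> ObjectiveKind:
        """The divergence this criterion is paired with during fitting."""
        if self in (Criterion.AIC_KL, Criterion.AICC_KL):
            return ObjectiveKind.KL
        return ObjectiveKind.LSE


@dataclass
class RankSelectionResult:
    criterion: Criterion
    rank_range: tuple[int, int]
    scores: np.ndarray
    selected_rank: int
    fits: list[FitResult | None]

    @property
    def ranks(self) -> np.ndarray:
        return np.arange(self.rank_range[0], self.rank_range[1] + 1)

    def fit_for_rank(self, rank: int) -> FitResult | None:
        lo, hi = self.rank_range
        if not lo <= rank <= hi:
            raise ValueError(f"rank {rank} outside swept range {self.rank_range}")
        return self.fits[rank - lo]

    @property
    def selected_fit(self) -> FitResult | None:
        return self.fit_for_rank(self.selected_rank)


def n_parameters(R: int, N: int) -> int:
    """Parameter count of a rank-R model over N sequences: ``R (N + 1)``."""
    if R < 1 or N < 1:
        raise ValueError("R and N must be >= 1")
    return R * (N + 1)


def aic_lse(D: float, M: int, N: int, R: int) -> float:
    """Gaussian AIC for a sum-of-squares fit, up to an R-independent constant.

    ``MN ln(D / MN) + 2 K`` with ``K = R(N+1)`` estimated parameters; D is
    floored so noise-free (D = 0) sweeps remain finite.
    """
    if D < 0:
        raise ValueError("objective value must be non-negative")
    if M < 1:
        raise ValueError("M must be >= 1")
    mn = M * N
    return mn * math.log(max(D, _D_FLOOR) / mn) + 2 * n_parameters(R, N)


def aic_kl(D_kl: float, R: int, N: int) -> float:
    """Poisson (Stirling-approximated) AIC, up to an R-independent constant."""
    if D_kl < 0:
        raise ValueError("objective value must be non-negative")
    return 2.0 * D_kl + 2 * n_parameters(R, N)


def aicc(aic: float, n_params: int, n_samples: int) -> float:
    """Finite-sample corrected AIC; +inf when the correction is undefined.

    Adds the second-order bias correction ``2 K (K+1) / (n - K - 1)`` where
    K is the parameter count and n the number of residuals entering the
    likelihood.  Once ``n <= K + 1`` the correction blows up and the
    criterion is undefined for that rank.
    """
    if n_samples <= n_params + 1:
        return math.inf
    return aic + 2.0 * n_params * (n_params + 1) / (n_samples - n_params - 1)


def _criterion_score(
    crit: Criterion, fit_result: FitResult, I: SignalMatrix
) -> float:
    M, N, R = I.n_times, I.n_sequences, fit_result.rank
    D = fit_result.objective_value
    K, n = n_parameters(R, N), M * N
    if crit is Criterion.AIC_LSE:
        return aic_lse(D, M, N, R)
    if crit is Criterion.AICC_LSE:
        return aicc(aic_lse(D, M, N, R), K, n)
    if crit is Criterion.AIC_KL:
        return aic_kl(D, R, N)
    if crit is Criterion.AICC_KL:
        return aicc(aic_kl(D, R, N), K, n)
    raise ValueError(f"{crit} is not an information criterion")


def select_rank(
    I: SignalMatrix,
    criterion: Criterion = Criterion.AIC_LSE,
    rank_range: tuple[int, int] = (1, 20),
    config: FitConfig | None = None,
) -> RankSelectionResult:
    """Fit every rank in ``rank_range`` and pick the criterion minimizer.

    Ties break toward the smaller rank (parsimony).  A rank whose fit fails
    scores +inf.  The fit objective is dictated by the criterion (Gaussian
    criteria pair with LSE fits, Poisson criteria with KL fits).
    """
    lo, hi = rank_range
    if not (1 <= lo <= hi):
        raise ValueError("rank_range must satisfy 1 <= R_min <= R_max")
    if criterion is Criterion.KFOLD_CV:
        return kfold_cv_rank(I, rank_range, k=3, config=config)
    if config is None:
        config = FitConfig(objective=criterion.objective)
    elif config.objective is not criterion.objective:
        config = replace(config, objective=criterion.objective)

    scores = np.full(hi - lo + 1, np.inf)
    fits: list[FitResult | None] = [None] * (hi - lo + 1)
    for r in range(lo, hi + 1):
        try:
            res = fit(I, r, config)
        except (RuntimeError, ValueError):
            continue
        fits[r - lo] = res
        scores[r - lo] = _criterion_score(criterion, res, I)
    selected = lo + int(np.argmin(scores))  # argmin takes the first minimum
    return RankSelectionResult(criterion, (lo, hi), scores, selected, fits)


def kfold_cv_rank(
    I: SignalMatrix,
    rank_range: tuple[int, int] = (1, 20),
    k: int = 3,
    config: FitConfig | None = None,
) -> RankSelectionResult:
    """Rank selection by k-fold cross-validation over sequences (columns).

    Columns are shuffled (seeded) into k folds.  For each candidate rank the
    time constants are learned on the training folds; coefficients alone are
    then refit on the held-out fold and the mean per-element squared
    reconstruction error is the fold score.  The rank minimizing the mean
    fold score wins; ties break toward the smaller rank.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if I.n_sequences < k:
        raise ValueError("need at least k sequences for k folds")
    lo, hi = rank_range
    if not (1 <= lo <= hi):
        raise ValueError("rank_range must satisfy 1 <= R_min <= R_max")
    if config is None:
        config = FitConfig()
    if config.objective is not ObjectiveKind.LSE:
        config = replace(config, objective=ObjectiveKind.LSE)

    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(I.n_sequences)
    folds = np.array_split(perm, k)
    if any(f.size == 0 for f in folds):
        raise ValueError("a fold received zero sequences")

    scores = np.full(hi - lo + 1, np.inf)
    fits: list[FitResult | None] = [None] * (hi - lo + 1)
    for r in range(lo, hi + 1):
        fold_scores = []
        for fold in folds:
            train_cols = np.setdiff1d(perm, fold)
            train = SignalMatrix(I.values[:, train_cols], I.grid,
                                 allow_negative=I.allow_negative)
            held = SignalMatrix(I.values[:, fold], I.grid,
                                allow_negative=I.allow_negative)
            res = fit(train, r, config)
            held_fit = fit_coeffs(held, res.factorization.taus, config)
            fold_scores.append(
                lse_objective(held, held_fit) / held.values.size
            )
        scores[r - lo] = float(np.mean(fold_scores))
        # keep a full-data fit for downstream parameter reporting
        fits[r - lo] = fit(I, r, config)
    selected = lo + int(np.argmin(scores))
    return RankSelectionResult(Criterion.KFOLD_CV, (lo, hi), scores, selected, fits)
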