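"""Ground-truth comparison: component matching, existence ratios, error rates.

Simulation studies summarize parameter recovery by two mean relative
deviations, reported as percentages:

* time-constant error rate
  ``D_tau = 1/(R S) * sum_s sum_r |tau_hat_r^(s) - tau_r*| / tau_r*``
  aggregated over the S input-matrix sets, and
* existence-ratio error rate
  ``D_h = 1/(R N~) * sum_i sum_r |h_hat_r^(i) - h_r*| / h_r*``
  aggregated over all ``N~ = N x S`` individual sequences.

Estimated components are matched to the truth by an optimal assignment on
log10 time-constant distance before the deviations are computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .model import Factorization


@dataclass
class ComponentRatios:
    """Per-sequence column-normalized coefficients of a factorization."""

    ratios: np.ndarray          # R x N, columns sum to 1 (NaN where undefined)
    mean: np.ndarray            # length R, over well-defined sequences
    std: np.ndarray             # length R, ddof=0
    excluded_sequences: list[int]


@dataclass
class EvaluationResult:
    """Recovery summary of a simulation study against its ground truth."""

    d_tau: float                # mean relative tau deviation (fraction)
    d_h: float                  # mean relative ratio deviation (fraction)
    n_sets: int
    n_total_sequences: int
    tau_deviations: np.ndarray  # R per-component means over sets
    ratio_deviations: np.ndarray
    matchings: list[np.ndarray]

    @property
    def d_tau_percent(self) -> float:
        return 100.0 * self.d_tau

    @property
    def d_h_percent(self) -> float:
        return 100.0 * self.d_h


def existence_ratios(f: Factorization) -> ComponentRatios:
    """Normalize coefficients per sequence: ``ratio_ri = h_ri / sum_r h_ri``.

    Sequences whose coefficients are all zero have no defined ratios; they
    are excluded from the mean/std and reported.
    """
    col_sums = f.coeffs.sum(axis=0)
    defined = col_sums > 0
    ratios = np.full_like(f.coeffs, np.nan)
    ratios[:, defined] = f.coeffs[:, defined] / col_sums[defined]
    if defined.any():
        mean = ratios[:, defined].mean(axis=1)
        std = ratios[:, defined].std(axis=1)
    else:
        mean = np.full(f.rank, np.nan)
        std = np.full(f.rank, np.nan)
    return ComponentRatios(
        ratios, mean, std, np.flatnonzero(~defined).tolist()
    )


def match_components(estimated_taus, true_taus) -> np.ndarray:
    """Optimal bijection of estimated onto true components.

    Minimizes the total |log10 tau_hat - log10 tau*| assignment cost and
    returns ``perm`` such that ``estimated_taus[perm[k]]`` is the estimate
    matched to ``true_taus[k]``.
    """
    est = np.asarray(estimated_taus, dtype=float)
    true = np.asarray(true_taus, dtype=float)
    if est.shape != true.shape or est.ndim != 1:
        raise ValueError("estimated and true tau vectors must have equal length")
    if np.any(est <= 0) or np.any(true <= 0):
        raise ValueError("time constants must be positive")
    cost = np.abs(np.log10(est)[:, None] - np.log10(true)[None, :])
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty_like(rows)
    perm[cols] = rows
    return perm


def error_rates(
    fits: Sequence[Factorization],
    true_taus,
    true_ratios,
) -> EvaluationResult:
    """Error rates of a study: one fitted factorization per input-matrix set.

    ``true_ratios`` are the per-component simulation existence ratios
    (shared by every sequence).  Each fit must have the true rank; its
    components are matched to the truth before deviations are taken.
    """
    true_taus = np.asarray(true_taus, dtype=float)
    true_ratios = np.asarray(true_ratios, dtype=float)
    if np.any(true_taus <= 0) or np.any(true_ratios <= 0):
        raise ValueError("true parameters must be strictly positive")
    R = true_taus.size
    S = len(fits)
    if S < 1:
        raise ValueError("need at least one fitted set")

    tau_devs = np.zeros((S, R))
    ratio_dev_sum = np.zeros(R)
    matchings = []
    n_total = 0
    for s, f in enumerate(fits):
        if f.rank != R:
            raise ValueError(
                f"set {s} has rank {f.rank}, truth has rank {R}"
            )
        perm = match_components(f.taus, true_taus)
        matchings.append(perm)
        tau_devs[s] = np.abs(f.taus[perm] - true_taus) / true_taus
        ratios = existence_ratios(f).ratios[perm]  # R x N, truth-ordered
        defined = ~np.isnan(ratios).any(axis=0)
        dev = np.abs(ratios[:, defined] - true_ratios[:, None]) / true_ratios[:, None]
        ratio_dev_sum += dev.sum(axis=1)
        n_total += int(defined.sum())

    d_tau = float(tau_devs.mean())
    d_h = float(ratio_dev_sum.sum() / (R * n_total))
    return EvaluationResult(
        d_tau=d_tau,
        d_h=d_h,
        n_sets=S,
        n_total_sequences=n_total,
        tau_deviations=tau_devs.mean(axis=0),
        ratio_deviations=ratio_dev_sum / n_total,
        matchings=matchings,
    )
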