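"""Synthetic multi-exponential signal generation for simulation studies.

The generator emulates the benchmark design used throughout the package's
validation: each of N sequences is an equal-weight sum of R_s exponential
decays with decade-separated time constants ``tau_r = 10**r``, sampled on a
log-spaced time grid, plus independent bounded uniform noise::

    I_ji = sum_{r=1..R_s} (1/R_s) * exp(-t_j / 10**r) + xi_ji,
    xi_ji ~ Uniform(-0.1, 0.1)

Noise dips below zero are retained by default: on a log-spaced grid most
measurement times fall in the fully decayed tail, and clipping there would
inject a positive bias (+half the noise half-width on average over clipped
entries) that masquerades as an extra slow component, corrupting both rank
selection and the slow time constants.  The factorization itself remains
non-negative; set ``clip_negatives=True`` to force a non-negative matrix
(the clipped fraction is then reported in the generation metadata).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

from .model import Factorization, SignalMatrix, TimeGrid

#: Default grid endpoints of the benchmark study (time units, e.g. us).
T_MIN_DEFAULT = 1.002
T_MAX_DEFAULT = 3269017.373


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated input-matrix set.

    Defaults reproduce the benchmark conditions: 50 sequences per set, three
    sets, noise uniform on [-0.1, 0.1], true time constants 10**r with equal
    existence ratios 1/R_s.
    """

    sim_rank: int = 3
    dims: int = 75
    n_sequences: int = 50
    n_sets: int = 3
    t_min: float = T_MIN_DEFAULT
    t_max: float = T_MAX_DEFAULT
    noise_half_width: float = 0.1
    clip_negatives: bool = False
    taus_true: np.ndarray | None = None
    ratios_true: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sim_rank < 1:
            raise ValueError("sim_rank must be >= 1")
        if self.noise_half_width < 0:
            raise ValueError("noise_half_width must be >= 0")
        if not (0 < self.t_min < self.t_max):
            raise ValueError("need 0 < t_min < t_max")
        taus = self.taus_true
        if taus is None:
            taus = 10.0 ** np.arange(1, self.sim_rank + 1)
        taus = np.asarray(taus, dtype=float)
        if taus.size != self.sim_rank or np.any(taus <= 0):
            raise ValueError("taus_true must be sim_rank positive values")
        ratios = self.ratios_true
        if ratios is None:
            ratios = np.full(self.sim_rank, 1.0 / self.sim_rank)
        ratios = np.asarray(ratios, dtype=float)
        if ratios.size != self.sim_rank or np.any(ratios < 0):
            raise ValueError("ratios_true must be sim_rank non-negative values")
        if abs(ratios.sum() - 1.0) > 1e-9:
            raise ValueError("ratios_true must sum to 1")
        object.__setattr__(self, "taus_true", taus)
        object.__setattr__(self, "ratios_true", ratios)


def log_time_grid(dims: int, t_min: float = T_MIN_DEFAULT,
                  t_max: float = T_MAX_DEFAULT) -> TimeGrid:
    """``dims`` points equally spaced in log10 between the two endpoints."""
    if dims < 2:
        raise ValueError("dims must be >= 2")
    if not (0 < t_min < t_max):
        raise ValueError("need 0 < t_min < t_max")
    times = np.logspace(math.log10(t_min), math.log10(t_max), dims)
    # guarantee exact endpoints despite floating exponentiation round-off
    times[0], times[-1] = t_min, t_max
    return TimeGrid(times)


def simulate_matrix(
    cfg: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[SignalMatrix, Factorization, dict]:
    """Generate one noisy input matrix plus its ground-truth factorization.

    Returns ``(matrix, truth, meta)`` where ``meta`` records the generation
    settings and the fraction of entries that noise drove below zero.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    grid = log_time_grid(cfg.dims, cfg.t_min, cfg.t_max)
    truth = Factorization(
        cfg.taus_true,
        np.repeat(cfg.ratios_true[:, None], cfg.n_sequences, axis=1),
        grid,
    )
    clean = np.exp(-grid.times[:, None] / cfg.taus_true[None, :]) @ truth.coeffs
    noise = rng.uniform(
        -cfg.noise_half_width, cfg.noise_half_width, size=clean.shape
    )
    noisy = clean + noise
    negative = noisy < 0
    if cfg.clip_negatives:
        noisy[negative] = 0.0
    meta = {
        "sim_rank": cfg.sim_rank,
        "dims": cfg.dims,
        "n_sequences": cfg.n_sequences,
        "noise_half_width": cfg.noise_half_width,
        "negative_fraction": float(negative.mean()),
        "clipped": cfg.clip_negatives,
    }
    matrix = SignalMatrix(noisy, grid, allow_negative=not cfg.clip_negatives)
    return matrix, truth, meta


@dataclass(frozen=True)
class StudyCell:
    """All sets generated for one (simulation rank, dims) grid cell."""

    sim_rank: int
    dims: int
    matrices: list[SignalMatrix]
    truths: list[Factorization]
    metas: list[dict] = field(repr=False)


def simulate_study(
    sim_ranks=(2, 3, 4, 5),
    dims=(75, 145, 715, 1430, 7150),
    n_sets: int = 3,
    base: SimulationConfig | None = None,
    seed: int = 0,
) -> Iterator[StudyCell]:
    """Yield the factorial {R_s} x {dims} study, ``n_sets`` matrices per cell.

    Reproducible: every matrix's noise stream is derived from ``seed`` via a
    spawned SeedSequence, so regeneration with the same seed is bitwise
    identical and independent of iteration order.
    """
    if base is None:
        base = SimulationConfig()
    children = np.random.SeedSequence(seed).spawn(len(sim_ranks) * len(dims))
    idx = 0
    for r_s in sim_ranks:
        for dim in dims:
            cfg = replace(
                base, sim_rank=r_s, dims=dim, n_sets=n_sets,
                taus_true=None, ratios_true=None,
            )
            rng = np.random.default_rng(children[idx])
            idx += 1
            matrices, truths, metas = [], [], []
            for _ in range(n_sets):
                mat, truth, meta = simulate_matrix(cfg, rng)
                matrices.append(mat)
                truths.append(truth)
                metas.append(meta)
            yield StudyCell(r_s, dim, matrices, truths, metas)
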