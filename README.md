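# bznmf

Automatic decomposition of composite decay signals — sums of non-negative
exponential components — with the number of components chosen by
information criteria.

## The problem

Time-resolved spectroscopy and fluorescence correlation spectroscopy
produce sets of signal sequences that are non-negative mixtures of a few
exponential decays,

    I_i(t_j) ≈ Σ_{r=1..R} h_{ri} · exp(−t_j / τ_r),

where the time constants τ_r carry the physics (diffusion or
energy-transfer times) and the weights h_{ri} give each component's
existence ratio within sequence *i*.  Analysts usually fix the number of
components R by hand from domain heuristics; this package estimates both
the parameters and R automatically from many sequences at once.

Stacking N sequences gives a matrix factorization `I ≈ W H` in which the
basis is *constrained* to exponential-decay (Boltzmann-distribution)
shapes, `w_jr = exp(−t_j/τ_r)` — a Boltzmann-constrained NMF.  Fitting uses
multiplicative updates for both the taus and the coefficients (under
either a least-squares or a generalized Kullback-Leibler objective), and
the rank is selected by sweeping R = 1..20 and minimizing AIC/AICc (or
3-fold cross-validation).  See `docs/methods.md` for the update rules,
parameter-count penalty, initialization, and the statistical limits of the
bundled benchmark.

## Worked example

Simulate one benchmark set — 50 sequences on 75 log-spaced time points,
two components with τ = (10, 100) and equal weights, uniform noise on
[−0.1, 0.1] — then decompose it with an automatic rank sweep:

    bznmf simulate --rank 2 --dim 75 --seed 7 --out demo
    bznmf decompose demo/set1.tsv --allow-negative \
        --criterion aic --objective lse --seed 7 --out demo/fit

which prints

    selected rank: 2
      component 1: tau = 10.2907, existence ratio = 0.5205 [±0.0312]
      component 2: tau = 105.4605, existence ratio = 0.4795 [±0.0312]
    report written to demo/fit/report.json

The Akaike criterion picked two components out of the twenty offered, and
the fitted time constants land within a few percent of the simulated truth
(τ = 10, 100) — about the statistical precision one set of this size
supports.  The existence ratios recover the simulated equal weights
(0.5 each); the ± figure is the spread across the 50 sequences.
`report.json` stores the full criterion sweep, the fitted parameters and
the per-sequence coefficients for downstream use.

The same machinery is available as a library:

```python
from bznmf import (SimulationConfig, simulate_matrix, select_rank,
                   Criterion, FitConfig)

I, truth, _ = simulate_matrix(SimulationConfig(sim_rank=2, dims=75, seed=7))
sel = select_rank(I, Criterion.AIC_LSE, (1, 20), FitConfig(seed=7))
print(sel.selected_rank, sel.selected_fit.factorization.taus)
```

A full factorial benchmark (ranks × dimensions × sets, with ground-truth
error rates) runs via `bznmf reproduce-study`, e.g.

    bznmf reproduce-study --ranks 2,3 --dims 145 --sets 3 --seed 1 --out study

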