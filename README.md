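# fecgbse

Blind source extraction of the fetal electrocardiogram (FECG) from
multichannel abdominal recordings.

A cutaneous recording from a pregnant woman is dominated by the maternal
ECG; the fetal complexes are buried under it together with breathing
drift, electrode-motion artifacts, and noise. Full blind source
*separation* recovers every source; when only the fetal trace is wanted,
one-unit blind source *extraction* (BSE) is faster and can exploit prior
knowledge — here, that the fetal heartbeat is periodic at a known lag.

`fecgbse` is for signal-processing researchers and method developers who
want a reproducible, fully synthetic-testable implementation of this
two-stage extraction approach.

## The method

With the linear instantaneous model `x(t) = A s(t)`, the mixture is
centered and prewhitened, `x̃(t) = V (x(t) − E{x})`, and a single source is
estimated as `y(t) = wᵀ x̃(t)` with `‖w‖ = 1`.

**Stage 1 — temporal-structure × non-Gaussianity.** The weight vector
maximizes

```
ψ(w) = E{ G(y(t)) · G(y(t) · y(t−τ)) },
```

where `G` is a smooth even contrast (`log cosh` by default, `y⁴/4`
optional) and `τ` is one period of the desired source (one fetal
heartbeat, in samples). The first factor rewards non-Gaussianity; the
second rewards a strong nonlinear autocorrelation at lag `τ`, which the
fetal ECG has and the other sources do not. ψ is maximized either by
projected gradient ascent or, preferably, by a learning-rate-free
fixed-point iteration that replaces `w` with the normalized gradient
direction. Evaluators of the associated stability and convergence
conditions (sample expectations over known source series) are included as
simulation diagnostics.

**Stage 2 — warm-started FastICA.** One-unit negentropy FastICA,

```
w ← E{x̃ g(wᵀx̃)} − E{g′(wᵀx̃)} w,   w ← w/‖w‖,
```

converges to *some* independent component from an arbitrary start; seeded
with the stage-1 solution it lands in the fetal source's basin of
attraction and sharpens the estimate. For the quartic contrast the basin
is characterized explicitly: starting at `q₀ = AᵀVᵀw₀` (source
coordinates), source *i* is reached when
`q₀ᵢ² > q₀ⱼ² · |k₄(sⱼ)/k₄(sᵢ)|` for every `j ≠ i`, with `k₄` the kurtosis.

**Scoring.** With known mixing (simulations), quality is the performance
index of the global vector `p = wᵀVA`:

```
PI = Σⱼ |pⱼ| / maxₖ |pₖ| − 1      (0 for perfect extraction).
```

A six-source synthetic scene generator (maternal ECG 1.2 Hz, fetal ECG
2.2 Hz, 0.3 Hz breathing, electrode transients, Gaussian and Laplacian
noise; 500 Hz, 10 s) and a Monte-Carlo trial harness make every stage
testable without clinical data.

## Worked example

```
$ fecgbse simulate --seed 1 -o scene
wrote scene to scene
$ fecgbse extract --algorithm fp2 --tau auto -i scene/mixed.csv \
      --sources scene/sources.csv --mixing scene/mixing_matrix.csv -o fecg
PI = 0.012819
extracted series written to fecg/extracted.csv (2 iterations, converged=True)
$ fecgbse evaluate --algorithm fp2 --n-trials 100 --seed 1 -o eval
median PI over 100 trials: 0.01164
```

The first command writes a seeded six-source scene and its mixture under
the fixed 6×6 benchmark matrix. The second runs the full two-stage
pipeline: the lag is estimated automatically as τ = 227 samples (one
2.2 Hz fetal period at 500 Hz), stage 1 converges in 7 fixed-point
iterations and stage 2 in 2 more; because the true sources and mixing
matrix were supplied, the run report records that the extracted series
matches the fetal source with |correlation| = 0.99997 and scores
PI = 0.0128 — i.e. residual cross-talk from all other sources summed is
about 1.3 % of the fetal component. The third command repeats the
experiment over 100 freshly seeded scenes and reports the median PI.

The library API mirrors the CLI: see `fecgbse.fixed_point_extract`,
`fecgbse.two_stage_extract`, `fecgbse.run_trials`.

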