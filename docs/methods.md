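# Methods

## Model and estimands

All algorithms assume the noiseless linear instantaneous mixing model
`x(t) = A s(t)` with `n` channels, `m = n` sources, and a full-column-rank
mixing matrix `A`. Preprocessing removes channel means and prewhitens with
`V = Λ^{-1/2} Eᵀ` from the eigendecomposition `Cov(x) = E Λ Eᵀ`, so the
whitened mixture `x̃ = V (x − E{x})` has identity sample covariance and
extraction reduces to finding a unit vector `w` with `y = wᵀ x̃`
proportional to one source. Scale and sign of `y` are unidentifiable, as
in any blind method; the CLI's display convention rescales extracted
series to unit variance with the dominant peak positive.

Every expectation `E{·}` is a sample mean. For lagged statistics, the
record is truncated to the overlapping range `t ∈ [τ, T)` — `y(t)` pairs
with `y(t−τ)` by pure indexing, never by circular wrapping, which would
fabricate correlations across the record boundary. The same convention is
applied to all three expectation terms of the objective gradient; the
alignment question is otherwise underdetermined.

## Stage 1: the temporal-structure × non-Gaussianity contrast

The objective `ψ(w) = E{G(y(t)) G(y(t) y(t−τ))}` is maximized on the unit
sphere. Its gradient is the sum of three lagged expectations

```
E{x̃(t) g(y) G(y y_τ)} + E{x̃(t) y_τ g(y y_τ) G(y)} + E{x̃(t−τ) y g(y y_τ) G(y)},
```

with `g = G′`. Two optimizers are provided:

- **Gradient ascent** (`gradient_ascent_extract`): `w ← normalize(w + μ ∇ψ)`.
  Kept as a cross-check; convergence is slow and μ-sensitive by design of
  the update, not of the implementation.
- **Fixed point** (`fixed_point_extract`): at a stable point the gradient
  is parallel to `w`, so the iteration replaces `w` by the normalized
  gradient direction — no learning rate. This is the recommended stage-1
  extractor. The update expression is algebraically identical to the
  gradient, and the implementation reuses it.

Both stop when `1 − |⟨w_{k+1}, w_k⟩| < tol` (sign-blind, since
normalization leaves `w` defined only up to sign). Defaults `tol = 1e-8`,
`max_iter = 200`: the benchmark scene converges in under ten fixed-point
iterations, so 200 is a generous ceiling, and `1e-8` bounds the angular
error of the solution by `√(2·tol) ≈ 1.4e-4` rad. On non-convergence the
best iterate by objective value is returned, flagged `converged=False`. A
near-zero update raises rather than silently re-randomizing, so runs stay
reproducible.

Contrasts: `logcosh` (`G = log cosh`, `g = tanh`, `g′ = 1 − tanh²`,
overflow-safe evaluation) and `quartic` (`G = y⁴/4`, `g = y³`,
`g′ = 3y²`). `logcosh` is the default everywhere; `quartic` exists chiefly
because the stage-2 basin analysis is exact for it.

### Theorem-condition diagnostics

`stability_margin(s_i, s_j, τ, G)` evaluates the sample expectation whose
negativity certifies that source *i* is a local maximum of ψ against
competitor *j* (a second-order perturbation condition); a separate
`convergence_condition(s_i, τ, G)` evaluates the expectation that must be
nonzero for the fixed-point iteration to settle on source *i*. Both are
analysis tools evaluated on *known source samples* in simulations — they
are not estimable from mixtures alone, and the package does not pretend
otherwise. The quantifier over competitors is left to the caller: the
margin takes one (i, j) pair, and the acceptance suite checks all j.
Statistical significance is judged against bootstrap standard errors
computed by i.i.d. resampling of the per-sample terms; this ignores serial
dependence, which is acceptable because the checks only need an order of
magnitude (the fetal-source condition value exceeds its SE by orders of
magnitude, and the white-noise margin check only needs "consistent with
zero at a few SEs").

## Stage 2: warm-started one-unit FastICA

The negentropy proxy `J(y) ∝ (E{G(y)} − E{G(ν)})²` (ν standard Gaussian)
is maximized with the Newton-simplified fixed-point update
`w ← E{x̃ g(wᵀx̃)} − E{g′(wᵀx̃)} w`. The Lagrange multiplier of the
underlying constrained problem cancels in this form and is never
materialized. The Gaussian reference `E{G(ν)}` is a constant: computed
once by adaptive quadrature for `logcosh` (≈ 0.3746), analytic `3/4` for
the quartic contrast — no Monte-Carlo noise in a constant.

Run from a random start, FastICA converges to whichever source's basin of
attraction the start falls into. The two-stage pipeline
(`two_stage_extract`) whitens once, runs the stage-1 fixed point at lag τ,
and uses its solution as the FastICA start. Stage-1 non-convergence
aborts by default (`on_stage1_failure="abort"`); a `"warn"` policy
proceeds with the best stage-1 iterate.

For `G = y⁴/4` the basin geometry is explicit in source coordinates
`q₀ = AᵀVᵀw₀`: source *i* is reached when
`q₀ᵢ² > q₀ⱼ² · |k₄(sⱼ)/k₄(sᵢ)|` for all `j ≠ i`. The kurtosis ratio is
compared **in magnitude**: the contraction argument behind the condition
bounds the modulus of the competing coordinate ratio, and a signed ratio
would be meaningless for sub-Gaussian sources. The condition is undefined
for `k₄(sᵢ) = 0` and the evaluator raises in that case. `k₄` uses raw
sample moments `E{s⁴} − 3(E{s²})²` without small-sample correction or
re-centering (all series involved are zero-mean by construction).

In simulation mode (true `A` and sources supplied) the pipeline reports
`q₀` and per-competitor basin flags; with mixtures alone these diagnostics
are unavailable and are omitted.

## Scoring and the trial harness

The global vector `p = wᵀVA` composes extraction with mixing; the
performance index `PI = Σⱼ|pⱼ|/maxₖ|pₖ| − 1` is evaluated on magnitudes
(`w` is sign-indeterminate, and only the magnitude form makes PI = 0
characterize perfect extraction). PI is scale-, sign-, and
permutation-invariant and nonnegative.

`run_trials` re-runs an extractor over trials seeded `seed + t` (fresh
sources each trial; fresh uniform(0,1) mixing matrices in
`random_uniform` mode, redrawn while the condition number exceeds 10⁶).
The initial weight vector follows the benchmark protocol: a fixed
reference 6-vector with the fixed mixing matrix, the last canonical basis
vector with random matrices; a `w0_mode="random"` option draws a fresh
unit start per trial, and the `fastica_random` baseline always does.
Per-iteration PI curves use each algorithm's stored iterate trace, padded
with the final value to the longest trial. Hard failures inside a trial
are recorded (PI = NaN) and counted, not fatal.

## The synthetic scene

The generator emulates a six-source abdominal-recording scene:

| source | waveform | defaults |
|---|---|---|
| maternal ECG | biphasic Gaussian-derivative pulse train | 1.2 Hz, width 0.018 s |
| fetal ECG | same, narrower and faster | 2.2 Hz, width 0.010 s |
| breathing | sinusoid | 0.3 Hz |
| electrode artifact | sparse ±jumps with exponential baseline recovery | ~0.3 events/s, 0.3 s decay |
| noise 1 | Gaussian white | — |
| noise 2 | Laplacian (impulsive) | — |

Defaults: 500 Hz, 10 s records; the fetal period is then 227 samples.
Pulse trains are generated in continuous beat phase (with a random phase
offset per realization), so the fundamental period is exact and the
sample autocorrelation peaks at `round(fs/rate)`. The width parameters
give QRS complexes spanning roughly 90 ms (maternal) and 50 ms (fetal),
ordinary physiological durations. Electrode transients decay back to
baseline (time constant 0.3 s) rather than persisting as steps: AC-coupled
electrodes cannot hold a DC offset, and persistent steps would carry
near-unit autocorrelation at *every* lag — an artifact of the stand-in
waveform that would spuriously compete with the fetal source at its own
period. Every row is standardized to zero mean and unit variance before
mixing, so the mixing matrix alone sets relative levels (the nominal
0.25 fetal-to-maternal amplitude ratio is absorbed by this convention).
All generation is a pure function of `(specs, n_samples, fs_hz, seed)`.

What the generator does **not** emulate: heart-rate variability and beat
morphology changes, P/T waves, baseline wander within beats, fetal
movement, sensor-specific coloration of the noise. Passing tests
therefore demonstrate the algorithms' behavior under exact periodicity
and stationary mixing; on clinical data the lag must track the fetal
rate, and performance can only be judged qualitatively (no ground-truth
mixing matrix). The delay-robustness suite — extraction succeeds across a
±(6–8)-sample window around the true fetal period — is the synthetic
counterpart of that concern.

## Delay selection

`estimate_delay` scans a lag range and returns the lag maximizing the
mean over channels of the *signed* sample autocorrelation (ties to the
smallest lag). The signed score lands on a full fundamental period; an
absolute-value score would tie the anti-correlated half period of an
oscillatory source and win by the tie-break. This heuristic replaces a
dedicated heartbeat-period estimator and is deliberately simple; the CLI
always accepts an explicit `--tau` (a 250 Hz clinical benchmark recording
of this kind has its optimal lag near 112 samples), and `--tau auto`
defaults to scanning 0.2–2.0 s worth of samples, bracketing plausible
maternal and fetal periods.

## Numerical choices and edge cases

- Whitening retains components with eigenvalue > `retain_eps` (default
  1e-10, relative to the largest); drops are logged. Guards exact rank
  deficiency only — the benchmark scene keeps all six dimensions.
- Zero-variance input to whitening, all-zero global vectors, zero-variance
  extracted series, and zero starting vectors raise typed errors rather
  than propagating NaNs.
- `log cosh` is evaluated as `|u| + log1p(exp(−2|u|)) − log 2` to avoid
  overflow.
- Problem sizes in the test and acceptance suites: 10 s × 500 Hz scenes,
  100-trial Monte-Carlo runs, 20 000-sample two-source toys for the basin
  study — sizes at which every sample statistic in play is stable to well
  inside the asserted tolerances.

## Known limitations

- Strictly one-unit: no deflation or symmetric multi-component mode.
- The stability/convergence diagnostics require ground-truth sources.
- The basin condition is exact only for the quartic contrast; for
  `logcosh` the warm start is justified empirically (the Monte-Carlo
  ordering study), not analytically.
- The delay heuristic assumes the desired source's period dominates the
  scanned autocorrelation range; with a strong competing periodicity in
  the same range, supply `--tau` explicitly.
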