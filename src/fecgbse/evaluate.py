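"""Performance-index scoring and the Monte-Carlo trial harness.

A converged extraction is scored through the global vector
``p = w^T V A`` — the composition of mixing, whitening, and unmixing.
Perfect extraction makes ``p`` proportional to a canonical basis vector;
the performance index

    PI = sum_j |p_j| / max_k |p_k| - 1

is 0 in that case and grows with cross-talk from the other sources.  The
index is evaluated on magnitudes because the extracted sign (and hence the
signs of the ``p_j``) is indeterminate in any blind method.

The trial harness re-runs an extractor over freshly generated scenes
(optionally fresh random mixing matrices) and records final and
per-iteration PI values, reproducibly from a single seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import bse_tempng
from .bse_tempng import REFERENCE_W0_6CH, make_nonlinearity
from .exceptions import DegenerateDataError, FecgbseError, ParameterError, ShapeError
from .fastica_warm import TwoStageConfig, fastica_extract, two_stage_extract
from .preprocess import WhiteningTransform, delayed_pair, whiten
from .synthio import (
    MixingMatrix,
    SignalMatrix,
    SourceSpec,
    default_scene,
    generate_sources,
    mix,
    benchmark_mixing_matrix,
    random_mixing_matrix,
)

__all__ = [
    "GlobalVector",
    "global_vector",
    "performance_index",
    "match_source",
    "SceneConfig",
    "TrialSummary",
    "run_trials",
]

ALGORITHMS = ("fp1", "fp2", "grad", "fastica_random")


@dataclass(frozen=True)
class GlobalVector:
    """p = w^T V A; proportional to a basis vector iff extraction is perfect."""

    p: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float).ravel()
        object.__setattr__(self, "p", p)
        if not np.all(np.isfinite(p)):
            raise ShapeError("global vector has non-finite entries")


def global_vector(w: np.ndarray, V: np.ndarray, A: MixingMatrix | np.ndarray) -> GlobalVector:
    """Exact matrix algebra w^T V A."""
    w = np.asarray(w, dtype=float).ravel()
    V = np.asarray(V, dtype=float)
    entries = A.entries if isinstance(A, MixingMatrix) else np.asarray(A, dtype=float)
    if V.shape[0] != w.shape[0] or V.shape[1] != entries.shape[0]:
        raise ShapeError(
            f"non-conforming shapes: w {w.shape}, V {V.shape}, A {entries.shape}"
        )
    return GlobalVector((w @ V) @ entries)


def performance_index(p: GlobalVector | np.ndarray) -> float:
    """PI = sum_j |p_j| / max_k |p_k| - 1; zero iff one component survives."""
    vec = p.p if isinstance(p, GlobalVector) else np.asarray(p, dtype=float).ravel()
    mags = np.abs(vec)
    peak = mags.max(initial=0.0)
    if peak == 0.0:
        raise DegenerateDataError("all-zero global vector has no defined PI")
    return float(mags.sum() / peak - 1.0)


def match_source(y: np.ndarray, sources: SignalMatrix) -> tuple[int, float]:
    """Identify the source best matching an extracted series.

    Returns the index maximizing the absolute Pearson correlation over the
    common (trailing) time range, and that absolute correlation.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = min(y.size, sources.n_samples)
    yc = y[-n:] - y[-n:].mean()
    denom_y = np.sqrt(np.sum(yc * yc))
    if denom_y == 0.0:
        raise DegenerateDataError("extracted series has zero variance")
    best_idx, best_corr = -1, -1.0
    for i, row in enumerate(sources.data):
        rc = row[-n:] - row[-n:].mean()
        denom_r = np.sqrt(np.sum(rc * rc))
        if denom_r == 0.0:
            continue
        corr = abs(float(np.dot(yc, rc) / (denom_y * denom_r)))
        if corr > best_corr:
            best_idx, best_corr = i, corr
    return best_idx, best_corr


@dataclass(frozen=True)
class SceneConfig:
    """Scene used by the trial harness: specs, record length, target source."""

    specs: tuple[SourceSpec, ...] = tuple(default_scene())
    fs_hz: float = 500.0
    n_samples: int = 5000
    target_kind: str = "fecg"

    @property
    def target_index(self) -> int:
        for i, s in enumerate(self.specs):
            if s.kind == self.target_kind:
                return i
        raise ParameterError(f"no {self.target_kind!r} source in scene")

    @property
    def target_tau(self) -> int:
        """One period of the target source, in samples."""
        return int(round(self.fs_hz / self.specs[self.target_index].rate_hz))


@dataclass
class TrialSummary:
    """Per-trial final PI plus the mean PI per iteration across trials."""

    per_trial_pi: np.ndarray
    iterations_trace: np.ndarray
    n_trials: int
    seed: int
    matrix_mode: str
    algorithm: str
    n_failures: int = 0


def _pi_trace(w_trace: list[np.ndarray], V: np.ndarray, A: MixingMatrix) -> np.ndarray:
    return np.array([
        performance_index(global_vector(w, V, A)) for w in w_trace
    ])


def _run_one(
    algorithm: str,
    x: SignalMatrix,
    tau: int,
    w0: np.ndarray,
    A: MixingMatrix,
) -> tuple[np.ndarray, np.ndarray]:
    """Run one trial; returns (final w, PI-per-iterate trace)."""
    x_white, transform = whiten(x)
    if algorithm == "fp1":
        pair = delayed_pair(x_white, tau)
        res = bse_tempng.fixed_point_extract(pair, w0)
        w_trace = res.w_trace
        w = res.w
    elif algorithm == "grad":
        pair = delayed_pair(x_white, tau)
        res = bse_tempng.gradient_ascent_extract(pair, w0, mu=0.1)
        w_trace = res.w_trace
        w = res.w
    elif algorithm == "fp2":
        report, res = two_stage_extract(x, tau, TwoStageConfig(w0=w0))
        w_trace = report.stage1.w_trace + res.w_trace[1:]
        w = res.w
    elif algorithm == "fastica_random":
        res = fastica_extract(x_white, w0)
        w_trace = res.w_trace
        w = res.w
    else:
        raise ParameterError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")
    return w, _pi_trace(w_trace, transform.V, A)


def run_trials(
    algorithm: str,
    n_trials: int,
    matrix_mode: str = "fixed_benchmark",
    seed: int = 0,
    scene: SceneConfig | None = None,
    w0_mode: str = "reference",
) -> TrialSummary:
    """Monte-Carlo evaluation of an extractor over seeded scenes.

    Trial ``t`` generates sources with seed ``seed + t``; in
    ``random_uniform`` mode it also draws a fresh uniform(0,1) mixing
    matrix.  ``w0_mode="reference"`` follows the benchmark protocol: the
    fixed reference vector with the fixed matrix, the last canonical basis
    vector with random matrices.  ``w0_mode="random"`` draws a fresh unit
    start per trial.  A trial's hard failure is recorded (PI = NaN), not
    fatal.
    """
    if n_trials < 1:
        raise ParameterError("n_trials must be >= 1")
    if matrix_mode not in ("fixed_benchmark", "random_uniform"):
        raise ParameterError(f"unknown matrix_mode {matrix_mode!r}")
    if algorithm not in ALGORITHMS:
        raise ParameterError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")
    scene = scene or SceneConfig()
    specs = list(scene.specs)
    n_src = len(specs)
    tau = scene.target_tau
    fixed_A = benchmark_mixing_matrix() if matrix_mode == "fixed_benchmark" else None

    per_trial = np.full(n_trials, np.nan)
    traces: list[np.ndarray] = []
    failures = 0
    for t in range(n_trials):
        trial_seed = seed + t
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), t, 0xA11]))
        sources = generate_sources(specs, scene.n_samples, scene.fs_hz, trial_seed)
        if fixed_A is not None:
            A = fixed_A
        else:
            A = random_mixing_matrix(n_src, n_src, rng)
        if algorithm == "fastica_random":
            # random-init baseline: a fresh start direction every trial
            w0 = rng.standard_normal(n_src)
        elif w0_mode == "random":
            w0 = rng.standard_normal(n_src)
        elif w0_mode == "reference":
            if matrix_mode == "fixed_benchmark" and n_src == REFERENCE_W0_6CH.size:
                w0 = REFERENCE_W0_6CH.copy()
            else:
                w0 = np.zeros(n_src)
                w0[-1] = 1.0
        else:
            raise ParameterError("w0_mode must be 'reference' or 'random'")
        x = mix(sources, A)
        try:
            _, pi_trace = _run_one(algorithm, x, tau, w0, A)
        except FecgbseError:
            failures += 1
            continue
        per_trial[t] = pi_trace[-1]
        traces.append(pi_trace)

    if traces:
        longest = max(len(tr) for tr in traces)
        padded = np.vstack([
            np.concatenate([tr, np.full(longest - len(tr), tr[-1])]) for tr in traces
        ])
        iterations_trace = padded.mean(axis=0)
    else:
        iterations_trace = np.array([])
    return TrialSummary(
        per_trial_pi=per_trial,
        iterations_trace=iterations_trace,
        n_trials=n_trials,
        seed=seed,
        matrix_mode=matrix_mode,
        algorithm=algorithm,
        n_failures=failures,
    )
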