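"""Synthetic ECG-mixture scenes and delimited-text signal I/O.

The generator emulates the six-source cutaneous-recording scene used
throughout the package's simulations: a strong maternal ECG, a weak and
faster fetal ECG, a slow breathing drift, sparse electrode-motion
transients, and two noises (Gaussian and impulsive).  Sources are
standardized to zero mean / unit variance before mixing so that the mixing
matrix alone controls the relative signal levels.

Mixtures follow the noiseless linear instantaneous model ``x(t) = A s(t)``.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import FormatError, ParameterError, ShapeError

__all__ = [
    "SourceSpec",
    "SignalMatrix",
    "MixingMatrix",
    "default_scene",
    "generate_sources",
    "mix",
    "benchmark_mixing_matrix",
    "random_mixing_matrix",
    "read_signals",
    "write_signals",
    "DEFAULT_FS_HZ",
    "DEFAULT_DURATION_S",
]

DEFAULT_FS_HZ = 500.0
DEFAULT_DURATION_S = 10.0

_PERIODIC_KINDS = frozenset({"mecg", "fecg", "breathing"})
_PULSE_KINDS = frozenset({"mecg", "fecg"})
_KNOWN_KINDS = _PERIODIC_KINDS | {"electrode", "noise_white", "noise_impulsive"}


@dataclass(frozen=True)
class SourceSpec:
    """Parametric description of one synthetic source.

    Parameters
    ----------
    kind:
        One of ``mecg``, ``fecg``, ``breathing``, ``electrode``,
        ``noise_white``, ``noise_impulsive``.
    rate_hz:
        Beats (pulse kinds) or cycles (breathing) per second; ignored for
        the aperiodic kinds except as an event rate for ``electrode``.
    amplitude:
        Peak scale of the raw waveform before standardization.  Because all
        rows are standardized to unit variance, it only matters when zero
        (degenerate) or when a future composite waveform mixes components.
    width_s:
        QRS pulse width parameter in seconds (pulse kinds only); the
        biphasic complex spans roughly ``5 * width_s``.
    seed_offset:
        Extra integer folded into the per-row random stream, so two
        otherwise identical specs in one scene stay independent.
    """

    kind: str
    rate_hz: float = 0.0
    amplitude: float = 1.0
    width_s: float | None = None
    seed_offset: int = 0

    def __post_init__(self) -> None:
        if self.kind not in _KNOWN_KINDS:
            raise ParameterError(f"unknown source kind {self.kind!r}")
        if self.kind in _PERIODIC_KINDS and not self.rate_hz > 0:
            raise ParameterError(
                f"{self.kind} requires rate_hz > 0, got {self.rate_hz}"
            )
        if self.amplitude < 0:
            raise ParameterError("amplitude must be >= 0")
        if self.width_s is not None and not self.width_s > 0:
            raise ParameterError("width_s must be > 0 when given")


@dataclass
class SignalMatrix:
    """Channels x samples array with its sampling rate and channel labels."""

    data: np.ndarray
    fs_hz: float
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ShapeError("signal data must be 2-D (channels x samples)")
        if not np.all(np.isfinite(self.data)):
            raise ShapeError("signal data contains non-finite entries")
        if self.data.shape[1] <= self.data.shape[0]:
            raise ShapeError(
                "need more samples than channels "
                f"(got {self.data.shape[0]} x {self.data.shape[1]})"
            )
        if not self.fs_hz > 0:
            raise ParameterError("fs_hz must be > 0")
        if self.labels is None:
            self.labels = tuple(f"ch{i + 1}" for i in range(self.data.shape[0]))
        else:
            self.labels = tuple(str(x) for x in self.labels)
            if len(self.labels) != self.data.shape[0]:
                raise ShapeError("one label per channel required")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class MixingMatrix:
    """Full-column-rank mixing matrix A of the model x(t) = A s(t)."""

    entries: np.ndarray

    def __post_init__(self) -> None:
        entries = np.asarray(self.entries, dtype=float)
        object.__setattr__(self, "entries", entries)
        if entries.ndim != 2:
            raise ShapeError("mixing matrix must be 2-D")
        if not np.all(np.isfinite(entries)):
            raise ShapeError("mixing matrix contains non-finite entries")
        if np.linalg.matrix_rank(entries) < entries.shape[1]:
            raise ShapeError("mixing matrix is column-rank deficient")

    @property
    def n_channels(self) -> int:
        return self.entries.shape[0]

    @property
    def n_sources(self) -> int:
        return self.entries.shape[1]


def default_scene() -> list[SourceSpec]:
    """The canonical six-source scene used in the simulation studies.

    Maternal ECG at 1.2 Hz (72 bpm), fetal ECG at 2.2 Hz (132 bpm) at a
    quarter of the maternal amplitude, 0.3 Hz breathing drift, sparse
    electrode transients, Gaussian white noise, and Laplacian impulsive
    noise.
    """
    return [
        SourceSpec("mecg", rate_hz=1.2, amplitude=1.0, width_s=0.018, seed_offset=0),
        SourceSpec("fecg", rate_hz=2.2, amplitude=0.25, width_s=0.010, seed_offset=1),
        SourceSpec("breathing", rate_hz=0.3, amplitude=1.0, seed_offset=2),
        SourceSpec("electrode", rate_hz=0.3, amplitude=1.0, seed_offset=3),
        SourceSpec("noise_white", amplitude=1.0, seed_offset=4),
        SourceSpec("noise_impulsive", amplitude=1.0, seed_offset=5),
    ]


def _pulse_train(spec: SourceSpec, n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    # Biphasic QRS-like complex: derivative-of-Gaussian bump repeated at
    # rate_hz, with a random beat phase per realization.  Periodicity is
    # exact in continuous phase, so the sample autocorrelation peaks at
    # round(fs / rate_hz).
    width = spec.width_s if spec.width_s is not None else 0.02
    t = np.arange(n) / fs
    phase0 = rng.uniform(0.0, 1.0)
    phase = np.mod(t * spec.rate_hz + phase0, 1.0)
    dt = (phase - 0.5) / spec.rate_hz  # seconds from the nearest beat centre
    u = dt / width
    return -u * np.exp(-0.5 * u * u)


def _breathing(spec: SourceSpec, n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    t = np.arange(n) / fs
    phase0 = rng.uniform(0.0, 2.0 * np.pi)
    return np.sin(2.0 * np.pi * spec.rate_hz * t + phase0)


def _electrode(spec: SourceSpec, n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    # Electrode-motion transients: sparse abrupt baseline jumps that decay
    # back exponentially (AC-coupled electrodes do not hold a DC offset).
    rate = spec.rate_hz if spec.rate_hz > 0 else 0.3
    duration = n / fs
    n_events = max(1, int(rng.poisson(rate * duration)))
    lo, hi = n // 10, max(n // 10 + 1, (9 * n) // 10)
    positions = rng.integers(lo, hi, size=n_events)
    impulses = np.zeros(n)
    amplitudes = rng.choice([-1.0, 1.0], size=n_events) * rng.uniform(0.5, 1.5, size=n_events)
    np.add.at(impulses, positions, amplitudes)
    tau_decay = 0.3  # s, baseline-recovery time constant
    kernel_len = min(n, int(5 * tau_decay * fs) + 1)
    kernel = np.exp(-np.arange(kernel_len) / (tau_decay * fs))
    return np.convolve(impulses, kernel)[:n]


def _generate_row(spec: SourceSpec, n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    if spec.kind in _PULSE_KINDS:
        raw = _pulse_train(spec, n, fs, rng)
    elif spec.kind == "breathing":
        raw = _breathing(spec, n, fs, rng)
    elif spec.kind == "electrode":
        raw = _electrode(spec, n, fs, rng)
    elif spec.kind == "noise_white":
        raw = rng.standard_normal(n)
    elif spec.kind == "noise_impulsive":
        raw = rng.laplace(size=n)
    else:  # pragma: no cover - guarded by SourceSpec.__post_init__
        raise ParameterError(f"unknown source kind {spec.kind!r}")
    raw = spec.amplitude * raw
    sd = raw.std()
    if not sd > 0:
        raise ParameterError(
            f"source {spec.kind!r} produced a constant row (amplitude 0?)"
        )
    return (raw - raw.mean()) / sd


def generate_sources(
    specs: list[SourceSpec], n_samples: int, fs_hz: float, seed: int
) -> SignalMatrix:
    """Generate one standardized row per :class:`SourceSpec`.

    Every row has zero sample mean and unit sample variance; generation is
    a pure function of ``(specs, n_samples, fs_hz, seed)``.
    """
    if not specs:
        raise ParameterError("specs must be non-empty")
    if not fs_hz > 0:
        raise ParameterError("fs_hz must be > 0")
    if n_samples < 2 * fs_hz:
        raise ParameterError(
            f"need at least 2 s of data: n_samples >= {2 * fs_hz:.0f}"
        )
    rows = []
    for i, spec in enumerate(specs):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), i, spec.seed_offset]))
        rows.append(_generate_row(spec, int(n_samples), float(fs_hz), rng))
    labels = tuple(s.kind for s in specs)
    return SignalMatrix(np.vstack(rows), float(fs_hz), labels)


def mix(sources: SignalMatrix, A: MixingMatrix) -> SignalMatrix:
    """Apply the linear instantaneous mixing model x(t) = A s(t)."""
    if A.n_sources != sources.n_channels:
        raise ShapeError(
            f"mixing matrix has {A.n_sources} columns but "
            f"{sources.n_channels} sources were given"
        )
    return SignalMatrix(A.entries @ sources.data, sources.fs_hz)


def benchmark_mixing_matrix() -> MixingMatrix:
    """The fixed 6x6 benchmark mixing matrix used in the simulation study."""
    return MixingMatrix(np.array([
        [0.8246, 0.9469, 0.7384, 0.1109, 0.5211, 0.5746],
        [0.4530, 0.5101, 0.9764, 0.3752, 0.7743, 0.8639],
        [0.3806, 0.7919, 0.5233, 0.3299, 0.1203, 0.1986],
        [0.9259, 0.4522, 0.4299, 0.3421, 0.6255, 0.6725],
        [0.7408, 0.8492, 0.2072, 0.8171, 0.3466, 0.9018],
        [0.7376, 0.3904, 0.3234, 0.5317, 0.3346, 0.1992],
    ]))


def random_mixing_matrix(
    n_channels: int, n_sources: int, rng: np.random.Generator, max_cond: float = 1e6
) -> MixingMatrix:
    """Draw a random mixing matrix with i.i.d. uniform(0, 1) entries.

    Redraws until the condition number is below ``max_cond`` so the mixture
    is never numerically degenerate.
    """
    while True:
        entries = rng.uniform(0.0, 1.0, size=(n_channels, n_sources))
        if np.linalg.cond(entries) < max_cond:
            return MixingMatrix(entries)


def write_signals(x: SignalMatrix, path) -> None:
    """Write a signal matrix as CSV, one channel per column.

    The sampling rate travels in a ``# fs_hz=...`` comment on the first
    line; values are printed with 17 significant digits so a round trip is
    lossless to double precision.
    """
    df = pd.DataFrame(x.data.T, columns=list(x.labels))
    with open(path, "w") as fh:
        fh.write(f"# fs_hz={x.fs_hz!r}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_signals(path) -> SignalMatrix:
    """Read a signal matrix written by :func:`write_signals`.

    Accepts any rectangular delimited numeric table with a header row; the
    sampling rate defaults to 1 Hz when no ``# fs_hz=`` comment is present.
    """
    with open(path) as fh:
        first = fh.readline()
        if not first:
            raise FormatError(f"{path}: empty file")
        fs_hz = 1.0
        if first.startswith("#"):
            if "fs_hz=" in first:
                try:
                    fs_hz = float(first.split("fs_hz=", 1)[1].strip())
                except ValueError as exc:
                    raise FormatError(f"{path}: bad fs_hz header") from exc
        else:
            fh.seek(0)
        try:
            df = pd.read_csv(fh)
        except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
            raise FormatError(f"{path}: {exc}") from exc
    if df.empty:
        raise FormatError(f"{path}: no data rows")
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    if np.isnan(values).any():
        raise FormatError(f"{path}: non-numeric cell encountered")
    return SignalMatrix(values.T, fs_hz, tuple(df.columns))
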