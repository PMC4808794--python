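"""Centering, prewhitening, delayed-signal alignment, and lag selection.

Whitening uses the eigendecomposition of the sample covariance,
``V = diag(eigvals) ** -1/2 @ E.T``, so that the whitened mixture has unit
sample covariance.  All time-lagged expectations in the package are sample
means over the overlapping range of a :class:`DelayedPair`: the first
``tau`` samples are truncated, never wrapped, because circular wrapping
would fabricate correlations across the record boundary.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateDataError, ParameterError, ShapeError
from .synthio import SignalMatrix

__all__ = [
    "WhiteningTransform",
    "DelayedPair",
    "center",
    "fit_whitening",
    "apply_whitening",
    "whiten",
    "delayed_pair",
    "estimate_delay",
    "autocorrelation",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WhiteningTransform:
    """Affine map x -> V (x - mean) that spheres the data it was fit to."""

    mean: np.ndarray
    V: np.ndarray
    eigvals: np.ndarray

    @property
    def n_kept(self) -> int:
        return self.V.shape[0]

    def pseudo_inverse(self) -> np.ndarray:
        """Matrix mapping whitened coordinates back to centered ones."""
        return np.linalg.pinv(self.V)


@dataclass(frozen=True)
class DelayedPair:
    """Aligned blocks x(t) and x(t - tau) over the overlapping time range.

    ``current[:, j]`` holds time ``tau + j`` and ``lagged[:, j]`` time
    ``j``; both blocks have ``T - tau`` columns.
    """

    current: np.ndarray
    lagged: np.ndarray
    tau: int

    def __post_init__(self) -> None:
        if self.current.shape != self.lagged.shape:
            raise ShapeError("current and lagged blocks must have equal shape")

    @property
    def n_channels(self) -> int:
        return self.current.shape[0]

    @property
    def n_samples(self) -> int:
        return self.current.shape[1]


def center(x: SignalMatrix) -> tuple[SignalMatrix, np.ndarray]:
    """Remove each channel's sample mean; returns the centered signal and
    the mean vector that restores the input."""
    if x.n_samples < 2:
        raise ShapeError("need at least 2 samples to center")
    mean = x.data.mean(axis=1)
    return SignalMatrix(x.data - mean[:, None], x.fs_hz, x.labels), mean


def fit_whitening(x_centered: SignalMatrix, retain_eps: float = 1e-10) -> WhiteningTransform:
    """Fit a sphering transform to (already centered) data.

    Components whose covariance eigenvalue is at most
    ``retain_eps * max_eigenvalue`` are dropped (rank deficiency); the drop
    is logged.  The stored mean is the row mean of the data passed in, so
    applying the transform to its own fitting data always yields identity
    covariance even if the caller forgot to center.
    """
    X = x_centered.data
    mean = X.mean(axis=1)
    Xc = X - mean[:, None]
    cov = (Xc @ Xc.T) / Xc.shape[1]
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    if not eigvals[0] > 0:
        raise DegenerateDataError("zero-variance input: nothing to whiten")
    keep = eigvals > retain_eps * eigvals[0]
    if not np.all(keep):
        logger.warning(
            "dropping %d of %d components below the retention threshold",
            int((~keep).sum()), keep.size,
        )
    eigvals, eigvecs = eigvals[keep], eigvecs[:, keep]
    V = (eigvecs / np.sqrt(eigvals)).T
    return WhiteningTransform(mean=mean, V=V, eigvals=eigvals)


def apply_whitening(w: WhiteningTransform, x: SignalMatrix) -> SignalMatrix:
    """Apply V (x - mean) to a signal with matching channel count."""
    if x.n_channels != w.mean.shape[0]:
        raise ShapeError(
            f"transform expects {w.mean.shape[0]} channels, got {x.n_channels}"
        )
    data = w.V @ (x.data - w.mean[:, None])
    labels = None if w.n_kept != x.n_channels else tuple(f"w{i+1}" for i in range(w.n_kept))
    return SignalMatrix(data, x.fs_hz, labels)


def whiten(x: SignalMatrix, retain_eps: float = 1e-10) -> tuple[SignalMatrix, WhiteningTransform]:
    """Convenience wrapper: center, fit, and apply in one call."""
    centered, _ = center(x)
    transform = fit_whitening(centered, retain_eps=retain_eps)
    # keep the raw-data mean so the transform maps raw coordinates directly
    full_mean = x.data.mean(axis=1)
    transform = WhiteningTransform(mean=full_mean, V=transform.V, eigvals=transform.eigvals)
    return apply_whitening(transform, x), transform


def delayed_pair(x_white: SignalMatrix, tau: int) -> DelayedPair:
    """Slice a signal into aligned current / lagged blocks at lag ``tau``."""
    tau = int(tau)
    if not 0 < tau < x_white.n_samples / 2:
        raise ParameterError(
            f"tau must satisfy 0 < tau < n_samples/2, got {tau} "
            f"with {x_white.n_samples} samples"
        )
    return DelayedPair(
        current=x_white.data[:, tau:],
        lagged=x_white.data[:, :-tau],
        tau=tau,
    )


def autocorrelation(row: np.ndarray, tau: int) -> float:
    """Normalized sample autocorrelation at lag ``tau`` (truncation convention)."""
    row = np.asarray(row, dtype=float)
    row = row - row.mean()
    var = float(np.mean(row * row))
    if var == 0.0:
        return 0.0
    return float(np.mean(row[tau:] * row[:-tau]) / var)


def estimate_delay(x_white: SignalMatrix, lag_min: int, lag_max: int) -> int:
    """Pick the lag with the strongest mean autocorrelation across channels.

    Scans ``tau in [lag_min, lag_max]``, scores each lag by the mean over
    channels of the (signed) sample autocorrelation, and returns the
    argmax (ties broken toward the smallest lag).  The signed score makes
    the estimate land on a full fundamental period rather than on the
    anti-correlated half period of an oscillatory source.  This is a
    pragmatic stand-in for a dedicated heartbeat-period estimator: for a
    periodic source present in all channels the score peaks at one period.
    """
    lag_min, lag_max = int(lag_min), int(lag_max)
    if lag_min < 1 or lag_max >= x_white.n_samples / 2 or lag_max < lag_min:
        raise ParameterError(
            f"need 1 <= lag_min <= lag_max < n_samples/2, got [{lag_min}, {lag_max}]"
        )
    lags = np.arange(lag_min, lag_max + 1)
    scores = np.empty(lags.size)
    for k, tau in enumerate(lags):
        scores[k] = np.mean(
            [autocorrelation(row, int(tau)) for row in x_white.data]
        )
    return int(lags[int(np.argmax(scores))])
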