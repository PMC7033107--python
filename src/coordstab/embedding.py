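"""Time-delay embedding: AMI delay selection, FNN dimension selection, embedding.

A scalar series x_t is unfolded into state vectors
(x_i, x_{i+tau}, ..., x_{i+(m-1)tau}). The delay tau is chosen at the first
local minimum of the average mutual information between the series and its
lagged copy; the dimension m is chosen where the fraction of false nearest
neighbours drops to (near) zero. The analysis defaults fix tau = 25 frames
and m = 6 (a quarter cycle at 100 points per cycle, in six dimensions), with
the selectors available as a verification mode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import DegenerateInputError, InsufficientDataError, ParameterError

__all__ = [
    "EmbeddingParams",
    "EmbeddedAttractor",
    "average_mutual_information",
    "select_delay",
    "false_nearest_neighbors",
    "select_dimension",
    "delay_embed",
]


@dataclass(frozen=True)
class EmbeddingParams:
    """Delay-embedding parameters and FNN thresholds.

    Rtol is the distance-ratio test threshold, Atol the attractor-size test
    threshold, fnn_fraction_cutoff the acceptable residual FNN fraction.
    """

    delay: int = 25
    dimension: int = 6
    rtol: float = 15.0
    atol: float = 2.0
    fnn_fraction_cutoff: float = 0.01

    def __post_init__(self) -> None:
        if self.delay < 1 or self.dimension < 1:
            raise ParameterError("delay and dimension must be >= 1")
        if self.rtol <= 1:
            raise ParameterError("Rtol must exceed 1")


@dataclass(frozen=True)
class EmbeddedAttractor:
    """Delay-embedded trajectory: points[i] = (x_i, x_{i+tau}, ...)."""

    points: np.ndarray  # (N', m)
    delay: int
    dimension: int

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, float)
        object.__setattr__(self, "points", pts)
        if pts.ndim != 2 or pts.shape[0] < 1:
            raise ParameterError("attractor needs at least one m-dimensional point")
        if not np.all(np.isfinite(pts)):
            raise ParameterError("attractor points must be finite")

    def __len__(self) -> int:
        return self.points.shape[0]


def _as_values(signal) -> np.ndarray:
    values = getattr(signal, "values", signal)
    return np.asarray(values, dtype=float)


def average_mutual_information(
    signal, max_lag: int, n_bins: int = 4
) -> tuple[np.ndarray, np.ndarray]:
    """AMI (bits) between x_t and x_{t+lag} for lags 0..max_lag.

    The joint distribution is estimated on an ``n_bins x n_bins`` equal-width
    histogram (default 4 x 4 = 16 cells) whose edges span the full signal
    range — the same edges for both coordinates, which makes the curve
    symmetric under time reversal. AMI(0) is the entropy of the binned
    marginal, hence the curve's maximum.

    The partition is deliberately coarse: on noiseless deterministic signals
    a fine partition resolves the functional dependence between x_t and
    x_{t+lag} at every lag, pinning AMI near its entropy bound and erasing
    the quarter-period minimum that delay selection relies on.
    """
    x = _as_values(signal)
    if n_bins < 2:
        raise ParameterError("need at least 2 bins per axis")
    if x.size <= max_lag + 1:
        raise InsufficientDataError("signal shorter than max_lag + 2")
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi <= lo:
        raise DegenerateInputError("constant signal has zero-entropy marginal")
    edges = np.linspace(lo, hi, n_bins + 1)
    # digitize once; searchsorted on the interior edges gives bins 0..n_bins-1
    binned = np.searchsorted(edges[1:-1], x, side="right")

    lags = np.arange(max_lag + 1)
    ami = np.empty(lags.size)
    for i, lag in enumerate(lags):
        a = binned[: x.size - lag]
        b = binned[lag:]
        joint = np.bincount(a * n_bins + b, minlength=n_bins * n_bins).astype(float)
        joint /= joint.sum()
        pa = joint.reshape(n_bins, n_bins).sum(axis=1)
        pb = joint.reshape(n_bins, n_bins).sum(axis=0)
        outer = np.outer(pa, pb).ravel()
        nz = joint > 0
        ami[i] = float(np.sum(joint[nz] * np.log2(joint[nz] / outer[nz])))
    return lags, ami


def select_delay(lags: np.ndarray, ami: np.ndarray, window: int = 5) -> int:
    """First local minimum of the AMI curve (global minimum as fallback).

    A lag qualifies when its AMI is below the preceding value and no lag
    within ``window`` of it is lower — the window makes the rule robust to
    the cell-alignment jitter a histogram estimator shows on near-periodic
    signals. ``window=1`` recovers the strict three-point local minimum.
    """
    lags = np.asarray(lags)
    ami = np.asarray(ami, float)
    if ami.size < 3:
        raise ParameterError("AMI curve needs at least 3 points")
    if window < 1:
        raise ParameterError("window must be >= 1")
    for i in range(1, ami.size - 1):  # endpoints cannot be local minima
        lo, hi = max(0, i - window), min(ami.size, i + window + 1)
        if ami[i] < ami[i - 1] and ami[i] <= np.min(ami[lo:hi]):
            return int(lags[i])
    warnings.warn(
        "AMI curve has no local minimum; falling back to the global minimum",
        stacklevel=2,
    )
    return int(lags[np.argmin(ami[1:]) + 1])


def delay_embed(signal, delay: int, dimension: int) -> EmbeddedAttractor:
    """Embed a scalar series; yields exactly N - (m-1)*tau points."""
    x = _as_values(signal)
    if delay < 1 or dimension < 1:
        raise ParameterError("delay and dimension must be >= 1")
    n_prime = x.size - (dimension - 1) * delay
    if n_prime < 1:
        raise InsufficientDataError(
            f"series of length {x.size} too short for m={dimension}, tau={delay}; "
            f"need more than {(dimension - 1) * delay} samples"
        )
    idx = np.arange(n_prime)[:, None] + delay * np.arange(dimension)[None, :]
    return EmbeddedAttractor(points=x[idx], delay=delay, dimension=dimension)


def false_nearest_neighbors(
    signal,
    delay: int,
    max_m: int = 10,
    rtol: float = 15.0,
    atol: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Fraction of false nearest neighbours for m = 1..max_m.

    For each point in dimension m, the nearest neighbour is found; it is
    declared false if adding the (m+1)-th coordinate either stretches the
    pair by more than ``rtol`` relative to its m-dimensional distance, or
    moves it beyond ``atol`` attractor sizes (standard deviation of the
    series). Deterministic low-dimensional signals drop to ~0 quickly; noise
    stays high for all m.
    """
    x = _as_values(signal)
    r_attractor = float(np.std(x))
    if r_attractor == 0:
        raise DegenerateInputError("constant signal")
    ms = np.arange(1, max_m + 1)
    fractions = np.empty(ms.size)
    for k, m in enumerate(ms):
        n_use = x.size - m * delay  # need x[i + m*delay] for the test
        if n_use < 10:
            raise InsufficientDataError(
                f"only {max(n_use, 0)} usable points at m={m}, tau={delay}; need >= 10"
            )
        emb = delay_embed(x, delay, m).points[:n_use]
        tree = cKDTree(emb)
        dist, nbr = tree.query(emb, k=2)
        dist, nbr = dist[:, 1], nbr[:, 1]
        extra = np.abs(x[np.arange(n_use) + m * delay] - x[nbr + m * delay])
        # floor the denominator at a sliver of the attractor size: exact
        # revisits of a periodic orbit have float-epsilon separations in both
        # dist and extra, and their ratio is numerical noise, not a neighbour
        # turning false
        ratio = extra / np.maximum(dist, 1e-10 * r_attractor)
        dist_m1 = np.sqrt(dist**2 + extra**2)
        false = (ratio > rtol) | (dist_m1 / r_attractor > atol)
        fractions[k] = float(np.mean(false))
    return ms, fractions


def select_dimension(ms: np.ndarray, fractions: np.ndarray, cutoff: float = 0.01) -> int:
    """Smallest m whose FNN fraction is <= cutoff (max m as fallback)."""
    ms = np.asarray(ms)
    fractions = np.asarray(fractions, float)
    if fractions.size == 0:
        raise ParameterError("empty FNN curve")
    ok = fractions <= cutoff
    if np.any(ok):
        return int(ms[np.argmax(ok)])
    warnings.warn(
        "no dimension reached the FNN cutoff; returning the largest tried",
        stacklevel=2,
    )
    return int(ms[-1])
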