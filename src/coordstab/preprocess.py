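"""Kinematic preprocessing: thinning, filtering, differentiation, cycle extraction.

Turns raw marker trajectories into the scalar series the downstream stages
consume: low-pass-filtered positions, vertical velocity, head-wrist 3D
distance, and fixed-length (2500-point) standardized segments covering 25
same-hand catch-to-catch cycles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .errors import InsufficientDataError, ParameterError, ShapeError

__all__ = [
    "SampledSignal",
    "FilterSpec",
    "downsample_thinning",
    "residual_cutoff",
    "butterworth_filter",
    "differentiate",
    "head_wrist_distance",
    "standardize_length",
    "extract_cycles",
]


@dataclass(frozen=True)
class SampledSignal:
    """A uniformly sampled scalar kinematic series.

    Parameters
    ----------
    values : array of float
        Sample values (mm for positions/distances, mm/s for velocities).
    rate : float
        Sampling rate in Hz, > 0.
    t0 : float
        Time of the first sample, s.
    kind : str
        Semantic tag, e.g. ``position_SI``, ``velocity_SI``, ``distance_3D``.
    """

    values: np.ndarray
    rate: float
    t0: float = 0.0
    kind: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size < 2:
            raise ParameterError("signal needs a 1-D array of length >= 2")
        if not np.all(np.isfinite(v)):
            raise ParameterError("signal values must be finite")
        if not self.rate > 0:
            raise ParameterError(f"rate must be > 0, got {self.rate}")

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.rate

    @property
    def duration(self) -> float:
        """Support length (first to last sample), s."""
        return (self.values.size - 1) / self.rate

    def with_values(self, values: np.ndarray, kind: str | None = None) -> "SampledSignal":
        return replace(self, values=values, kind=self.kind if kind is None else kind)


@dataclass(frozen=True)
class FilterSpec:
    """Second-order low-pass Butterworth specification."""

    cutoff: float
    order: int = 2
    zero_phase: bool = True

    def validate(self, rate: float) -> None:
        if not 0 < self.cutoff < rate / 2:
            raise ParameterError(
                f"cutoff {self.cutoff} Hz must lie in (0, Nyquist={rate / 2} Hz)"
            )
        if self.order < 1:
            raise ParameterError("filter order must be >= 1")


def downsample_thinning(signal: SampledSignal, factor: int) -> SampledSignal:
    """Decimate by keeping every ``factor``-th sample (no anti-alias filter).

    This is literal thinning, as used to bring 1000 Hz audio/sync channels
    down to the 100 Hz motion-capture rate.
    """
    if not isinstance(factor, (int, np.integer)) or factor < 1:
        raise ParameterError(f"thinning factor must be a positive integer, got {factor}")
    return SampledSignal(
        values=signal.values[::factor],
        rate=signal.rate / factor,
        t0=signal.t0,
        kind=signal.kind,
    )


def butterworth_filter(signal: SampledSignal, spec: FilterSpec) -> SampledSignal:
    """Low-pass Butterworth filter, dual-pass (zero phase lag) by default."""
    spec.validate(signal.rate)
    b, a = sps.butter(spec.order, spec.cutoff, btype="low", fs=signal.rate)
    if spec.zero_phase:
        out = sps.filtfilt(b, a, signal.values)
    else:
        out = sps.lfilter(b, a, signal.values)
    return signal.with_values(out)


def residual_cutoff(
    signal: SampledSignal,
    candidate_cutoffs: np.ndarray | None = None,
    tail_fraction: float = 0.5,
) -> float:
    """Choose a low-pass cutoff by residual analysis (Winter's procedure).

    For each candidate cutoff the RMS residual between the raw and filtered
    series is computed. Over the high-frequency tail of the residual-vs-cutoff
    curve (the noise-dominated regime, here the upper ``tail_fraction`` of the
    candidates) a straight line is fitted; its intercept at 0 Hz estimates the
    noise floor. The chosen cutoff is the smallest candidate whose residual
    does not exceed that intercept.

    A noiseless signal yields an (almost) flat, near-zero curve; in that case
    the smallest candidate is returned with a warning.
    """
    nyq = signal.rate / 2
    if candidate_cutoffs is None:
        candidate_cutoffs = np.arange(1.0, min(21.0, nyq), 1.0)
    fc = np.asarray(candidate_cutoffs, dtype=float)
    if fc.size < 5:
        raise ParameterError("need at least 5 candidate cutoffs")
    if np.any(fc <= 0) or np.any(fc >= nyq):
        raise ParameterError("candidate cutoffs must lie in (0, Nyquist)")
    fc = np.sort(fc)

    res = np.empty(fc.size)
    for i, f in enumerate(fc):
        filt = butterworth_filter(signal, FilterSpec(cutoff=f))
        res[i] = float(np.sqrt(np.mean((signal.values - filt.values) ** 2)))

    n_tail = max(2, int(round(tail_fraction * fc.size)))
    slope, intercept = np.polyfit(fc[-n_tail:], res[-n_tail:], 1)

    # a noiseless signal has an essentially flat, near-zero tail: call the
    # curve degenerate when the extrapolated noise floor is below 0.5% of the
    # raw RMS amplitude
    floor = 0.005 * float(np.std(signal.values))
    ok = res <= intercept
    if intercept <= floor or not np.any(ok):
        warnings.warn(
            "flat/degenerate residual curve (noiseless input?); "
            "returning the smallest candidate cutoff",
            stacklevel=2,
        )
        return float(fc[0])
    return float(fc[np.argmax(ok)])


def differentiate(signal: SampledSignal) -> SampledSignal:
    """Differentiate (central differences; one-sided at the ends)."""
    if len(signal) < 3:
        raise InsufficientDataError("differentiation needs at least 3 samples")
    vel = np.gradient(signal.values, 1.0 / signal.rate)
    kind = signal.kind.replace("position", "velocity") if signal.kind else "velocity"
    return signal.with_values(vel, kind=kind)


def head_wrist_distance(head, wrist) -> SampledSignal:
    """Per-frame Euclidean distance between two 3D marker trajectories (mm)."""
    hx, wx = np.asarray(head.xyz, float), np.asarray(wrist.xyz, float)
    if hx.shape != wx.shape:
        raise ShapeError(f"trajectory shapes differ: {hx.shape} vs {wx.shape}")
    if head.rate != wrist.rate:
        raise ShapeError("trajectory rates differ")
    d = np.linalg.norm(hx - wx, axis=1)
    return SampledSignal(values=d, rate=head.rate, kind="distance_3D")


def standardize_length(signal: SampledSignal, n_points: int = 2500) -> SampledSignal:
    """Resample onto ``n_points`` equally spaced times by linear interpolation.

    The new grid spans the original support exactly, so the endpoint values
    are preserved.
    """
    if n_points < 2:
        raise ParameterError("n_points must be >= 2")
    old_t = np.arange(len(signal)) / signal.rate
    new_t = np.linspace(0.0, old_t[-1], n_points)
    out = np.interp(new_t, old_t, signal.values)
    new_rate = (n_points - 1) / old_t[-1]
    return SampledSignal(values=out, rate=new_rate, t0=signal.t0, kind=signal.kind)


def extract_cycles(
    signal: SampledSignal,
    catch_times: np.ndarray,
    n_cycles: int = 25,
    skip_cycles: int = 2,
) -> SampledSignal:
    """Cut the segment spanning ``n_cycles`` same-hand catch-to-catch cycles.

    ``catch_times`` are the catch times of ONE hand (s, same clock as the
    signal). The first ``skip_cycles`` complete cycles are treated as warm-up
    and skipped; the returned segment runs from the end of the warm-up to the
    catch ``n_cycles`` later.
    """
    ct = np.asarray(catch_times, dtype=float)
    t_end = signal.t0 + signal.duration
    ct = ct[(ct >= signal.t0) & (ct <= t_end)]
    n_avail = max(0, ct.size - 1 - skip_cycles)
    if n_avail < n_cycles:
        raise InsufficientDataError(
            f"found {n_avail} complete cycles after skipping {skip_cycles}, "
            f"need {n_cycles}"
        )
    start, end = ct[skip_cycles], ct[skip_cycles + n_cycles]
    i0 = int(np.ceil((start - signal.t0) * signal.rate))
    i1 = int(np.floor((end - signal.t0) * signal.rate))
    return SampledSignal(
        values=signal.values[i0 : i1 + 1],
        rate=signal.rate,
        t0=signal.t0 + i0 / signal.rate,
        kind=signal.kind,
    )
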