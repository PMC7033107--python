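"""Coordination Pattern Index: spectral concentration at the movement fundamental.

The CPI is the proportion of spectral power of the vertical hand velocity
that falls within a narrow band around the fundamental movement frequency
f0. A smoothly rhythmic (sinusoid-like) movement concentrates its power at
f0 (CPI near 1); a discrete move-and-dwell movement spreads power into
harmonics (CPI well below 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import DegenerateInputError, ParameterError, ResolutionError
from .preprocess import SampledSignal
from .synthetic import BeepTrain

__all__ = [
    "SpectralDensity",
    "CpiResult",
    "power_spectrum",
    "fundamental_frequency",
    "coordination_pattern_index",
    "normalize_spectrum",
    "participant_cpi",
]


@dataclass(frozen=True)
class SpectralDensity:
    """One-sided power spectral density (or its f/f0-normalized variant)."""

    freqs: np.ndarray
    power: np.ndarray
    resolution: float

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, float)
        p = np.asarray(self.power, float)
        object.__setattr__(self, "freqs", f)
        object.__setattr__(self, "power", p)
        if f.size != p.size:
            raise ParameterError("freqs and power must have equal length")
        if np.any(np.diff(f) <= 0) or f[0] < 0:
            raise ParameterError("freqs must be non-negative ascending")
        if np.any(p < -1e-12):
            raise ParameterError("power must be non-negative")


@dataclass(frozen=True)
class CpiResult:
    """CPI for one signal: fundamental, band actually used, and the index."""

    f0: float
    band: tuple
    cpi: float

    def __post_init__(self) -> None:
        lo, hi = self.band
        if not lo < self.f0 < hi:
            raise ParameterError("band must bracket f0")
        if not 0 <= self.cpi <= 1 + 1e-12:
            raise ParameterError("cpi must lie in [0, 1]")


def power_spectrum(velocity: SampledSignal) -> SpectralDensity:
    """Rectangular-window periodogram of a uniformly sampled signal.

    Density scaling, so ``sum(power) * resolution`` equals the signal's mean
    square (Parseval); downstream CPI sums exclude the DC bin.
    """
    if len(velocity) < 64:
        raise ParameterError("need at least 64 samples for a usable spectrum")
    freqs, power = sps.periodogram(
        velocity.values, fs=velocity.rate, window="boxcar", detrend=False
    )
    return SpectralDensity(freqs=freqs, power=power, resolution=float(freqs[1] - freqs[0]))


def fundamental_frequency(
    beeps: BeepTrain | None = None,
    signal: SampledSignal | None = None,
    convention: str = "half_beep_rate",
) -> float:
    """Fundamental movement frequency f0 of one hand, Hz.

    For fixed-tempo metronome trials the default convention is
    ``f0 = 1 / (2 * interval)``: catches alternate hands in cascade juggling,
    so each hand completes one full cycle per two beeps (``beep_rate`` is
    selectable). Without a metronome (Preferred condition) f0 is picked as
    the largest non-DC periodogram peak of the hand's vertical velocity.
    Ramped trains have no single tempo, hence no f0.
    """
    if beeps is not None and beeps.condition == "fixed":
        interval_s = beeps.interval_ms / 1000.0
        if convention == "half_beep_rate":
            return 1.0 / (2.0 * interval_s)
        if convention == "beep_rate":
            return 1.0 / interval_s
        raise ParameterError(f"unknown f0 convention {convention!r}")
    if beeps is not None and beeps.condition in ("up_ramp", "down_ramp"):
        raise ParameterError("f0 is undefined for ramped beep trains")
    if signal is None:
        raise ParameterError("need a velocity signal to pick f0 without a metronome")
    spec = power_spectrum(signal)
    idx = 1 + int(np.argmax(spec.power[1:]))  # skip DC
    return float(spec.freqs[idx])


def coordination_pattern_index(
    spectrum: SpectralDensity,
    f0: float,
    band_width_fraction: float = 0.10,
) -> CpiResult:
    """Proportion of (non-DC) spectral power inside a band around f0.

    The band has total width ``band_width_fraction * f0`` centred on f0,
    i.e. f0 +/- 5% by default. The denominator is all power above DC up to
    Nyquist, so the CPI is amplitude-scale invariant and lies in [0, 1].
    """
    if not 0 < f0 <= spectrum.freqs[-1]:
        raise ParameterError(f"f0={f0} outside spectrum support")
    if not 0 < band_width_fraction < 2:
        raise ParameterError("band_width_fraction must lie in (0, 2)")
    half = band_width_fraction / 2.0
    lo, hi = f0 * (1 - half), f0 * (1 + half)
    in_band = (spectrum.freqs >= lo) & (spectrum.freqs <= hi) & (spectrum.freqs > 0)
    if not np.any(in_band):
        needed = int(np.ceil(spectrum.freqs[-1] * 2 / (f0 * band_width_fraction)))
        raise ResolutionError(
            f"no spectral bin falls in [{lo:.4g}, {hi:.4g}] Hz "
            f"(resolution {spectrum.resolution:.4g} Hz); "
            f"need roughly {needed} samples"
        )
    total = float(np.sum(spectrum.power[spectrum.freqs > 0]))
    if total <= 0:
        raise DegenerateInputError("signal has no power above DC")
    cpi = float(np.sum(spectrum.power[in_band]) / total)
    return CpiResult(f0=f0, band=(lo, hi), cpi=min(cpi, 1.0))


def normalize_spectrum(spectrum: SpectralDensity, f0: float) -> SpectralDensity:
    """Express the frequency axis in multiples of f0 (fundamental at 1.0)."""
    if not f0 > 0:
        raise ParameterError("f0 must be > 0")
    return SpectralDensity(
        freqs=spectrum.freqs / f0,
        power=spectrum.power,
        resolution=spectrum.resolution / f0,
    )


def participant_cpi(left, right) -> float:
    """Representative CPI: mean of the left- and right-hand values."""
    lv = left.cpi if isinstance(left, CpiResult) else float(left)
    rv = right.cpi if isinstance(right, CpiResult) else float(right)
    for v in (lv, rv):
        if not 0 <= v <= 1:
            raise ParameterError("per-hand CPI must lie in [0, 1]")
    return 0.5 * (lv + rv)
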