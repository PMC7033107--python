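"""Recurrence quantification analysis: %REC, %DET, %MAXLINE.

A recurrence matrix marks pairs of times at which the embedded trajectory
returns within a radius of itself; the radius is 15% of the maximum
pairwise distance, and a Theiler band (minimum recurrence time, 10 frames)
around the main diagonal is excluded from every count. From the diagonal
line structure three indices are computed:

%REC      recurrent cells / valid cells (overall revisitation),
%DET      recurrent points on diagonals of length >= the minimum line
          length / all recurrent points (deterministic structure),
%MAXLINE  longest qualifying diagonal / longest achievable diagonal
          (attractor strength).

Counting is done on the upper triangle only; by symmetry this equals the
both-triangle counts for all three ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .errors import DegenerateInputError, ParameterError
from .embedding import EmbeddedAttractor

__all__ = [
    "RecurrenceMatrix",
    "RqaMetrics",
    "pairwise_distance_matrix",
    "recurrence_matrix",
    "diagonal_line_histogram",
    "rqa_metrics",
    "participant_rqa",
]


@dataclass(frozen=True)
class RecurrenceMatrix:
    """Thresholded recurrence structure with its parameters.

    ``entries`` is the full symmetric boolean matrix with the Theiler band
    |i - j| < theiler zeroed out; cells inside the band are excluded from all
    denominators, not merely non-recurrent.
    """

    entries: np.ndarray
    radius: float
    radius_fraction: float
    theiler: int

    def __post_init__(self) -> None:
        e = np.asarray(self.entries, dtype=bool)
        object.__setattr__(self, "entries", e)
        if e.ndim != 2 or e.shape[0] != e.shape[1]:
            raise ParameterError("recurrence matrix must be square")
        if not self.radius > 0:
            raise ParameterError("radius must be > 0")

    @property
    def n_points(self) -> int:
        return self.entries.shape[0]

    @property
    def n_valid_cells(self) -> int:
        """Upper-triangle cells with j - i >= theiler."""
        n, w = self.n_points, self.theiler
        k = n - w  # longest off-band diagonal length
        return k * (k + 1) // 2 if k > 0 else 0


@dataclass(frozen=True)
class RqaMetrics:
    """%REC / %DET / %MAXLINE triple with the line-length histogram."""

    rec: float
    det: float  # nan when undefined (no recurrent point)
    maxline: float
    line_histogram: dict = field(default_factory=dict)
    n_points: int = 0
    params: dict = field(default_factory=dict)

    @property
    def det_defined(self) -> bool:
        return not np.isnan(self.det)


def pairwise_distance_matrix(attractor) -> np.ndarray:
    """Full symmetric Euclidean distance matrix between attractor points."""
    pts = attractor.points if isinstance(attractor, EmbeddedAttractor) else np.asarray(attractor, float)
    if pts.ndim == 1:
        pts = pts[:, None]
    if pts.shape[0] < 2:
        raise ParameterError("need at least 2 points")
    if not np.all(np.isfinite(pts)):
        raise ParameterError("attractor points must be finite")
    return cdist(pts, pts)


def _clear_theiler_band(entries: np.ndarray, theiler: int) -> None:
    """Zero all cells with |i - j| < theiler, in place, diagonal by diagonal."""
    n = entries.shape[0]
    flat = entries.ravel()
    for off in range(-(theiler - 1), theiler):
        start = off if off >= 0 else -off * n
        flat[start : (n - abs(off)) * (n + 1) + start : n + 1] = False


def recurrence_matrix(
    distances: np.ndarray,
    radius_fraction: float = 0.15,
    theiler: int = 10,
) -> RecurrenceMatrix:
    """Threshold a distance matrix at ``radius_fraction`` of its maximum.

    entry(i, j) = 1 iff distance(i, j) <= e and |i - j| >= theiler, with
    e = radius_fraction * max(distances).
    """
    d = np.asarray(distances, float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ParameterError("distance matrix must be square")
    if not 0 < radius_fraction:
        raise ParameterError("radius_fraction must be > 0")
    if theiler < 0:
        raise ParameterError("theiler window must be >= 0")
    dmax = float(d.max())
    if dmax == 0:
        raise DegenerateInputError("all points coincide; radius would be zero")
    e = radius_fraction * dmax
    entries = d <= e
    _clear_theiler_band(entries, theiler)
    n = d.shape[0]
    rm = RecurrenceMatrix(entries=entries, radius=e, radius_fraction=radius_fraction, theiler=theiler)
    if rm.n_valid_cells == 0:
        raise DegenerateInputError(
            f"Theiler window {theiler} leaves no valid cell for N'={n}"
        )
    return rm


def diagonal_line_histogram(rm: RecurrenceMatrix, min_line: int = 10) -> dict:
    """Histogram {length: count} of maximal diagonal runs (upper triangle).

    All runs are recorded, including those shorter than ``min_line``; the
    metrics layer applies the threshold. Only diagonals with offset
    >= theiler are scanned (the band is excluded by construction anyway).
    """
    n = rm.n_points
    counts: dict[int, int] = {}
    entries = rm.entries
    for off in range(rm.theiler, n):
        diag = np.diagonal(entries, offset=off)
        if not diag.any():
            continue
        # run-length encode the boolean diagonal
        padded = np.empty(diag.size + 2, dtype=bool)
        padded[0] = padded[-1] = False
        padded[1:-1] = diag
        flips = np.flatnonzero(padded[1:] != padded[:-1])
        run_lengths = flips[1::2] - flips[0::2]
        for length in run_lengths:
            counts[int(length)] = counts.get(int(length), 0) + 1
    return counts


def rqa_metrics(rm: RecurrenceMatrix, min_line: int = 10,
                maxline_denominator: str = "n_minus_theiler") -> RqaMetrics:
    """Compute %REC, %DET, %MAXLINE from a recurrence matrix.

    %MAXLINE normalizes the longest qualifying diagonal by the longest
    achievable off-band diagonal, N' - theiler (``n_minus_one`` selects
    N' - 1 instead). When no diagonal reaches ``min_line``, Lmax counts as 0.
    %DET is flagged undefined (nan) when there is no recurrent point at all.
    """
    if min_line < 1:
        raise ParameterError("min_line must be >= 1")
    hist = diagonal_line_histogram(rm, min_line)
    recurrent = sum(length * cnt for length, cnt in hist.items())
    valid = rm.n_valid_cells
    rec = 100.0 * recurrent / valid

    if recurrent == 0:
        det, maxline = float("nan"), 0.0
        lmax = 0
    else:
        on_lines = sum(length * cnt for length, cnt in hist.items() if length >= min_line)
        det = 100.0 * on_lines / recurrent
        qualifying = [length for length in hist if length >= min_line]
        lmax = max(qualifying) if qualifying else 0
        if maxline_denominator == "n_minus_theiler":
            denom = rm.n_points - rm.theiler
        elif maxline_denominator == "n_minus_one":
            denom = rm.n_points - 1
        else:
            raise ParameterError(f"unknown maxline denominator {maxline_denominator!r}")
        maxline = 100.0 * lmax / denom

    return RqaMetrics(
        rec=rec,
        det=det,
        maxline=maxline,
        line_histogram=hist,
        n_points=rm.n_points,
        params={
            "radius": rm.radius,
            "radius_fraction": rm.radius_fraction,
            "theiler": rm.theiler,
            "min_line": min_line,
            "lmax": lmax,
        },
    )


def recurrence_from_attractor(
    attractor,
    radius_fraction: float = 0.15,
    theiler: int = 10,
) -> RecurrenceMatrix:
    """Threshold directly on squared distances from a Gram matrix.

    Equivalent to ``recurrence_matrix(pairwise_distance_matrix(a))`` up to
    float rounding at the threshold boundary, but avoids both the explicit
    distance matrix construction and the square roots, which matters when
    thousands of 2375-point attractors are processed.
    """
    pts = attractor.points if isinstance(attractor, EmbeddedAttractor) else np.asarray(attractor, float)
    if pts.ndim == 1:
        pts = pts[:, None]
    if pts.shape[0] < 2:
        raise ParameterError("need at least 2 points")
    # normalise the attractor scale before degrading precision: the radius
    # is a fraction of the maximum distance, so the result is invariant to
    # amplitude scaling, and dividing out the scale in float64 keeps that
    # invariance through the float32 rounding below
    scale = float(np.max(np.abs(pts)))
    if scale == 0:
        raise DegenerateInputError("all points coincide; radius would be zero")
    # float32 keeps the memory traffic of the N'xN' passes tolerable; the
    # resulting ~1e-7 relative distance error is immaterial against a
    # threshold at 15% of the maximum distance
    pts = np.ascontiguousarray(pts / scale, dtype=np.float32)
    sq = np.einsum("ij,ij->i", pts, pts)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (pts @ pts.T)
    np.maximum(d2, np.float32(0.0), out=d2)
    d2max = float(d2.max())
    if d2max == 0:
        raise DegenerateInputError("all points coincide; radius would be zero")
    e_norm = radius_fraction * np.sqrt(d2max)
    entries = d2 <= e_norm * e_norm
    _clear_theiler_band(entries, theiler)
    rm = RecurrenceMatrix(entries=entries, radius=float(e_norm * scale),
                          radius_fraction=radius_fraction, theiler=theiler)
    if rm.n_valid_cells == 0:
        raise DegenerateInputError(
            f"Theiler window {theiler} leaves no valid cell for N'={pts.shape[0]}"
        )
    return rm


def rqa_from_signal(values, delay: int = 25, dimension: int = 6,
                    radius_fraction: float = 0.15, theiler: int = 10,
                    min_line: int = 10) -> RqaMetrics:
    """Convenience chain: embed -> distances -> threshold -> metrics."""
    from .embedding import delay_embed

    att = delay_embed(values, delay, dimension)
    rm = recurrence_from_attractor(att, radius_fraction, theiler)
    return rqa_metrics(rm, min_line)


def participant_rqa(left: RqaMetrics, right: RqaMetrics) -> RqaMetrics:
    """Representative metrics: element-wise mean of the two hands."""
    if not (left.det_defined and right.det_defined):
        warnings.warn("one hand has undefined %DET; propagating undefined", stacklevel=2)
        det = float("nan")
    else:
        det = 0.5 * (left.det + right.det)
    return RqaMetrics(
        rec=0.5 * (left.rec + right.rec),
        det=det,
        maxline=0.5 * (left.maxline + right.maxline),
        n_points=left.n_points,
        params={"averaged_hands": True},
    )
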