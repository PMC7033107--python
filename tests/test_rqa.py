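"""Recurrence quantification: oracle equivalence and metric properties.

The reference implementation below is a deliberately naive O(N^2) double
loop, written independently of the package's vectorised path, and serves as
the ground truth for exact-equivalence checks.
"""

import math

import numpy as np
import pytest

from coordstab.embedding import delay_embed
from coordstab.errors import DegenerateInputError
from coordstab.rqa import (
    RecurrenceMatrix,
    diagonal_line_histogram,
    pairwise_distance_matrix,
    participant_rqa,
    recurrence_from_attractor,
    recurrence_matrix,
    rqa_from_signal,
    rqa_metrics,
)


def naive_rqa(points, radius_fraction=0.15, theiler=10, min_line=10):
    """Brute-force %REC/%DET/%MAXLINE over both triangles of the matrix."""
    pts = [list(map(float, p)) for p in np.atleast_2d(points)]
    n = len(pts)
    dist = [[0.0] * n for _ in range(n)]
    dmax = 0.0
    for i in range(n):
        for j in range(n):
            s = 0.0
            for a, b in zip(pts[i], pts[j]):
                s += (a - b) ** 2
            dist[i][j] = math.sqrt(s)
            dmax = max(dmax, dist[i][j])
    e = radius_fraction * dmax
    rec = [[dist[i][j] <= e and abs(i - j) >= theiler for j in range(n)] for i in range(n)]
    valid = sum(1 for i in range(n) for j in range(n) if abs(i - j) >= theiler)
    n_rec = sum(1 for i in range(n) for j in range(n) if rec[i][j])

    # diagonal runs over every off-band diagonal, both triangles
    runs = []
    for off in range(theiler, n):
        for sign in (+1, -1) if off > 0 else (+1,):
            length = 0
            for i in range(n - off):
                j = i + off
                a, b = (i, j) if sign > 0 else (j, i)
                if rec[a][b]:
                    length += 1
                else:
                    if length:
                        runs.append(length)
                    length = 0
            if length:
                runs.append(length)
    on_lines = sum(r for r in runs if r >= min_line)
    lmax = max([r for r in runs if r >= min_line], default=0)
    pct_rec = 100.0 * n_rec / valid
    pct_det = 100.0 * on_lines / n_rec if n_rec else float("nan")
    pct_max = 100.0 * lmax / (n - theiler)
    return pct_rec, pct_det, pct_max


def _random_attractor(seed, n, dim=3):
    r = np.random.default_rng(seed)
    kind = seed % 3
    if kind == 0:
        x = np.cumsum(r.standard_normal(n + (dim - 1) * 5))  # random walk
        return delay_embed(x, 5, dim).points
    if kind == 1:
        x = np.sin(2 * np.pi * np.arange(n + (dim - 1) * 7) / 37) + 0.3 * r.standard_normal(
            n + (dim - 1) * 7
        )
        return delay_embed(x, 7, dim).points
    return r.standard_normal((n, dim))


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(6))
    def test_metrics_match_naive_reference_exactly(self, seed):
        pts = _random_attractor(seed, 120)
        m = rqa_metrics(recurrence_matrix(pairwise_distance_matrix(pts)))
        ref = naive_rqa(pts)
        assert (m.rec, m.det, m.maxline) == ref

    def test_fast_gram_path_matches_distance_path(self):
        for seed in range(6):
            pts = _random_attractor(seed, 150)
            a = rqa_metrics(recurrence_matrix(pairwise_distance_matrix(pts)))
            b = rqa_metrics(recurrence_from_attractor(pts))
            assert (a.rec, a.det, a.maxline) == (b.rec, b.det, b.maxline)

    def test_hand_drawn_12x12_run_histogram(self):
        # enumerated by hand: full diagonals at offsets 1, 2 and 9 of a 12x12
        # matrix have runs of 11, 10 and 3 recurrent points
        n = 12
        m = np.zeros((n, n), bool)
        for off, length in ((1, 11), (2, 10), (9, 3)):
            for i in range(length):
                m[i, i + off] = True
        m |= m.T
        rm = RecurrenceMatrix(entries=m, radius=1.0, radius_fraction=0.5, theiler=1)
        hist = diagonal_line_histogram(rm, min_line=10)
        assert hist == {11: 1, 10: 1, 3: 1}


class TestDistanceMatrix:
    def test_two_points_345(self):
        d = pairwise_distance_matrix(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert d[0, 1] == 5.0 and d[1, 0] == 5.0 and d[0, 0] == 0.0

    def test_identical_points_zero(self):
        d = pairwise_distance_matrix(np.ones((4, 3)))
        assert np.all(d == 0.0)

    def test_matches_double_loop(self, rng):
        pts = rng.standard_normal((50, 4))
        d = pairwise_distance_matrix(pts)
        for i in range(50):
            for j in range(50):
                assert d[i, j] == pytest.approx(
                    math.sqrt(sum((pts[i, k] - pts[j, k]) ** 2 for k in range(4))),
                    abs=1e-12,
                )


class TestRecurrenceMatrix:
    def test_radius_at_max_distance_saturates_rec(self, rng):
        pts = rng.standard_normal((60, 3))
        rm = recurrence_matrix(pairwise_distance_matrix(pts), radius_fraction=1.0, theiler=2)
        assert rqa_metrics(rm, min_line=2).rec == 100.0

    def test_theiler_exhaustion_raises(self, rng):
        pts = rng.standard_normal((20, 2))
        with pytest.raises(DegenerateInputError):
            recurrence_matrix(pairwise_distance_matrix(pts), theiler=20)

    def test_constant_attractor_raises(self):
        with pytest.raises(DegenerateInputError):
            recurrence_matrix(np.zeros((10, 10)))

    def test_symmetry_and_band_exclusion(self, rng):
        pts = rng.standard_normal((40, 3))
        rm = recurrence_matrix(pairwise_distance_matrix(pts), theiler=5)
        assert np.array_equal(rm.entries, rm.entries.T)
        i = np.arange(40)
        assert not rm.entries[np.abs(i[:, None] - i[None, :]) < 5].any()


class TestMetrics:
    def test_periodic_sine_is_highly_deterministic(self, sine_period100):
        m = rqa_from_signal(sine_period100)
        assert m.det >= 99.0
        assert m.rec > 0

    def test_single_recurrent_point_gives_zero_det_and_maxline(self):
        n = 30
        entries = np.zeros((n, n), bool)
        entries[0, 15] = entries[15, 0] = True
        rm = RecurrenceMatrix(entries=entries, radius=1.0, radius_fraction=0.1, theiler=10)
        m = rqa_metrics(rm, min_line=10)
        assert m.det == 0.0 and m.maxline == 0.0 and m.rec > 0

    def test_shuffling_destroys_determinism(self, sine_period100):
        orig = rqa_from_signal(sine_period100[:800]).det
        dets = []
        for seed in range(5):
            r = np.random.default_rng(seed)
            dets.append(rqa_from_signal(r.permutation(sine_period100[:800])).det)
        assert np.all(np.array(dets) < orig)

    def test_rec_monotone_in_radius(self, rng):
        x = np.sin(2 * np.pi * np.arange(600) / 100) + 0.2 * rng.standard_normal(600)
        att = delay_embed(x, 25, 6)
        d = pairwise_distance_matrix(att)
        recs = [
            rqa_metrics(recurrence_matrix(d, radius_fraction=f)).rec
            for f in (0.05, 0.1, 0.15, 0.3, 0.6, 1.0)
        ]
        assert np.all(np.diff(recs) >= 0)

    def test_det_nonincreasing_in_min_line(self, rng):
        x = np.sin(2 * np.pi * np.arange(600) / 100) + 0.2 * rng.standard_normal(600)
        rm = recurrence_matrix(pairwise_distance_matrix(delay_embed(x, 25, 6)))
        dets = [rqa_metrics(rm, min_line=k).det for k in (2, 5, 10, 20, 40)]
        assert np.all(np.diff(dets) <= 0)

    def test_amplitude_scaling_invariance(self, rng):
        x = np.sin(2 * np.pi * np.arange(700) / 100) + 0.1 * rng.standard_normal(700)
        a = rqa_from_signal(x)
        b = rqa_from_signal(1000.0 * x)
        assert a.rec == pytest.approx(b.rec, abs=1e-9)
        assert a.det == pytest.approx(b.det, abs=1e-9)
        assert a.maxline == pytest.approx(b.maxline, abs=1e-9)


class TestParticipantRqa:
    def test_elementwise_mean(self):
        from coordstab.rqa import RqaMetrics

        a = RqaMetrics(rec=4.0, det=90.0, maxline=20.0)
        b = RqaMetrics(rec=6.0, det=80.0, maxline=40.0)
        m = participant_rqa(a, b)
        assert (m.rec, m.det, m.maxline) == (5.0, 85.0, 30.0)

    def test_undefined_side_propagates_with_warning(self):
        from coordstab.rqa import RqaMetrics

        a = RqaMetrics(rec=4.0, det=float("nan"), maxline=0.0)
        b = RqaMetrics(rec=6.0, det=80.0, maxline=40.0)
        with pytest.warns(UserWarning):
            m = participant_rqa(a, b)
        assert np.isnan(m.det) and m.rec == 5.0
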