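# Methods

`coordstab` quantifies the stability of movement coordination patterns with
recurrence quantification analysis (RQA) and relates it to how rhythmic the
pattern is and how well the performer adapts to a changing pacing signal.
The package is an analysis pipeline over synthetic juggling-like kinematics;
every stage also accepts user-supplied marker data in the documented CSV
dialect.

## The scientific objects

**Coordination Pattern Index (CPI).** The vertical wrist velocity of a
tempo-locked movement is Fourier-analysed (rectangular-window periodogram,
density scaling). The CPI is the fraction of non-DC spectral power inside a
band of total width 10% centred on the fundamental movement frequency f0
(i.e. f0 ± 5%). A smoothly rhythmic, sinusoid-like movement concentrates its
power at f0 (CPI → 1); a move-and-dwell "discrete" movement spreads power
into harmonics (CPI ≪ 1). For metronome trials f0 = 1/(2·interval), because
catches alternate hands in cascade juggling, so each hand completes one full
cycle every two beeps (the beep-rate convention is selectable). Without a
metronome f0 is the largest non-DC periodogram peak of that hand's vertical
velocity. Per-hand CPIs are averaged into the participant value.

**Attractor reconstruction.** Each scalar channel (head–wrist 3D distance
and the ML/SI/AP wrist positions), cut to 25 same-hand catch-to-catch cycles
and linearly resampled to 2500 points, is delay-embedded as
(x_i, x_{i+τ}, …, x_{i+(m−1)τ}). The pipeline default fixes τ = 25 frames
(a quarter cycle at 100 points per cycle) and m = 6; the selectors —
average mutual information (AMI) for τ, false nearest neighbours (FNN) for
m — are implemented as a verification mode.

**RQA.** Distances between all pairs of embedded points are thresholded at
e = 15% of the maximum pairwise distance; a Theiler band |i−j| < 10 (the
minimum recurrence time) is excluded from every count. With a minimum line
length of 10:

- %REC = 100 · recurrent cells / valid cells,
- %DET = 100 · recurrent points on diagonals of length ≥ 10 / recurrent
  points (undefined when there is no recurrent point),
- %MAXLINE = 100 · longest qualifying diagonal / (N′ − Theiler).

Counting uses the upper triangle only; by symmetry all three ratios equal
their both-triangle versions. Hands are averaged into the participant value.

**%Asynchrony.** In ramp trials each catch (hands merged, time order) is
paired with its beep by index; the absolute error is scaled by the interval
*ending at* the paired beep — the tempo at which the error occurs, which
matters because intervals shrink or grow by 3 ms per beep — and expressed in
percent. The first 6 of the 101 catches are task onset and are discarded, so
a complete trial scores 95 catches; a dropped ball truncates the pairing.
Trial scores are averaged over the trials of a condition.

**Statistics.** Pooled correlations are Pearson's r, or Spearman's rank
correlation when a Shapiro-Wilk test (α = 0.05) rejects normality of either
variable. Spearman p-values are exact (full 10!-permutation null) for
n ≤ 10, t-approximated above. Robustness of within-participant effects is
summarised by the mean Fisher z of per-participant correlations with a 95%
CI, tanh(mean z ± 1.96·sd(z)/√n). Per-family significance levels are
Bonferroni-corrected and printed truncated to two decimals of a percent
(0.05/12 → "0.41%", 0.05/2 → "2.5%").

## The synthetic generator: what it emulates

The generator is the stated world in which all cohort-level claims are
tested. One hand cycle of duration T is

y(t) = A·(1 − cos(2π·t / ((1−d)·T)))  for t < (1−d)·T,  else 0,

where d ∈ [0, 0.9) is the **dwell fraction**: the part of the cycle spent
motionless at the rest position. d = 0 is a pure sinusoid (rhythmic
pattern); d > 0 compresses the excursion and appends a flat dwell (discrete
pattern). The excursion is a raised cosine, so the waveform is C¹ at the
joins and peak-to-peak amplitude is 2A for every d. Catch events sit at the
cycle joins: one catch per beep, hands alternating (left first), with catch
time = beep + N(μ, σ) timing error; each hand's waveform is re-timed so
successive same-hand catches bound its cycles, which handles ramped tempos
naturally. The lateral (ML) channel is the same waveform a quarter-cycle
ahead scaled by 0.35, the fore-aft (AP) channel an in-phase copy scaled by
0.15, around anatomical offsets; the head marker is stationary. Isotropic
Gaussian noise is added to every coordinate.

Defaults, chosen once for realism and not revisited:

| parameter | default | rationale |
|---|---|---|
| amplitude A | 100 mm | typical cascade-juggling hand excursion |
| marker noise | 1 mm | reported calibration residual of the capture system |
| catch jitter σ0 | 20 ms | 3–5% of interval, typical sensorimotor-synchronisation variability |
| adaptability coupling c | 40 ms | ramp-trial σ = σ0 + c·(1−d): rhythmic movers adapt worse |
| expert d vs tempo | 0 at 260 ms → 0.6 at 620 ms, linear | the rhythmic→discrete transition with slowing tempo |
| preferred cycle | 0.75 + 0.4·d s | discrete-leaning jugglers prefer slower tempos; keeps ≥ 28 cycles in 30 s |

What the generator does **not** emulate: ball flight and its mechanical
coupling to the hand, arm dynamics, learning or drift across trials,
marker dropout, and genuinely independent ML/AP dynamics (the three axes
are phase-shifted copies of one waveform plus noise). A green cohort-level
test therefore establishes that the pipeline recovers the built-in
couplings — low-d participants score high CPI, high %DET and high
%Asynchrony — not that real jugglers behave this way.

## Numerical choices

- **AMI partition.** The joint histogram uses 16 equal-width cells (4 × 4).
  Coarseness is deliberate: on noiseless deterministic signals a fine
  partition resolves the functional dependence between x_t and x_{t+ℓ} at
  every lag, pinning AMI near its entropy bound and erasing the
  quarter-period minimum the delay rule needs. With a 16-bins-per-axis
  partition the AMI of a noiseless period-100 sine has no minimum near 25
  at all.
- **First local minimum.** A lag qualifies when its AMI is below the
  previous value and not above any value within ±5 lags; the window absorbs
  the cell-alignment jitter that histogram estimators show on near-periodic
  signals. A curve with no local minimum falls back to the global minimum
  with a warning.
- **FNN near-duplicates.** The distance-ratio test floors its denominator
  at 1e-10 of the attractor size: exact revisits of a periodic orbit have
  float-epsilon separations in both numerator and denominator, and their
  ratio is numerical noise rather than a false neighbour. Thresholds
  R_tol = 15, A_tol = 2, acceptance fraction 1% are the conventional
  settings.
- **Filtering.** Second-order low-pass Butterworth, applied
  forward-backward: zero phase lag so event timing is not shifted. The
  cutoff comes from residual analysis: RMS residual vs candidate cutoff
  (1–20 Hz, 1 Hz grid), straight line fitted to the upper half of the
  curve, smallest cutoff whose residual is at or below the intercept. A
  noise floor below 0.5% of the signal's sd is treated as a noiseless
  degenerate case (smallest candidate, with a warning).
- **Cycle window.** A cycle is a same-hand catch-to-catch interval; the
  first 2 cycles are warm-up and skipped before the 25 analysed ones.
- **RQA at scale.** The production path forms squared distances from a Gram
  matrix in float32 and never takes square roots; against the float64
  distance-matrix path this can differ only for cells within ~1e-7 of the
  threshold, and both paths are verified to agree exactly on the test
  fixtures. The naive O(N²) double-loop reference lives in the test suite.
- **%MAXLINE denominator** is N′ − Theiler, the longest achievable off-band
  diagonal (N′ − 1 selectable); a trial with no diagonal ≥ 10 scores
  %MAXLINE = 0.
- **Degenerate inputs.** Constant signals are rejected before AMI (zero
  entropy) and before thresholding (zero radius); a single recurrent point
  yields %DET = 0, while zero recurrent points flag %DET undefined (NaN)
  and propagate with a warning when hands are averaged.

## Open choices and how they were fixed

- The "range of 10%" around f0 is read as total width 10% (f0 ± 5%); the
  width is a config knob, and widening it can only increase the CPI.
- The CPI denominator is all non-DC power up to Nyquist, making the index
  amplitude-invariant.
- Down-ramp intervals are the exact reverse of the up-ramp list (so the up
  ramp realises 600 … 303 ms and the down ramp 303 … 600 ms; with 101
  beeps only 100 intervals exist). The convention is recorded in the beep
  train metadata.
- %Asynchrony averages trial means rather than pooling catches across
  trials.
- Per-participant Fisher z uses the between-participant sd of z; with all
  r equal the CI collapses to a point.

## Known limitations

- The AMI delay selector is tuned for signals whose dominant period is
  well inside the lag range; for periods near 4× the maximum lag the
  windowed rule can settle on a jitter dip (a usable but not quarter-period
  delay).
- The exact Spearman permutation null (n ≤ 10) materialises a 10!-row
  matrix (~36 MB) on first use; it is cached per n.
- Channels in the generator share one waveform, so cross-channel RQA
  differences in synthetic cohorts are smaller than in real data.
- Cohort-level claims are directional (sign and rank strength of
  correlations), not calibrated to the magnitudes of any particular
  empirical dataset.
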