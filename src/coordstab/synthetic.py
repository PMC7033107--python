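"""Synthetic juggling-like trials with a controllable rhythmic-discrete continuum.

The generator emulates the kinematics a motion-capture system would record
from three-ball cascade juggling paced by a metronome: vertical wrist
oscillation that is tempo-locked, a head marker used only as a reference
point, metronome beep trains (fixed tempo, or ramped 600<->300 ms in 3 ms
steps), and catch/throw events with a configurable timing-error model.

The one scientific dial is the dwell fraction ``d``: the fraction of each
hand cycle spent motionless at the rest position. ``d = 0`` gives a pure
sinusoid (rhythmic pattern); increasing ``d`` compresses the up-down
excursion into the first ``(1 - d)`` of the cycle and appends a flat dwell,
producing the move-and-stop waveform characteristic of a discrete pattern.
The excursion is a raised cosine, so the waveform is C1 at the joins and the
peak-to-peak amplitude is ``2 * amplitude`` for every ``d``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ParameterError

__all__ = [
    "PatternParams",
    "LagModel",
    "BeepTrain",
    "EventSeries",
    "Trajectory",
    "TrialBundle",
    "make_beep_train",
    "simulate_hand_cycle",
    "simulate_trial",
    "simulate_cohort",
    "simulate_tempo_conditions",
    "write_trial",
    "write_cohort",
    "UP_RAMP_INTERVALS_MS",
]

#: Up condition: tempo speeds up, inter-beep intervals 600, 597, ..., 303 ms
#: (100 intervals -> 101 beeps). The Down condition uses the exact reverse.
UP_RAMP_INTERVALS_MS = np.arange(600.0, 302.0, -3.0)

RAMP_STEP_MS = 3.0
HEAD_POSITION_MM = np.array([0.0, 1500.0, 0.0])  # x=AP, y=SI, z=ML
HAND_OFFSET_ML_MM = 150.0  # lateral offset of each wrist from the midline
ML_COUPLING = 0.35  # lateral excursion as a fraction of the vertical one
AP_COUPLING = 0.15


@dataclass(frozen=True)
class PatternParams:
    """Parameters of one hand's cyclic movement pattern.

    cycle_duration : s per full hand cycle (two beeps at fixed tempo, since
        catches alternate hands).
    dwell_fraction : d in [0, 0.9), fraction of the cycle spent motionless.
    amplitude : mm; peak-to-peak vertical excursion is 2*amplitude.
    noise_sd : mm of additive Gaussian measurement noise per coordinate.
    phase_offset : additional phase (radians) applied to the right hand on
        top of the half-cycle offset already implied by alternating catches.
    seed : RNG seed used when the pattern is simulated standalone.
    """

    cycle_duration: float
    dwell_fraction: float = 0.0
    amplitude: float = 100.0
    noise_sd: float = 1.0
    phase_offset: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.cycle_duration > 0:
            raise ParameterError("cycle_duration must be > 0")
        if not 0 <= self.dwell_fraction < 1:
            raise ParameterError("dwell_fraction must lie in [0, 1)")
        if self.dwell_fraction > 0.9:
            raise ParameterError("dwell_fraction above 0.9 is outside the model's domain")
        if not self.amplitude > 0:
            raise ParameterError("amplitude must be > 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")


@dataclass(frozen=True)
class LagModel:
    """Gaussian catch-timing error: catch = beep + N(mu, sigma)."""

    mu: float = 0.0
    sigma: float = 0.02

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ParameterError("lag sigma must be >= 0")


@dataclass(frozen=True)
class BeepTrain:
    """Metronome beep onsets (s) plus the condition that generated them."""

    onsets: np.ndarray
    condition: str  # "fixed" | "up_ramp" | "down_ramp" | "none"
    interval_ms: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        on = np.asarray(self.onsets, dtype=float)
        object.__setattr__(self, "onsets", on)
        if on.size and np.any(np.diff(on) <= 0):
            raise ParameterError("beep onsets must be strictly increasing")

    @property
    def intervals_ms(self) -> np.ndarray:
        return np.diff(self.onsets) * 1000.0

    def __len__(self) -> int:
        return self.onsets.size


@dataclass(frozen=True)
class EventSeries:
    """Catch and throw times (s) per hand."""

    catch_left: np.ndarray
    catch_right: np.ndarray
    throw_left: np.ndarray
    throw_right: np.ndarray

    def __post_init__(self) -> None:
        for name in ("catch_left", "catch_right", "throw_left", "throw_right"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.size > 1 and np.any(np.diff(arr) <= 0):
                raise ParameterError(f"{name} must be strictly increasing")

    def catches(self, hand: str) -> np.ndarray:
        return self.catch_left if hand == "left" else self.catch_right

    @property
    def merged_catches(self) -> np.ndarray:
        """All catches in time order (hands interleaved)."""
        return np.sort(np.concatenate([self.catch_left, self.catch_right]))


@dataclass(frozen=True)
class Trajectory:
    """A 3D marker trajectory: columns x=AP, y=SI (vertical), z=ML; mm."""

    xyz: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        xyz = np.asarray(self.xyz, dtype=float)
        object.__setattr__(self, "xyz", xyz)
        if xyz.ndim != 2 or xyz.shape[1] != 3:
            raise ParameterError("trajectory must be (N, 3)")

    def axis(self, name: str) -> np.ndarray:
        return self.xyz[:, {"AP": 0, "SI": 1, "ML": 2}[name]]

    def __len__(self) -> int:
        return self.xyz.shape[0]


@dataclass(frozen=True)
class TrialBundle:
    """Everything recorded in one juggling trial."""

    head: Trajectory
    wrist_left: Trajectory
    wrist_right: Trajectory
    beeps: BeepTrain
    events: EventSeries
    sampling_rate: float
    condition: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.head)
        if not (len(self.wrist_left) == len(self.wrist_right) == n):
            raise ParameterError("all trajectories must share one length")

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.head)) / self.sampling_rate

    def wrist(self, hand: str) -> Trajectory:
        return self.wrist_left if hand == "left" else self.wrist_right


def make_beep_train(
    condition: str,
    interval_ms: float | None = None,
    n_beeps: int = 65,
    t0: float = 0.0,
) -> BeepTrain:
    """Build a metronome beep train.

    ``fixed`` gives ``n_beeps`` onsets at constant spacing ``interval_ms``
    (valid range 100-2000 ms). ``up_ramp`` gives 101 onsets whose 100
    intervals shrink 600, 597, ..., 303 ms; ``down_ramp`` is the exact
    reverse (303 ... 600 ms). ``none`` gives an empty train (Preferred,
    free-tempo condition).

    Ramp endpoint bookkeeping: with 101 beeps only 100 intervals exist, so
    the up ramp realises 600 ms but stops at 303 ms (and the mirror for
    down); this convention is recorded in the train metadata.
    """
    if condition == "fixed":
        if interval_ms is None or not 100 <= interval_ms <= 2000:
            raise ParameterError(
                f"fixed tempo needs interval_ms in [100, 2000], got {interval_ms}"
            )
        if n_beeps < 2:
            raise ParameterError("need at least 2 beeps")
        onsets = t0 + np.arange(n_beeps) * (interval_ms / 1000.0)
        return BeepTrain(onsets, "fixed", interval_ms=float(interval_ms))
    if condition in ("up_ramp", "down_ramp"):
        iv = UP_RAMP_INTERVALS_MS if condition == "up_ramp" else UP_RAMP_INTERVALS_MS[::-1]
        onsets = t0 + np.concatenate([[0.0], np.cumsum(iv) / 1000.0])
        meta = {"ramp_endpoints_ms": (float(iv[0]), float(iv[-1])), "step_ms": RAMP_STEP_MS}
        return BeepTrain(onsets, condition, metadata=meta)
    if condition == "none":
        return BeepTrain(np.empty(0), "none")
    raise ParameterError(f"unknown beep condition {condition!r}")


def simulate_hand_cycle(pattern: PatternParams, t_in_cycle) -> np.ndarray:
    """Vertical position (mm above rest) at time(s) ``t_in_cycle`` within a cycle.

    The excursion is ``A * (1 - cos(2*pi*t / ((1-d)*T)))`` for
    ``t < (1-d)*T`` and exactly 0 during the dwell. For ``d = 0`` this is a
    pure sinusoid of period ``T`` (value ``+A`` a quarter-cycle in); the
    velocity is 0 at both joins for every ``d``, so cycles concatenate
    smoothly.
    """
    t = np.asarray(t_in_cycle, dtype=float)
    T = pattern.cycle_duration
    if np.any((t < 0) | (t >= T)):
        raise ParameterError("t_in_cycle must lie in [0, cycle_duration)")
    move = (1.0 - pattern.dwell_fraction) * T
    y = np.where(
        t < move,
        pattern.amplitude * (1.0 - np.cos(2.0 * np.pi * t / move)),
        0.0,
    )
    return y if y.shape else float(y)


def _piecewise_cycles(t: np.ndarray, anchors: np.ndarray, pattern: PatternParams,
                      phase: float = 0.0) -> np.ndarray:
    """Evaluate the cycle waveform re-timed so cycle k spans anchors[k]..[k+1].

    Outside the anchored range the first/last cycle is extended periodically.
    ``phase`` (radians) shifts the evaluation point within each cycle.
    """
    k = np.clip(np.searchsorted(anchors, t, side="right") - 1, 0, anchors.size - 2)
    T_k = anchors[k + 1] - anchors[k]
    local = np.mod(t - anchors[k] - phase / (2 * np.pi) * T_k, T_k)
    move = (1.0 - pattern.dwell_fraction) * T_k
    return np.where(
        local < move,
        pattern.amplitude * (1.0 - np.cos(2.0 * np.pi * local / np.maximum(move, 1e-12))),
        0.0,
    )


def _alternating_catches(beep_onsets: np.ndarray, lag_model: LagModel,
                         rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """One catch per beep, hands alternating (left first), with timing error."""
    lags = lag_model.mu + lag_model.sigma * rng.standard_normal(beep_onsets.size)
    if beep_onsets.size > 1:
        # keep catch order strictly monotone even for extreme draws
        half_gap = 0.45 * np.min(np.diff(beep_onsets))
        lags = np.clip(lags, -half_gap, half_gap)
    catches = beep_onsets + lags
    return catches[0::2], catches[1::2]  # left, right


def simulate_trial(
    pattern: PatternParams,
    beeps: BeepTrain,
    lag_model: LagModel | None = None,
    seed: int | np.random.SeedSequence | None = None,
    sampling_rate: float = 100.0,
    duration: float | None = None,
    condition: str | None = None,
) -> TrialBundle:
    """Simulate one juggling trial.

    With a metronome, each beep receives one catch (hands alternating, left
    first) at ``beep + N(mu, sigma)``; each hand's vertical wrist signal is
    the cycle waveform re-timed so successive same-hand catches bound the
    cycles. Without beeps (Preferred condition) catches are self-paced at
    ``cycle_duration / 2`` spacing over ``duration`` seconds (default 30 s).
    The head marker is stationary plus noise. All randomness flows through
    one generator seeded by ``seed``.
    """
    lag_model = lag_model or LagModel()
    rng = np.random.default_rng(pattern.seed if seed is None else seed)

    if len(beeps) == 0:
        dur = 30.0 if duration is None else duration
        onsets = np.arange(1.0, 1.0 + dur, pattern.cycle_duration / 2.0)
    else:
        onsets = beeps.onsets + 1.0  # 1 s lead-in before the first beep
        beeps = BeepTrain(onsets, beeps.condition, beeps.interval_ms, dict(beeps.metadata))
        dur = None

    c_left, c_right = _alternating_catches(onsets, lag_model, rng)
    if c_left.size < 2 or c_right.size < 2:
        raise ParameterError("trial too short: need at least 2 catches per hand")

    t_end = (onsets[-1] + pattern.cycle_duration) if dur is None else (1.0 + dur)
    n = int(np.floor(t_end * sampling_rate)) + 1
    t = np.arange(n) / sampling_rate

    trajs = {}
    for hand, anchors, sign, extra_phase in (
        ("left", c_left, -1.0, 0.0),
        ("right", c_right, +1.0, pattern.phase_offset),
    ):
        y = _piecewise_cycles(t, anchors, pattern, phase=extra_phase)
        # lateral sweep leads the vertical excursion by a quarter cycle;
        # fore-aft is a small in-phase copy
        z_wave = _piecewise_cycles(t, anchors, pattern, phase=extra_phase + np.pi / 2)
        xyz = np.column_stack(
            [
                AP_COUPLING * y,
                y,
                sign * (HAND_OFFSET_ML_MM + ML_COUPLING * z_wave),
            ]
        )
        xyz += pattern.noise_sd * rng.standard_normal(xyz.shape)
        trajs[hand] = Trajectory(xyz, sampling_rate)

    head = Trajectory(
        HEAD_POSITION_MM + pattern.noise_sd * rng.standard_normal((n, 3)),
        sampling_rate,
    )

    # throws: shortly before the movement peak of the following catch cycle
    throw_frac = 0.45 * (1.0 - pattern.dwell_fraction)
    events = EventSeries(
        catch_left=c_left,
        catch_right=c_right,
        throw_left=c_left[:-1] + throw_frac * np.diff(c_left),
        throw_right=c_right[:-1] + throw_frac * np.diff(c_right),
    )
    return TrialBundle(
        head=head,
        wrist_left=trajs["left"],
        wrist_right=trajs["right"],
        beeps=beeps,
        events=events,
        sampling_rate=sampling_rate,
        condition=condition or beeps.condition,
        metadata={
            "dwell_fraction": pattern.dwell_fraction,
            "cycle_duration": pattern.cycle_duration,
            "lag_mu": lag_model.mu,
            "lag_sigma": lag_model.sigma,
        },
    )


@dataclass(frozen=True)
class ParticipantTrials:
    """All simulated trials of one synthetic participant."""

    participant: int
    dwell_fraction: float
    trials: dict  # condition label -> list[TrialBundle]


def simulate_cohort(
    n_participants: int,
    d_values,
    adaptability_coupling: float = 0.04,
    seed: int | np.random.SeedSequence = 0,
    n_trials: int = 3,
    base_lag_sigma: float = 0.02,
    noise_sd: float = 1.0,
    amplitude: float = 100.0,
    conditions: tuple = ("preferred", "up_ramp", "down_ramp"),
    preferred_duration: float = 30.0,
) -> list[ParticipantTrials]:
    """Simulate an intermediate-juggler cohort (adaptation-experiment design).

    Participant ``i`` juggles with dwell fraction ``d_i``; their preferred
    cycle duration grows with discreteness (0.75 + 0.4 * d_i s). In the ramp
    conditions the catch-timing spread is ``sigma0 + c * (1 - d_i)`` with
    ``c = adaptability_coupling``, encoding the finding that more rhythmic
    (low-d) jugglers adapt worse to a changing tempo.
    """
    d = np.asarray(d_values, dtype=float)
    if n_participants < 2:
        raise ParameterError("need at least 2 participants")
    if d.size != n_participants:
        raise ParameterError(f"d_values has length {d.size}, expected {n_participants}")
    if adaptability_coupling < 0:
        raise ParameterError("adaptability_coupling must be >= 0")

    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    part_seeds = root.spawn(n_participants)

    cohort = []
    for i, (d_i, ss) in enumerate(zip(d, part_seeds)):
        cycle = 0.75 + 0.4 * d_i
        pattern = PatternParams(
            cycle_duration=cycle, dwell_fraction=float(d_i),
            amplitude=amplitude, noise_sd=noise_sd,
        )
        ramp_sigma = base_lag_sigma + adaptability_coupling * (1.0 - d_i)
        trials: dict[str, list[TrialBundle]] = {}
        trial_seeds = iter(ss.spawn(n_trials * len(conditions)))
        for cond in conditions:
            trials[cond] = []
            for _ in range(n_trials):
                ts = next(trial_seeds)
                if cond == "preferred":
                    bundle = simulate_trial(
                        pattern, make_beep_train("none"),
                        LagModel(sigma=base_lag_sigma), seed=ts,
                        duration=preferred_duration, condition="preferred",
                    )
                else:
                    bundle = simulate_trial(
                        pattern, make_beep_train(cond),
                        LagModel(sigma=ramp_sigma), seed=ts, condition=cond,
                    )
                trials[cond].append(bundle)
        cohort.append(ParticipantTrials(i, float(d_i), trials))
    return cohort


def simulate_tempo_conditions(
    n_participants: int = 7,
    intervals_ms: tuple = (260, 300, 340, 380, 420, 460, 500, 540, 580, 620),
    seed: int | np.random.SeedSequence = 0,
    d_max: float = 0.6,
    d_spread: float = 0.05,
    lag_sigma: float = 0.02,
    noise_sd: float = 1.0,
    amplitude: float = 100.0,
    n_beeps: int = 65,
) -> list[ParticipantTrials]:
    """Simulate an expert cohort over fixed-tempo conditions (tempo experiment).

    The coordination pattern follows the tempo: at the fastest tempo the
    movement is fully rhythmic (d = 0) and discreteness grows linearly to
    ``d_max`` at the slowest, with a per-participant offset (sd ``d_spread``)
    so participants differ. One trial per condition, 65 beeps each, and a
    hand cycle lasting two beep intervals (catches alternate hands).
    """
    iv = np.asarray(intervals_ms, dtype=float)
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    part_seeds = root.spawn(n_participants)

    cohort = []
    for i, ss in enumerate(part_seeds):
        rng = np.random.default_rng(ss)
        offset = d_spread * rng.standard_normal()
        trials: dict[str, list[TrialBundle]] = {}
        trial_seeds = iter(ss.spawn(iv.size))
        for interval in iv:
            frac = (interval - iv.min()) / (iv.max() - iv.min())
            d_i = float(np.clip(d_max * frac + offset * frac, 0.0, 0.9))
            pattern = PatternParams(
                cycle_duration=2.0 * interval / 1000.0, dwell_fraction=d_i,
                amplitude=amplitude, noise_sd=noise_sd,
            )
            label = f"fixed_{int(interval)}"
            trials[label] = [
                simulate_trial(
                    pattern, make_beep_train("fixed", interval, n_beeps=n_beeps),
                    LagModel(sigma=lag_sigma), seed=next(trial_seeds), condition=label,
                )
            ]
        cohort.append(ParticipantTrials(i, float("nan"), trials))
    return cohort


# ---------------------------------------------------------------------------
# on-disk representation: one CSV per trial (long marker table), beeps as a
# single-column text file, events as CSV, cohort manifest as YAML
# ---------------------------------------------------------------------------

def write_trial(bundle: TrialBundle, directory, stem: str = "trial") -> dict:
    """Write one trial as text files; returns the paths written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    t = bundle.times
    rows = []
    for marker_id, traj in (
        ("head", bundle.head),
        ("wrist_left", bundle.wrist_left),
        ("wrist_right", bundle.wrist_right),
    ):
        for ti, (x, y, z) in zip(t, traj.xyz):
            rows.append(f"{ti:.6f},{marker_id},{x:.6f},{y:.6f},{z:.6f}")
    markers_path = directory / f"{stem}_markers.csv"
    markers_path.write_text(
        "time_s,marker_id,x_mm,y_mm,z_mm\n" + "\n".join(rows) + "\n"
    )

    beeps_path = directory / f"{stem}_beeps.txt"
    beeps_path.write_text("".join(f"{b:.6f}\n" for b in bundle.beeps.onsets))

    ev = bundle.events
    ev_rows = ["hand,type,time_s"]
    for hand, kind, times in (
        ("left", "catch", ev.catch_left),
        ("right", "catch", ev.catch_right),
        ("left", "throw", ev.throw_left),
        ("right", "throw", ev.throw_right),
    ):
        ev_rows += [f"{hand},{kind},{x:.6f}" for x in times]
    events_path = directory / f"{stem}_events.csv"
    events_path.write_text("\n".join(ev_rows) + "\n")

    meta = {
        "condition": bundle.condition,
        "sampling_rate": float(bundle.sampling_rate),
        "beep_condition": bundle.beeps.condition,
        **{k: float(v) for k, v in bundle.metadata.items()},
    }
    meta_path = directory / f"{stem}_meta.yaml"
    meta_path.write_text(yaml.safe_dump(meta, sort_keys=True))
    return {
        "markers": markers_path,
        "beeps": beeps_path,
        "events": events_path,
        "meta": meta_path,
    }


def write_cohort(cohort: list[ParticipantTrials], directory) -> Path:
    """Write every trial of a cohort plus a YAML manifest; returns its path."""
    directory = Path(directory)
    manifest: dict = {"participants": []}
    for part in cohort:
        entry: dict = {
            "participant": part.participant,
            "dwell_fraction": None if np.isnan(part.dwell_fraction) else float(part.dwell_fraction),
            "trials": {},
        }
        for cond, bundles in part.trials.items():
            entry["trials"][cond] = []
            for j, bundle in enumerate(bundles):
                stem = f"p{part.participant:02d}_{cond}_t{j}"
                write_trial(bundle, directory / f"p{part.participant:02d}", stem)
                entry["trials"][cond].append(f"p{part.participant:02d}/{stem}")
        manifest["participants"].append(entry)
    path = directory / "manifest.yaml"
    path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return path
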