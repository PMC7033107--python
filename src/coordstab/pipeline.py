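"""End-to-end orchestration of the two experiments over synthetic cohorts.

Experiment 1 (tempo experiment): expert-like participants juggle under ten
fixed metronome tempos; per participant x condition the Coordination Pattern
Index and the RQA indices of four channels (head-wrist 3D distance and the
ML/SI/AP wrist positions) are computed, then CPI-tempo and CPI-RQA
correlations are summarised.

Experiment 2 (adaptation experiment): intermediate-like participants juggle
at their preferred tempo (CPI + RQA) and follow up/down tempo ramps
(%Asynchrony); correlations among CPI, RQA and %Asynchrony are summarised
with a normality gate choosing Pearson or Spearman.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .adaptation import pair_catches_to_beeps, percent_asynchrony
from .embedding import delay_embed
from .errors import CoordstabError, FormatError, ParameterError
from .preprocess import (
    FilterSpec,
    SampledSignal,
    butterworth_filter,
    differentiate,
    extract_cycles,
    head_wrist_distance,
    residual_cutoff,
    standardize_length,
)
from .rqa import (
    RqaMetrics,
    participant_rqa,
    recurrence_from_attractor,
    rqa_metrics,
)
from .spectral import (
    coordination_pattern_index,
    fundamental_frequency,
    participant_cpi,
    power_spectrum,
)
from .stats import (
    CorrelationSummary,
    bonferroni_alpha,
    fisher_summary,
    normality_gate,
    pearson,
    spearman,
)
from .synthetic import (
    BeepTrain,
    EventSeries,
    Trajectory,
    TrialBundle,
    simulate_cohort,
    simulate_tempo_conditions,
)

log = logging.getLogger("coordstab")

CHANNELS = ("distance_3D", "ML", "SI", "AP")
RQA_INDICES = ("rec", "det", "maxline")


@dataclass(frozen=True)
class AnalysisSpec:
    """All analysis knobs, with the study's defaults."""

    # preprocessing
    filter_mode: str = "residual"  # "residual" | "fixed"
    fixed_cutoff: float = 10.0
    n_cycles: int = 25
    warmup_cycles: int = 2
    n_points: int = 2500
    # spectral
    band_width_fraction: float = 0.10
    f0_convention: str = "half_beep_rate"  # or "beep_rate"
    preferred_f0: str = "peak_pick"  # or "event_rate"
    # embedding + RQA
    delay: int = 25
    dimension: int = 6
    radius_fraction: float = 0.15
    theiler: int = 10
    min_line: int = 10
    maxline_denominator: str = "n_minus_theiler"
    # adaptation
    discard_first: int = 6
    pairing: str = "sequential"
    channels: tuple = CHANNELS


@dataclass(frozen=True)
class CohortSpec:
    """Synthetic cohort description for one experiment run."""

    n_participants: int = 10
    d_values: tuple | None = None  # default: linspace over [0, 0.6]
    adaptability_coupling: float = 0.04
    n_trials: int = 3

    def resolved_d(self) -> np.ndarray:
        if self.d_values is not None:
            return np.asarray(self.d_values, float)
        return np.linspace(0.0, 0.6, self.n_participants)


@dataclass(frozen=True)
class RunConfig:
    experiment: str  # "exp1" | "exp2"
    seed: int = 0
    cohort: CohortSpec = field(default_factory=CohortSpec)
    analysis: AnalysisSpec = field(default_factory=AnalysisSpec)
    out_dir: str | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# single-trial processing
# ---------------------------------------------------------------------------

def _filtered_axis(traj: Trajectory, axis: str, rate: float, spec: AnalysisSpec) -> SampledSignal:
    sig = SampledSignal(traj.axis(axis), rate=rate, kind=f"position_{axis}")
    if spec.filter_mode == "fixed":
        cutoff = spec.fixed_cutoff
    else:
        cutoff = residual_cutoff(sig)
    return butterworth_filter(sig, FilterSpec(cutoff=cutoff))


def _filtered_trajectory(traj: Trajectory, rate: float, spec: AnalysisSpec) -> Trajectory:
    cols = [
        _filtered_axis(traj, axis, rate, spec).values for axis in ("AP", "SI", "ML")
    ]
    return Trajectory(np.column_stack(cols), rate)


def hand_cpi(bundle: TrialBundle, hand: str, spec: AnalysisSpec) -> float:
    """CPI of one hand: spectral concentration of vertical velocity at f0."""
    rate = bundle.sampling_rate
    pos = _filtered_axis(bundle.wrist(hand), "SI", rate, spec)
    vel = differentiate(pos)
    segment = extract_cycles(
        vel, bundle.events.catches(hand), spec.n_cycles, spec.warmup_cycles
    )
    spectrum = power_spectrum(segment)
    if bundle.beeps.condition == "fixed":
        f0 = fundamental_frequency(beeps=bundle.beeps, convention=spec.f0_convention)
    elif spec.preferred_f0 == "event_rate":
        f0 = 1.0 / float(np.mean(np.diff(bundle.events.catches(hand))))
    else:
        f0 = fundamental_frequency(signal=segment)
    return coordination_pattern_index(spectrum, f0, spec.band_width_fraction).cpi


def hand_rqa(bundle: TrialBundle, hand: str, channel: str, spec: AnalysisSpec,
             filtered: dict | None = None) -> RqaMetrics:
    """RQA metrics of one hand and channel (position axis or 3D distance)."""
    rate = bundle.sampling_rate
    if channel == "distance_3D":
        head = (filtered or {}).get("head") or _filtered_trajectory(bundle.head, rate, spec)
        wrist = (filtered or {}).get(hand) or _filtered_trajectory(bundle.wrist(hand), rate, spec)
        sig = head_wrist_distance(head, wrist)
    elif channel in ("ML", "SI", "AP"):
        sig = _filtered_axis(bundle.wrist(hand), channel, rate, spec)
    else:
        raise ParameterError(f"unknown channel {channel!r}")
    segment = extract_cycles(
        sig, bundle.events.catches(hand), spec.n_cycles, spec.warmup_cycles
    )
    segment = standardize_length(segment, spec.n_points)
    att = delay_embed(segment, spec.delay, spec.dimension)
    rm = recurrence_from_attractor(att, spec.radius_fraction, spec.theiler)
    return rqa_metrics(rm, spec.min_line, spec.maxline_denominator)


def process_trial(bundle: TrialBundle, spec: AnalysisSpec) -> dict:
    """CPI and per-channel RQA for one trial, hands averaged.

    Returns ``{"cpi": float, "cpi_left": ..., "cpi_right": ...,
    "rqa": {channel: RqaMetrics}}``.
    """
    rate = bundle.sampling_rate
    filtered = {
        "head": _filtered_trajectory(bundle.head, rate, spec),
        "left": _filtered_trajectory(bundle.wrist_left, rate, spec),
        "right": _filtered_trajectory(bundle.wrist_right, rate, spec),
    }
    cpi_l = hand_cpi(bundle, "left", spec)
    cpi_r = hand_cpi(bundle, "right", spec)
    out = {
        "cpi_left": cpi_l,
        "cpi_right": cpi_r,
        "cpi": participant_cpi(cpi_l, cpi_r),
        "rqa": {},
    }
    for channel in spec.channels:
        m_l = hand_rqa(bundle, "left", channel, spec, filtered)
        m_r = hand_rqa(bundle, "right", channel, spec, filtered)
        out["rqa"][channel] = participant_rqa(m_l, m_r)
    return out


def trial_asynchrony(bundle: TrialBundle, spec: AnalysisSpec) -> float:
    """%Asynchrony of one ramped-tempo trial."""
    pairs = pair_catches_to_beeps(bundle.events, bundle.beeps, spec.pairing)
    return percent_asynchrony(pairs, spec.discard_first).percent_asynchrony


# ---------------------------------------------------------------------------
# experiment drivers
# ---------------------------------------------------------------------------

def _correlate(analysis_id: str, x, y, method: str, k: int,
               per_participant: dict | None = None) -> CorrelationSummary:
    fn = pearson if method == "pearson" else spearman
    r, p = fn(x, y)
    mean_z, ci = (None, None)
    if per_participant:
        rs = []
        for xi, yi in per_participant.values():
            try:
                ri, _ = fn(xi, yi)
            except CoordstabError:
                continue
            if abs(ri) < 1:
                rs.append(ri)
        if len(rs) >= 2:
            mean_z, ci = fisher_summary(rs)
    return CorrelationSummary(
        analysis_id=analysis_id, method=method, n=len(x), r=r, p=p,
        mean_z=mean_z, ci95_r=ci, alpha=bonferroni_alpha(0.05, k),
    )


def _summaries_to_frame(summaries: list[CorrelationSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append(
            {
                "analysis_id": s.analysis_id,
                "method": s.method,
                "n": s.n,
                "r": s.r,
                "p": s.p,
                "mean_z": s.mean_z,
                "ci_lo": None if s.ci95_r is None else s.ci95_r[0],
                "ci_hi": None if s.ci95_r is None else s.ci95_r[1],
                "alpha": s.alpha,
                "significant": s.significant,
            }
        )
    return pd.DataFrame(rows)


def run_experiment1(config: RunConfig) -> dict:
    """Tempo experiment: 7 participants x 10 fixed tempos by default.

    Returns ``{"measurements": DataFrame, "correlations": DataFrame}``.
    A failing participant x condition cell is logged and skipped; it never
    aborts the run.
    """
    if config.experiment != "exp1":
        raise ParameterError("config.experiment must be 'exp1'")
    spec = config.analysis
    cohort = simulate_tempo_conditions(
        n_participants=config.cohort.n_participants,
        seed=config.seed,
    )
    rows = []
    for part in cohort:
        for cond, bundles in part.trials.items():
            try:
                res = process_trial(bundles[0], spec)
            except CoordstabError as exc:
                log.warning("participant %d condition %s failed: %s",
                            part.participant, cond, exc)
                continue
            row = {
                "participant": part.participant,
                "condition": cond,
                "interval_ms": float(cond.split("_")[1]),
                "cpi": res["cpi"],
            }
            for channel in spec.channels:
                m = res["rqa"][channel]
                row |= {f"rec_{channel}": m.rec, f"det_{channel}": m.det,
                        f"maxline_{channel}": m.maxline}
            rows.append(row)
    meas = pd.DataFrame(rows)

    def per_participant(col_x, col_y):
        return {
            pid: (g[col_x].to_numpy(), g[col_y].to_numpy())
            for pid, g in meas.groupby("participant")
        }

    summaries = [
        _correlate("cpi_vs_tempo", meas["interval_ms"], meas["cpi"],
                   "pearson", k=1, per_participant=per_participant("interval_ms", "cpi"))
    ]
    for index in RQA_INDICES:
        for channel in spec.channels:
            col = f"{index}_{channel}"
            summaries.append(
                _correlate(f"cpi_vs_{col}", meas["cpi"], meas[col], "pearson",
                           k=12, per_participant=per_participant("cpi", col))
            )
    return {"measurements": meas, "correlations": _summaries_to_frame(summaries)}


def run_experiment2(config: RunConfig) -> dict:
    """Adaptation experiment: preferred-tempo CPI/RQA plus ramp %Asynchrony.

    Per-participant values are means over the trials of each condition; the
    correlation method is chosen by a Shapiro-Wilk normality gate per
    analysis.
    """
    if config.experiment != "exp2":
        raise ParameterError("config.experiment must be 'exp2'")
    spec = config.analysis
    cs = config.cohort
    cohort = simulate_cohort(
        n_participants=cs.n_participants,
        d_values=cs.resolved_d(),
        adaptability_coupling=cs.adaptability_coupling,
        seed=config.seed,
        n_trials=cs.n_trials,
    )
    rows = []
    for part in cohort:
        try:
            trial_results = [process_trial(b, spec) for b in part.trials["preferred"]]
            row = {
                "participant": part.participant,
                "dwell_fraction": part.dwell_fraction,
                "cpi": float(np.mean([t["cpi"] for t in trial_results])),
            }
            for channel in spec.channels:
                for index in RQA_INDICES:
                    row[f"{index}_{channel}"] = float(
                        np.mean([getattr(t["rqa"][channel], index) for t in trial_results])
                    )
            for cond, label in (("up_ramp", "up"), ("down_ramp", "down")):
                row[f"asynchrony_{label}"] = float(
                    np.mean([trial_asynchrony(b, spec) for b in part.trials[cond]])
                )
        except CoordstabError as exc:
            log.warning("participant %d failed: %s", part.participant, exc)
            continue
        rows.append(row)
    meas = pd.DataFrame(rows)

    def gated(analysis_id, col_x, col_y, k):
        method = normality_gate([meas[col_x].to_numpy(), meas[col_y].to_numpy()])
        return _correlate(analysis_id, meas[col_x], meas[col_y], method, k)

    summaries = []
    for index in RQA_INDICES:
        for channel in spec.channels:
            summaries.append(gated(f"cpi_vs_{index}_{channel}", "cpi",
                                   f"{index}_{channel}", k=12))
    for label in ("up", "down"):
        summaries.append(gated(f"cpi_vs_asynchrony_{label}", "cpi",
                               f"asynchrony_{label}", k=2))
    for label in ("up", "down"):
        for index in RQA_INDICES:
            for channel in spec.channels:
                summaries.append(
                    gated(f"asynchrony_{label}_vs_{index}_{channel}",
                          f"asynchrony_{label}", f"{index}_{channel}", k=12)
                )
    return {"measurements": meas, "correlations": _summaries_to_frame(summaries)}


# ---------------------------------------------------------------------------
# focused cohort summaries (used by the replication sweep and acceptance)
# ---------------------------------------------------------------------------

def cohort_cpi_det_si(seed, n_participants: int = 10,
                      spec: AnalysisSpec | None = None) -> pd.DataFrame:
    """One cohort's preferred-condition CPI and SI-channel %DET per participant.

    A lean variant of the adaptation experiment used for replication sweeps:
    one preferred trial per participant, SI channel only.
    """
    spec = spec or AnalysisSpec(channels=("SI",))
    cohort = simulate_cohort(
        n_participants=n_participants,
        d_values=np.linspace(0.0, 0.6, n_participants),
        seed=seed,
        n_trials=1,
        conditions=("preferred",),
    )
    rows = []
    for part in cohort:
        bundle = part.trials["preferred"][0]
        cpi = participant_cpi(hand_cpi(bundle, "left", spec), hand_cpi(bundle, "right", spec))
        det = participant_rqa(
            hand_rqa(bundle, "left", "SI", spec), hand_rqa(bundle, "right", "SI", spec)
        ).det
        rows.append({"participant": part.participant, "d": part.dwell_fraction,
                     "cpi": cpi, "det_SI": det})
    return pd.DataFrame(rows)


def cohort_cpi_asynchrony(seed, n_participants: int = 10,
                          adaptability_coupling: float = 0.04,
                          spec: AnalysisSpec | None = None) -> pd.DataFrame:
    """One cohort's preferred CPI and up-ramp %Asynchrony per participant."""
    spec = spec or AnalysisSpec()
    cohort = simulate_cohort(
        n_participants=n_participants,
        d_values=np.linspace(0.0, 0.6, n_participants),
        adaptability_coupling=adaptability_coupling,
        seed=seed,
        n_trials=1,
        conditions=("preferred", "up_ramp"),
    )
    rows = []
    for part in cohort:
        pref = part.trials["preferred"][0]
        cpi = participant_cpi(hand_cpi(pref, "left", spec), hand_cpi(pref, "right", spec))
        asyn = trial_asynchrony(part.trials["up_ramp"][0], spec)
        rows.append({"participant": part.participant, "d": part.dwell_fraction,
                     "cpi": cpi, "asynchrony_up": asyn})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# trial I/O (CSV dialect defined by the synthetic generator) and results
# ---------------------------------------------------------------------------

def read_trial(directory, stem: str = "trial") -> TrialBundle:
    """Read a trial written by :func:`coordstab.synthetic.write_trial`."""
    directory = Path(directory)
    markers_path = directory / f"{stem}_markers.csv"
    if not markers_path.exists():
        raise FormatError(f"missing {markers_path}")
    df = pd.read_csv(markers_path)
    required = ["time_s", "marker_id", "x_mm", "y_mm", "z_mm"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{markers_path}: missing columns {missing}")
    if df.empty:
        raise FormatError(f"{markers_path}: no data rows")
    numeric = df[["time_s", "x_mm", "y_mm", "z_mm"]]
    if numeric.isna().any().any():
        bad = int(numeric.isna().any(axis=1).idxmax()) + 2  # +header +1-based
        raise FormatError(f"{markers_path}: NaN at line {bad}")

    meta_path = directory / f"{stem}_meta.yaml"
    meta = yaml.safe_load(meta_path.read_text()) if meta_path.exists() else {}
    rate = float(meta.get("sampling_rate", 100.0))

    trajs = {}
    for marker_id, g in df.groupby("marker_id"):
        t = g["time_s"].to_numpy()
        if np.any(np.diff(t) <= 0):
            bad = int(g.index[np.argmax(np.diff(t) <= 0) + 1]) + 2
            raise FormatError(f"{markers_path}: non-monotone time at line {bad}")
        trajs[marker_id] = Trajectory(g[["x_mm", "y_mm", "z_mm"]].to_numpy(), rate)
    for name in ("head", "wrist_left", "wrist_right"):
        if name not in trajs:
            raise FormatError(f"{markers_path}: marker {name!r} absent")

    beeps_path = directory / f"{stem}_beeps.txt"
    onsets = np.loadtxt(beeps_path, ndmin=1) if beeps_path.exists() and beeps_path.stat().st_size else np.empty(0)
    beep_condition = meta.get("beep_condition", "none" if onsets.size == 0 else "fixed")
    interval_ms = None
    if beep_condition == "fixed" and onsets.size > 1:
        interval_ms = float(np.round(np.mean(np.diff(onsets)) * 1000.0, 6))
    beeps = BeepTrain(onsets, beep_condition, interval_ms=interval_ms)

    ev = pd.read_csv(directory / f"{stem}_events.csv")

    def series(hand, kind):
        sel = ev[(ev["hand"] == hand) & (ev["type"] == kind)]["time_s"].to_numpy()
        return np.sort(sel)

    events = EventSeries(
        catch_left=series("left", "catch"),
        catch_right=series("right", "catch"),
        throw_left=series("left", "throw"),
        throw_right=series("right", "throw"),
    )
    return TrialBundle(
        head=trajs["head"],
        wrist_left=trajs["wrist_left"],
        wrist_right=trajs["wrist_right"],
        beeps=beeps,
        events=events,
        sampling_rate=rate,
        condition=str(meta.get("condition", beep_condition)),
        metadata=meta,
    )


def write_results(tables: dict, out_dir, config: RunConfig | None = None) -> dict:
    """Write result DataFrames as CSV plus a reproducibility manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in tables.items():
        p = out / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = p
    if config is not None:
        cfg = config.to_dict()
        blob = yaml.safe_dump(cfg, sort_keys=True)
        manifest = {
            "package_version": __version__,
            "config": cfg,
            "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        }
        mp = out / "manifest.yaml"
        mp.write_text(yaml.safe_dump(manifest, sort_keys=False))
        paths["manifest"] = mp
    return paths
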