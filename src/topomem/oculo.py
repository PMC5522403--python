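"""Gaze calibration, saccade detection and memory-guided-saccade scoring.

Monocular gaze is sampled at 1000 Hz.  Raw tracker coordinates are mapped
to degrees of visual angle with a third-order (bivariate cubic) polynomial
fit to known calibration locations.  Saccades are detected as maximal runs
where eye speed exceeds a velocity threshold (30 deg/s by convention).

Each memory-guided-saccade trial is scored with two error metrics:

* **MGS error** — distance from the endpoint of the initial memory-guided
  saccade (first saccade after the response cue with amplitude above a
  minimum) to the true target, in degrees.
* **FEP error** — distance from the final eye position (mean gaze over a
  short window just before feedback re-presentation, i.e. after any
  corrective saccades) to the target.

Trials are excluded when the saccadic response time falls outside
(100, 900) ms, when fixation is broken before the response cue, or when no
qualifying saccade occurs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "TrialEvents",
    "GazeTrace",
    "CalibrationModel",
    "SaccadeEvent",
    "TrialScore",
    "ScoreConfig",
    "fit_calibration",
    "apply_calibration",
    "velocity_trace",
    "detect_saccades",
    "score_trial",
    "score_session",
    "scores_to_frame",
    "exclusion_summary",
    "write_asc",
    "read_asc",
    "write_gaze_csv",
    "read_gaze_csv",
]

EXCLUSION_REASONS = ("rt_short", "rt_long", "fixation_break", "no_saccade")


@dataclass
class TrialEvents:
    """Event markers for one trial, times in trace milliseconds."""

    target_x: float
    target_y: float
    target_onset_ms: float
    cue_ms: float
    feedback_ms: float
    delay_s: float | None = None


@dataclass
class GazeTrace:
    """Gaze samples for one trial with event markers and labels."""

    time_ms: np.ndarray
    x: np.ndarray
    y: np.ndarray
    events: TrialEvents | None = None
    calibrated: bool = True
    trial_id: int | str | None = None
    condition: str = "noTMS"
    subject: str | None = None
    run: int | None = None

    def __post_init__(self) -> None:
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.time_ms) == len(self.x) == len(self.y)):
            raise ValueError("time, x, y must have equal length")
        if len(self.time_ms) >= 2 and not (np.diff(self.time_ms) > 0).all():
            raise ValueError("time must be strictly increasing")
        if self.events is not None:
            e = self.events
            if not (e.target_onset_ms < e.cue_ms < e.feedback_ms):
                raise ValueError("events must be ordered onset < cue < feedback")


# ---------------------------------------------------------------------------
# calibration

def _cubic_terms(x: np.ndarray, y: np.ndarray, reduced: bool) -> np.ndarray:
    """Bivariate cubic design matrix.

    Full model: all monomials x^i y^j with i + j <= 3 (10 terms).  The
    reduced 9-term model (for exactly nine calibration points, where x^3
    and y^3 are collinear with x and y on a 3x3 grid) swaps the pure cubic
    terms for the x^2 y^2 cross term.
    """
    cols = [np.ones_like(x), x, y, x * y, x ** 2, y ** 2,
            x ** 2 * y, x * y ** 2]
    if reduced:
        cols.append(x ** 2 * y ** 2)
    else:
        cols.extend([x ** 3, y ** 3])
    return np.column_stack(cols)


@dataclass
class CalibrationModel:
    """Third-order polynomial mapping raw gaze to degrees of visual angle."""

    coef_x: np.ndarray
    coef_y: np.ndarray
    reduced: bool
    residual_rms: float

    def __call__(self, x_raw: np.ndarray, y_raw: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        A = _cubic_terms(np.asarray(x_raw, float), np.asarray(y_raw, float),
                         self.reduced)
        return A @ self.coef_x, A @ self.coef_y


def fit_calibration(raw_points: np.ndarray, known_locations: np.ndarray) -> CalibrationModel:
    """Least-squares cubic calibration from raw samples to known locations.

    With exactly nine point pairs (the standard 9-point grid) the reduced
    9-term model is used; ten or more pairs fit the full 10-term cubic.
    """
    raw = np.asarray(raw_points, dtype=float)
    known = np.asarray(known_locations, dtype=float)
    if raw.shape != known.shape or raw.ndim != 2 or raw.shape[1] != 2:
        raise ValueError("raw_points and known_locations must both be (N, 2)")
    n = raw.shape[0]
    if n < 9:
        raise ValueError(f"need at least 9 calibration points, got {n}")
    reduced = n == 9
    A = _cubic_terms(raw[:, 0], raw[:, 1], reduced)
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        raise ValueError(
            f"rank-deficient calibration design (rank {rank} < {A.shape[1]}): "
            "calibration points are collinear or degenerate")
    coef_x, *_ = np.linalg.lstsq(A, known[:, 0], rcond=None)
    coef_y, *_ = np.linalg.lstsq(A, known[:, 1], rcond=None)
    pred = np.column_stack([A @ coef_x, A @ coef_y])
    rms = float(np.sqrt(np.mean((pred - known) ** 2)))
    return CalibrationModel(coef_x=coef_x, coef_y=coef_y, reduced=reduced,
                            residual_rms=rms)


def apply_calibration(trace: GazeTrace, model: CalibrationModel) -> GazeTrace:
    """Return a calibrated copy of a raw trace."""
    x, y = model(trace.x, trace.y)
    return replace(trace, x=x, y=y, calibrated=True)


# ---------------------------------------------------------------------------
# velocity & saccade detection

@dataclass(frozen=True)
class SmoothConfig:
    """Velocity estimation settings: moving-average pre-smooth then a
    5-point central-difference derivative."""

    presmooth_ms: int = 7


def _moving_average(v: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return v
    pad = width // 2
    vp = np.pad(v, pad, mode="edge")
    kernel = np.ones(width) / width
    out = np.convolve(vp, kernel, mode="same")
    return out[pad:len(vp) - pad]


def velocity_trace(trace: GazeTrace, smooth: SmoothConfig | None = None) -> np.ndarray:
    """Per-sample eye speed in deg/s.

    Positions are pre-smoothed with a short moving average, differentiated
    with a 5-point central-difference stencil, and combined as the
    Euclidean norm of the two velocity components.
    """
    smooth = smooth or SmoothConfig()
    n = len(trace.time_ms)
    if n < max(5, smooth.presmooth_ms):
        raise ValueError(
            f"trace of {n} samples is shorter than the smoothing window")
    dt_ms = float(np.median(np.diff(trace.time_ms)))
    xs = _moving_average(trace.x, smooth.presmooth_ms)
    ys = _moving_average(trace.y, smooth.presmooth_ms)

    def deriv(v: np.ndarray) -> np.ndarray:
        d = np.empty_like(v)
        d[2:-2] = (v[:-4] - 8 * v[1:-3] + 8 * v[3:-1] - v[4:]) / (12.0 * dt_ms)
        d[:2] = d[2]
        d[-2:] = d[-3]
        return d

    vx = deriv(xs)
    vy = deriv(ys)
    return np.hypot(vx, vy) * 1000.0  # deg/ms -> deg/s


@dataclass
class SaccadeEvent:
    """One detected saccade."""

    onset_ms: float
    offset_ms: float
    start_xy: tuple[float, float]
    end_xy: tuple[float, float]
    peak_velocity: float

    @property
    def amplitude(self) -> float:
        return math.hypot(self.end_xy[0] - self.start_xy[0],
                          self.end_xy[1] - self.start_xy[1])


def detect_saccades(trace: GazeTrace, threshold: float = 30.0,
                    min_amplitude: float = 0.0, merge_ms: float = 10.0,
                    smooth: SmoothConfig | None = None,
                    speed: np.ndarray | None = None) -> list[SaccadeEvent]:
    """Velocity-threshold saccade detection.

    Events are maximal runs where speed > ``threshold`` deg/s; onset is the
    first supra-threshold sample and offset the first sample back at or
    below threshold.  Runs separated by less than ``merge_ms`` are merged
    (debounce); events with amplitude below ``min_amplitude`` are dropped.
    """
    if speed is None:
        speed = velocity_trace(trace, smooth)
    above = speed > threshold
    if not above.any():
        return []
    idx = np.flatnonzero(above)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    run_ends = np.concatenate([idx[breaks], [idx[-1]]])  # inclusive

    t = trace.time_ms
    merged: list[list[int]] = []
    for s, e in zip(run_starts, run_ends):
        if merged and t[s] - t[merged[-1][1]] < merge_ms:
            merged[-1][1] = e
        else:
            merged.append([int(s), int(e)])

    events: list[SaccadeEvent] = []
    for s, e in merged:
        off = min(e + 1, len(t) - 1)  # first sample back at/below threshold
        ev = SaccadeEvent(
            onset_ms=float(t[s]), offset_ms=float(t[off]),
            start_xy=(float(trace.x[s]), float(trace.y[s])),
            end_xy=(float(trace.x[off]), float(trace.y[off])),
            peak_velocity=float(speed[s:e + 1].max()))
        if ev.amplitude >= min_amplitude:
            events.append(ev)
    return events


# ---------------------------------------------------------------------------
# trial scoring

@dataclass
class ScoreConfig:
    """Scoring thresholds (degrees, milliseconds)."""

    saccade_threshold: float = 30.0   # deg/s velocity criterion
    min_saccade_amp: float = 0.5      # detection floor
    min_primary_amp: float = 2.0      # MGS must exceed this (no microsaccades)
    rt_min_ms: float = 100.0
    rt_max_ms: float = 900.0
    fixation_radius: float = 2.0      # break window around fixation
    fep_window_ms: float = 100.0      # averaging window before feedback
    max_blink_gap_ms: float = 50.0
    merge_ms: float = 10.0
    smooth: SmoothConfig = field(default_factory=SmoothConfig)


@dataclass
class TrialScore:
    """Per-trial outcome: errors in degrees, SRT in ms, exclusion status."""

    trial_id: int | str | None
    condition: str
    subject: str | None
    target_x: float
    target_y: float
    delay_s: float | None
    excluded: bool
    reason: str | None
    srt_ms: float = float("nan")
    mgs_error: float = float("nan")
    fep_error: float = float("nan")
    mgs_x: float = float("nan")
    mgs_y: float = float("nan")
    n_saccades: int = 0


def _interpolate_blinks(trace: GazeTrace, cfg: ScoreConfig) -> tuple[GazeTrace, bool]:
    """Linearly interpolate missing samples; flag long gaps in the response
    window (cue .. feedback) as unscorable."""
    bad = ~(np.isfinite(trace.x) & np.isfinite(trace.y))
    if not bad.any():
        return trace, False
    t = trace.time_ms
    e = trace.events
    long_gap_in_response = False
    idx = np.flatnonzero(bad)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    gap_starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    gap_ends = np.concatenate([idx[breaks], [idx[-1]]])
    for s, g in zip(gap_starts, gap_ends):
        dur = t[g] - t[s] + 1.0
        if dur > cfg.max_blink_gap_ms and e is not None:
            if t[g] >= e.cue_ms and t[s] <= e.feedback_ms:
                long_gap_in_response = True
    good = ~bad
    x = trace.x.copy()
    y = trace.y.copy()
    x[bad] = np.interp(t[bad], t[good], trace.x[good])
    y[bad] = np.interp(t[bad], t[good], trace.y[good])
    return replace(trace, x=x, y=y), long_gap_in_response


def score_trial(trace: GazeTrace, cfg: ScoreConfig | None = None) -> TrialScore:
    """Score one memory-guided-saccade trial (see module docstring)."""
    cfg = cfg or ScoreConfig()
    if trace.events is None:
        raise ValueError("trace is missing trial events")
    e = trace.events
    for marker in ("target_onset_ms", "cue_ms", "feedback_ms"):
        if getattr(e, marker) is None or not np.isfinite(getattr(e, marker)):
            raise ValueError(f"trace is missing event marker {marker!r}")

    base = dict(trial_id=trace.trial_id, condition=trace.condition,
                subject=trace.subject, target_x=e.target_x, target_y=e.target_y,
                delay_s=e.delay_s)

    trace, long_gap = _interpolate_blinks(trace, cfg)
    if long_gap:
        return TrialScore(**base, excluded=True, reason="no_saccade")

    t = trace.time_ms
    # fixation-break check over [target onset, cue)
    pre = (t >= e.target_onset_ms) & (t < e.cue_ms)
    r = np.hypot(trace.x[pre], trace.y[pre])
    if (r > cfg.fixation_radius).any():
        return TrialScore(**base, excluded=True, reason="fixation_break")

    speed = velocity_trace(trace, cfg.smooth)
    saccades = detect_saccades(trace, threshold=cfg.saccade_threshold,
                               min_amplitude=cfg.min_saccade_amp,
                               merge_ms=cfg.merge_ms, speed=speed)
    primary = next((s for s in saccades
                    if s.onset_ms > e.cue_ms and s.amplitude >= cfg.min_primary_amp),
                   None)
    if primary is None:
        return TrialScore(**base, excluded=True, reason="no_saccade")
    srt = primary.onset_ms - e.cue_ms
    if srt < cfg.rt_min_ms:
        return TrialScore(**base, excluded=True, reason="rt_short", srt_ms=srt)
    if srt > cfg.rt_max_ms:
        return TrialScore(**base, excluded=True, reason="rt_long", srt_ms=srt)

    mgs_x, mgs_y = primary.end_xy
    mgs_error = math.hypot(mgs_x - e.target_x, mgs_y - e.target_y)

    fep_sel = (t >= e.feedback_ms - cfg.fep_window_ms) & (t < e.feedback_ms)
    if not fep_sel.any():
        raise ValueError("trace does not cover the final-eye-position window")
    fep_x = float(trace.x[fep_sel].mean())
    fep_y = float(trace.y[fep_sel].mean())
    fep_error = math.hypot(fep_x - e.target_x, fep_y - e.target_y)

    n_post = sum(1 for s in saccades if s.onset_ms > e.cue_ms)
    return TrialScore(**base, excluded=False, reason=None, srt_ms=srt,
                      mgs_error=mgs_error, fep_error=fep_error,
                      mgs_x=mgs_x, mgs_y=mgs_y, n_saccades=n_post)


def score_session(traces: list[GazeTrace], cfg: ScoreConfig | None = None) -> list[TrialScore]:
    """Score a list of trials; trial identifiers must be unique."""
    ids = [t.trial_id for t in traces]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate trial identifiers in session")
    return [score_trial(t, cfg) for t in traces]


def scores_to_frame(scores: list[TrialScore]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in scores])


def exclusion_summary(scores: list[TrialScore]) -> dict[str, int]:
    """Counts of included trials and of each exclusion reason."""
    out = {"included": sum(not s.excluded for s in scores)}
    for reason in EXCLUSION_REASONS:
        out[reason] = sum(s.reason == reason for s in scores)
    return out


# ---------------------------------------------------------------------------
# I/O: EyeLink-ASC-like text and a CSV dialect

def write_asc(traces: list[GazeTrace], path: str) -> None:
    """Write trials as EyeLink-ASC-style text (MSG lines + sample lines)."""
    with open(path, "w") as fh:
        for tr in traces:
            e = tr.events
            t0 = int(tr.time_ms[0])
            fh.write(f"MSG\t{t0} TRIALID {tr.trial_id}\n")
            fh.write(f"MSG\t{t0} CONDITION {tr.condition}\n")
            if tr.subject is not None:
                fh.write(f"MSG\t{t0} SUBJECT {tr.subject}\n")
            if e is not None:
                fh.write(f"MSG\t{t0} TARGET_POS {e.target_x:.4f} {e.target_y:.4f}\n")
                fh.write(f"MSG\t{int(e.target_onset_ms)} TARGET_ONSET\n")
                fh.write(f"MSG\t{int(e.cue_ms)} CUE\n")
                fh.write(f"MSG\t{int(e.feedback_ms)} FEEDBACK\n")
                if e.delay_s is not None:
                    fh.write(f"MSG\t{t0} DELAY {e.delay_s}\n")
            for t, x, y in zip(tr.time_ms, tr.x, tr.y):
                if np.isfinite(x) and np.isfinite(y):
                    fh.write(f"{int(t)}\t{x:.4f}\t{y:.4f}\t1000.0\n")
                else:
                    fh.write(f"{int(t)}\t.\t.\t0.0\n")
            fh.write(f"MSG\t{int(tr.time_ms[-1])} TRIAL_END\n")


def read_asc(path: str) -> list[GazeTrace]:
    """Read trials from the ASC-like text written by :func:`write_asc`."""
    traces: list[GazeTrace] = []
    cur: dict | None = None

    def finish(c: dict) -> None:
        ev = None
        if "target" in c and "onset" in c:
            ev = TrialEvents(target_x=c["target"][0], target_y=c["target"][1],
                             target_onset_ms=c["onset"], cue_ms=c["cue"],
                             feedback_ms=c["feedback"], delay_s=c.get("delay"))
        traces.append(GazeTrace(
            time_ms=np.array(c["t"]), x=np.array(c["x"]), y=np.array(c["y"]),
            events=ev, trial_id=c.get("id"), condition=c.get("condition", "noTMS"),
            subject=c.get("subject")))

    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "MSG":
                t = float(parts[1])
                tag = parts[2]
                if tag == "TRIALID":
                    if cur is not None:
                        finish(cur)
                    cur = {"t": [], "x": [], "y": [], "id": _maybe_int(parts[3])}
                elif cur is None:
                    continue
                elif tag == "CONDITION":
                    cur["condition"] = parts[3]
                elif tag == "SUBJECT":
                    cur["subject"] = parts[3]
                elif tag == "TARGET_POS":
                    cur["target"] = (float(parts[3]), float(parts[4]))
                elif tag == "TARGET_ONSET":
                    cur["onset"] = t
                elif tag == "CUE":
                    cur["cue"] = t
                elif tag == "FEEDBACK":
                    cur["feedback"] = t
                elif tag == "DELAY":
                    cur["delay"] = float(parts[3])
            elif cur is not None:
                cur["t"].append(float(parts[0]))
                if parts[1] == ".":
                    cur["x"].append(np.nan)
                    cur["y"].append(np.nan)
                else:
                    cur["x"].append(float(parts[1]))
                    cur["y"].append(float(parts[2]))
    if cur is not None:
        finish(cur)
    return traces


def _maybe_int(s: str):
    try:
        return int(s)
    except ValueError:
        return s


def write_gaze_csv(traces: list[GazeTrace], samples_path: str, events_path: str) -> None:
    """Write gaze as a samples CSV plus an events CSV."""
    srows, erows = [], []
    for tr in traces:
        for t, x, y in zip(tr.time_ms, tr.x, tr.y):
            srows.append({"trial_id": tr.trial_id, "time_ms": t,
                          "x": x, "y": y, "pupil": 1000.0})
        e = tr.events
        erows.append({
            "trial_id": tr.trial_id, "condition": tr.condition,
            "subject": tr.subject, "run": tr.run,
            "target_x": e.target_x if e else np.nan,
            "target_y": e.target_y if e else np.nan,
            "target_onset_ms": e.target_onset_ms if e else np.nan,
            "cue_ms": e.cue_ms if e else np.nan,
            "feedback_ms": e.feedback_ms if e else np.nan,
            "delay_s": e.delay_s if e else np.nan,
        })
    pd.DataFrame(srows).to_csv(samples_path, index=False)
    pd.DataFrame(erows).to_csv(events_path, index=False)


def read_gaze_csv(samples_path: str, events_path: str) -> list[GazeTrace]:
    samples = pd.read_csv(samples_path)
    events = pd.read_csv(events_path)
    traces = []
    for _, erow in events.iterrows():
        sel = samples[samples["trial_id"] == erow["trial_id"]]
        ev = TrialEvents(target_x=erow["target_x"], target_y=erow["target_y"],
                         target_onset_ms=erow["target_onset_ms"],
                         cue_ms=erow["cue_ms"], feedback_ms=erow["feedback_ms"],
                         delay_s=erow.get("delay_s"))
        run = erow.get("run")
        traces.append(GazeTrace(
            time_ms=sel["time_ms"].to_numpy(), x=sel["x"].to_numpy(),
            y=sel["y"].to_numpy(), events=ev, trial_id=erow["trial_id"],
            condition=str(erow["condition"]),
            subject=None if pd.isna(erow.get("subject")) else str(erow["subject"]),
            run=None if pd.isna(run) else int(run)))
    return traces
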