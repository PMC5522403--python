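"""Ground-truth-known synthetic data for every pipeline stage.

Three generators:

* :func:`simulate_voxels` — BOLD time series driven by the CSS pRF forward
  model with known parameters plus white (optionally AR(1)) noise at a
  target SNR, for parameter-recovery studies.
* :func:`simulate_trial` — a 1000 Hz memory-guided-saccade gaze trace with
  main-sequence saccade dynamics: fixation, a primary saccade at a sampled
  response latency toward the target plus bivariate-normal endpoint error,
  zero to two corrective saccades that move gaze toward an independently
  drawn memory anchor, and band-limited measurement noise.  Exclusion
  violations (late/early responses, fixation breaks) are planted
  explicitly and recorded as ground truth.
* :func:`simulate_cohort` — a multi-subject experiment: a no-TMS baseline
  session per subject plus TMS sessions, targets at 10 deg eccentricity
  away from the cardinal axes, delays drawn from {3, 3.5, 4, 4.5, 5} s,
  and condition-dependent error inflation emulating stimulation effects.
  :func:`simulate_cohort_scores` is a score-level fast path drawing the
  same per-trial error distributions directly (no traces), for large
  Monte-Carlo calibration runs.

Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .oculo import GazeTrace, TrialEvents
from .prf import PRFParams, double_gamma_hrf, predict_bold
from .stats import SITE_HEMISPHERES
from .stimulus import ApertureMovie

__all__ = [
    "BoldSimConfig",
    "SaccadeSimConfig",
    "CohortSpec",
    "TrialTruth",
    "simulate_voxels",
    "simulate_trial",
    "simulate_saccade_sequence",
    "simulate_cohort",
    "simulate_cohort_scores",
    "main_sequence_duration_ms",
]


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# ---------------------------------------------------------------------------
# BOLD simulation

@dataclass
class BoldSimConfig:
    """Parameter ranges and noise model for synthetic voxels."""

    x0_range: tuple[float, float] = (-8.0, 8.0)
    y0_range: tuple[float, float] = (-8.0, 8.0)
    sigma_range: tuple[float, float] = (0.5, 4.0)
    n_range: tuple[float, float] = (0.2, 1.0)
    beta_range: tuple[float, float] = (0.5, 2.0)
    snr: float = 5.0          # signal SD / noise SD; np.inf for noiseless
    ar1: float = 0.0          # AR(1) coefficient of the noise, in [0, 1)
    tr_s: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.snr <= 0:
            raise ValueError(f"snr must be positive, got {self.snr}")
        if not 0 <= self.ar1 < 1:
            raise ValueError("ar1 must be in [0, 1)")


def simulate_voxels(cfg: BoldSimConfig, movie: ApertureMovie, n_voxels: int,
                    rng=None) -> tuple[np.ndarray, list[PRFParams]]:
    """Simulate voxel time series with known CSS pRF parameters.

    Returns a (n_voxels, T) array and the generating parameters.  Noise SD
    is set per voxel to clean-signal SD divided by ``cfg.snr``.
    """
    if n_voxels < 1:
        raise ValueError("n_voxels must be >= 1")
    rng = _rng(cfg.seed if rng is None else rng)
    hrf = double_gamma_hrf(movie.tr_s)
    T = movie.n_frames
    Y = np.empty((n_voxels, T))
    truths: list[PRFParams] = []
    for v in range(n_voxels):
        p = PRFParams(
            x0=rng.uniform(*cfg.x0_range), y0=rng.uniform(*cfg.y0_range),
            sigma=rng.uniform(*cfg.sigma_range), n_exp=rng.uniform(*cfg.n_range),
            beta=rng.uniform(*cfg.beta_range))
        clean = predict_bold(p, movie, hrf).values
        if np.isinf(cfg.snr):
            noise = np.zeros(T)
        else:
            sd = clean.std() / cfg.snr
            w = rng.normal(0.0, 1.0, T)
            if cfg.ar1 > 0:
                e = np.empty(T)
                e[0] = w[0]
                for t in range(1, T):
                    e[t] = cfg.ar1 * e[t - 1] + w[t]
                e *= math.sqrt(1 - cfg.ar1 ** 2)  # unit stationary variance
                noise = sd * e
            else:
                noise = sd * w
        Y[v] = clean + noise
        truths.append(p)
    return Y, truths


# ---------------------------------------------------------------------------
# saccade-trace simulation

def main_sequence_duration_ms(amplitude_deg: float, slope: float = 2.2,
                              intercept: float = 21.0) -> float:
    """Saccade duration from amplitude via the main sequence (ms)."""
    return slope * amplitude_deg + intercept


@dataclass
class SaccadeSimConfig:
    """Trial-trace generator settings (degrees, milliseconds)."""

    mgs_noise_sd: float = 1.2       # endpoint scatter of the primary saccade
    fep_noise_sd: float = 0.5       # scatter of the final memory anchor
    corrective_probs: tuple[float, ...] = (0.25, 0.55, 0.20)  # P(0, 1, 2)
    corrective_gain: float = 1.0    # fraction of gaze->anchor distance covered
    corrective_latency_ms: float = 130.0
    srt_shape: float = 9.0          # gamma(shape, scale) + shift -> mean 350 ms
    srt_scale: float = 25.0
    srt_shift_ms: float = 125.0
    fixation_noise_sd: float = 0.05
    noise_smooth_ms: int = 20       # band limit of measurement noise
    pre_target_ms: float = 500.0
    flash_ms: float = 200.0
    feedback_delay_ms: float = 800.0  # cue -> feedback re-presentation
    tail_ms: float = 150.0
    cardinal_margin_deg: float = 10.0
    ms_slope: float = 2.2
    ms_intercept: float = 21.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mgs_noise_sd < 0 or self.fep_noise_sd < 0 or self.fixation_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if not 0 < self.corrective_gain <= 1:
            raise ValueError("corrective_gain must be in (0, 1]")
        if abs(sum(self.corrective_probs) - 1.0) > 1e-9:
            raise ValueError("corrective_probs must sum to 1")


@dataclass
class TrialTruth:
    """Generator ground truth for one simulated trial."""

    trial_id: int | str | None
    condition: str
    subject: str | None
    target_x: float
    target_y: float
    delay_s: float
    srt_ms: float
    mgs_x: float
    mgs_y: float
    mgs_error: float
    fep_x: float
    fep_y: float
    fep_error: float
    n_correctives: int
    planted_reason: str | None


def _raised_cosine_profile(n_ms: int) -> np.ndarray:
    """Normalized displacement profile s(tau) with raised-cosine velocity."""
    tau = np.linspace(0.0, 1.0, n_ms + 1)[1:]
    return tau - np.sin(2 * np.pi * tau) / (2 * np.pi)


def _add_movement(pos: np.ndarray, t: np.ndarray, onset_ms: float,
                  displacement: np.ndarray, duration_ms: float) -> None:
    """Add a saccadic displacement (in place) to a (N, 2) position array."""
    n = max(int(round(duration_ms)), 2)
    i0 = int(np.searchsorted(t, onset_ms))
    prof = _raised_cosine_profile(n)
    i1 = min(i0 + n, len(t))
    pos[i0:i1] += displacement[None, :] * prof[: i1 - i0, None]
    pos[i1:] += displacement[None, :]


def _band_limited_noise(rng: np.random.Generator, n: int, sd: float,
                        smooth_ms: int) -> np.ndarray:
    """Temporally correlated positional noise with the requested SD."""
    if sd == 0:
        return np.zeros((n, 2))
    w = rng.normal(0.0, 1.0, (n + smooth_ms, 2))
    kernel = np.ones(smooth_ms) / smooth_ms
    sm = np.column_stack([np.convolve(w[:, k], kernel, mode="same")
                          for k in range(2)])[smooth_ms // 2:smooth_ms // 2 + n]
    sm *= sd / sm.std(axis=0, keepdims=True).mean()
    return sm


def simulate_trial(cfg: SaccadeSimConfig, target_xy: tuple[float, float],
                   condition: str = "noTMS", mgs_inflation: float = 1.0,
                   fep_inflation: float = 1.0, planted: str | None = None,
                   delay_s: float | None = None, trial_id=None,
                   subject: str | None = None,
                   rng=None) -> tuple[GazeTrace, TrialTruth]:
    """Simulate one memory-guided-saccade trial at 1000 Hz.

    ``mgs_inflation`` and ``fep_inflation`` scale the respective endpoint
    noise SDs (condition-dependent error inflation); ``planted`` forces an
    exclusion violation (``rt_long``, ``rt_short`` or ``fixation_break``).
    """
    rng = _rng(cfg.seed if rng is None else rng)
    tx, ty = float(target_xy[0]), float(target_xy[1])
    ecc = math.hypot(tx, ty)
    if ecc <= 0:
        raise ValueError("target eccentricity must be positive")
    ang = math.degrees(math.atan2(ty, tx)) % 90.0
    if min(ang, 90.0 - ang) < cfg.cardinal_margin_deg:
        raise ValueError("target lies near a cardinal axis")
    if planted is not None and planted not in ("rt_long", "rt_short", "fixation_break"):
        raise ValueError(f"unknown planted violation {planted!r}")

    if delay_s is None:
        delay_s = float(rng.choice([3.0, 3.5, 4.0, 4.5, 5.0]))
    delay_ms = delay_s * 1000.0
    target_onset = cfg.pre_target_ms
    cue = target_onset + cfg.flash_ms + delay_ms
    feedback = cue + cfg.feedback_delay_ms

    # primary saccade latency
    if planted == "rt_long":
        srt = 950.0
    elif planted == "rt_short":
        srt = 80.0
    else:
        srt = cfg.srt_shift_ms + rng.gamma(cfg.srt_shape, cfg.srt_scale)
        srt = float(np.clip(srt, 150.0, 750.0))

    # trace must cover the saccade even for late (excluded) responses
    t_end = max(feedback + cfg.tail_ms, cue + srt + 150.0)
    t = np.arange(0.0, t_end)
    pos = np.zeros((len(t), 2))

    e_mgs = rng.normal(0.0, cfg.mgs_noise_sd * mgs_inflation, 2)
    e_fep = rng.normal(0.0, cfg.fep_noise_sd * fep_inflation, 2)
    mgs_end = np.array([tx, ty]) + e_mgs
    anchor = np.array([tx, ty]) + e_fep

    amp = float(np.linalg.norm(mgs_end))
    dur = main_sequence_duration_ms(amp, cfg.ms_slope, cfg.ms_intercept)
    _add_movement(pos, t, cue + srt, mgs_end, dur)
    primary_off = cue + srt + dur

    n_corr = int(rng.choice(len(cfg.corrective_probs), p=cfg.corrective_probs))
    cur = mgs_end.copy()
    t_next = primary_off + cfg.corrective_latency_ms
    executed = 0
    for _ in range(n_corr):
        step = cfg.corrective_gain * (anchor - cur)
        a = float(np.linalg.norm(step))
        d = main_sequence_duration_ms(a, cfg.ms_slope, cfg.ms_intercept)
        if t_next + d > feedback - 110.0:
            break  # too late to land before the final-eye-position window
        _add_movement(pos, t, t_next, step, d)
        cur = cur + step
        t_next += d + cfg.corrective_latency_ms
        executed += 1

    if planted == "fixation_break":
        theta = rng.uniform(0, 2 * np.pi)
        out = 3.2 * np.array([math.cos(theta), math.sin(theta)])
        t_mid = target_onset + cfg.flash_ms + delay_ms / 2.0
        d_out = main_sequence_duration_ms(3.2, cfg.ms_slope, cfg.ms_intercept)
        _add_movement(pos, t, t_mid, out, d_out)
        _add_movement(pos, t, t_mid + d_out + 150.0, -out, d_out)

    pos += _band_limited_noise(rng, len(t), cfg.fixation_noise_sd,
                               cfg.noise_smooth_ms)

    events = TrialEvents(target_x=tx, target_y=ty, target_onset_ms=target_onset,
                         cue_ms=cue, feedback_ms=feedback, delay_s=delay_s)
    trace = GazeTrace(time_ms=t, x=pos[:, 0], y=pos[:, 1], events=events,
                      trial_id=trial_id, condition=condition, subject=subject)
    truth = TrialTruth(
        trial_id=trial_id, condition=condition, subject=subject,
        target_x=tx, target_y=ty, delay_s=delay_s, srt_ms=srt,
        mgs_x=float(mgs_end[0]), mgs_y=float(mgs_end[1]),
        mgs_error=float(np.linalg.norm(e_mgs)),
        fep_x=float(cur[0]), fep_y=float(cur[1]),
        fep_error=float(np.linalg.norm(cur - np.array([tx, ty]))),
        n_correctives=executed, planted_reason=planted)
    return trace, truth


def simulate_saccade_sequence(n_saccades: int, amp_range: tuple[float, float] = (2.0, 12.0),
                              gap_ms: float = 400.0, noise_sd: float = 0.1,
                              noise_smooth_ms: int = 20,
                              rng=None) -> tuple[GazeTrace, np.ndarray, np.ndarray]:
    """A long fixation trace with planted saccades at known onsets.

    Saccades have amplitudes uniform in ``amp_range``, random directions
    (bounded so gaze stays within +/-15 deg), main-sequence durations and
    raised-cosine velocity profiles, separated by ``gap_ms`` of fixation.
    Returns the trace plus ground-truth onset times and amplitudes — the
    benchmark input for velocity-threshold detector validation.
    """
    rng = _rng(0 if rng is None else rng)
    t_total = int(n_saccades * gap_ms + 200)
    t = np.arange(float(t_total))
    pos = np.zeros((t_total, 2))
    cur = np.zeros(2)
    onsets = np.empty(n_saccades)
    amps = np.empty(n_saccades)
    for k in range(n_saccades):
        onset = 200.0 + k * gap_ms
        amp = rng.uniform(*amp_range)
        theta = rng.uniform(0, 2 * np.pi)
        step = amp * np.array([math.cos(theta), math.sin(theta)])
        if np.linalg.norm(cur + step) > 15.0:
            step = -amp * cur / np.linalg.norm(cur)
        _add_movement(pos, t, onset, step, main_sequence_duration_ms(amp))
        cur = cur + step
        onsets[k] = onset
        amps[k] = amp
    pos += _band_limited_noise(rng, t_total, noise_sd, noise_smooth_ms)
    return GazeTrace(time_ms=t, x=pos[:, 0], y=pos[:, 1]), onsets, amps


# ---------------------------------------------------------------------------
# cohort simulation

@dataclass
class CohortSpec:
    """Multi-subject experiment design with planted stimulation effects.

    ``effects`` maps (site, laterality, metric) — e.g. ``("sPCS",
    "contra", "mgs")`` — to an endpoint-noise inflation factor (>= 1 for a
    planted impairment, 1 for null).
    """

    n_subjects: int = 9
    n_runs: int = 10
    trials_per_run: int = 30
    delays: tuple[float, ...] = (3.0, 3.5, 4.0, 4.5, 5.0)
    target_ecc: float = 10.0
    sites: tuple[str, ...] = ("PFC", "sPCS", "IPS2")
    site_hemispheres: dict[str, str] = field(
        default_factory=lambda: dict(SITE_HEMISPHERES))
    effects: dict[tuple[str, str, str], float] = field(default_factory=dict)
    exclusion_rate: float = 0.05
    saccade: SaccadeSimConfig = field(default_factory=SaccadeSimConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for key, v in self.effects.items():
            if v < 1:
                raise ValueError(f"inflation factor for {key} must be >= 1")

    def participation(self) -> dict[str, list[str]]:
        """Sites per subject.  The nine-subject design reproduces the
        study pattern: seven subjects complete all three TMS conditions,
        one completes only sPCS, one completes PFC and IPS2 (eight
        subjects per condition)."""
        subjects = [f"s{i:02d}" for i in range(self.n_subjects)]
        out = {}
        for i, s in enumerate(subjects):
            if self.n_subjects == 9 and set(self.sites) == {"PFC", "sPCS", "IPS2"}:
                if i == 7:
                    out[s] = ["sPCS"]
                elif i == 8:
                    out[s] = ["PFC", "IPS2"]
                else:
                    out[s] = list(self.sites)
            else:
                out[s] = list(self.sites)
        return out


def _sample_target(rng: np.random.Generator, ecc: float, margin: float) -> tuple[float, float]:
    """Uniform off-cardinal target at fixed eccentricity."""
    quadrant = rng.integers(4)
    ang = rng.uniform(margin + 1.0, 89.0 - margin) + 90.0 * quadrant
    a = math.radians(ang)
    return ecc * math.cos(a), ecc * math.sin(a)


def _trial_inflations(spec: CohortSpec, condition: str,
                      target_x: float) -> tuple[float, float]:
    if condition == "noTMS":
        return 1.0, 1.0
    hemifield = "R" if target_x > 0 else "L"
    lat = "ipsi" if hemifield == spec.site_hemispheres[condition] else "contra"
    return (spec.effects.get((condition, lat, "mgs"), 1.0),
            spec.effects.get((condition, lat, "fep"), 1.0))


def simulate_cohort(spec: CohortSpec, rng=None
                    ) -> tuple[list[GazeTrace], pd.DataFrame]:
    """Simulate full gaze traces for a cohort; returns traces + truth table."""
    rng = _rng(spec.seed if rng is None else rng)
    margin = spec.saccade.cardinal_margin_deg
    traces: list[GazeTrace] = []
    truths: list[TrialTruth] = []
    for subject, sites in spec.participation().items():
        for condition in ["noTMS"] + sites:
            for run in range(spec.n_runs):
                for i in range(spec.trials_per_run):
                    tx, ty = _sample_target(rng, spec.target_ecc, margin)
                    mgs_inf, fep_inf = _trial_inflations(spec, condition, tx)
                    planted = None
                    if rng.uniform() < spec.exclusion_rate:
                        planted = str(rng.choice(
                            ["rt_long", "rt_short", "fixation_break"]))
                    delay = float(rng.choice(spec.delays))
                    tid = f"{subject}-{condition}-r{run}-t{i}"
                    trace, truth = simulate_trial(
                        spec.saccade, (tx, ty), condition=condition,
                        mgs_inflation=mgs_inf, fep_inflation=fep_inf,
                        planted=planted, delay_s=delay, trial_id=tid,
                        subject=subject, rng=rng)
                    trace.run = run
                    traces.append(trace)
                    truths.append(truth)
    return traces, pd.DataFrame([vars(tr) for tr in truths])


def simulate_cohort_scores(spec: CohortSpec, rng=None) -> pd.DataFrame:
    """Score-level cohort fast path: sample per-trial errors directly.

    Draws MGS and FEP errors from the same endpoint-noise model as the
    trace generator (norm of a bivariate normal, SD scaled by the planted
    inflation) without synthesizing gaze traces: the MGS endpoint is
    target + e_mgs, corrective saccades (count drawn from
    ``corrective_probs``) move gaze toward an independent memory anchor
    target + e_fep by the corrective gain, and the FEP error is the
    distance of the resulting final position from the target (equal to the
    MGS error when no corrective occurs).  Returns an included-trials
    table ready for the stats stage.
    """
    rng = _rng(spec.seed if rng is None else rng)
    sac = spec.saccade
    rows = []
    for subject, sites in spec.participation().items():
        for condition in ["noTMS"] + sites:
            n = spec.n_runs * spec.trials_per_run
            ang = (rng.uniform(sac.cardinal_margin_deg + 1.0,
                               89.0 - sac.cardinal_margin_deg, n)
                   + 90.0 * rng.integers(0, 4, n))
            tx = spec.target_ecc * np.cos(np.radians(ang))
            ty = spec.target_ecc * np.sin(np.radians(ang))
            mgs_inf = np.empty(n)
            fep_inf = np.empty(n)
            for i in range(n):
                mgs_inf[i], fep_inf[i] = _trial_inflations(spec, condition, tx[i])
            e_mgs = rng.normal(0.0, 1.0, (n, 2)) * (sac.mgs_noise_sd * mgs_inf)[:, None]
            e_fep = rng.normal(0.0, 1.0, (n, 2)) * (sac.fep_noise_sd * fep_inf)[:, None]
            k = rng.choice(len(sac.corrective_probs), size=n,
                           p=sac.corrective_probs)
            shrink = (1.0 - sac.corrective_gain) ** k
            final = e_fep + shrink[:, None] * (e_mgs - e_fep)
            mgs_err = np.linalg.norm(e_mgs, axis=1)
            fep_err = np.linalg.norm(final, axis=1)
            srt = sac.srt_shift_ms + rng.gamma(sac.srt_shape, sac.srt_scale, n)
            delays = rng.choice(spec.delays, n)
            for i in range(n):
                rows.append({
                    "subject": subject, "condition": condition,
                    "target_x": tx[i], "target_y": ty[i],
                    "delay_s": delays[i], "mgs_error": mgs_err[i],
                    "fep_error": fep_err[i], "srt_ms": srt[i],
                    "excluded": False, "reason": None})
    return pd.DataFrame(rows)
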