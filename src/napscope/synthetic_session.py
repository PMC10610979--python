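"""Synthetic nap-session and study generator with known ground truth.

Real recordings for this kind of study are nap videos of roughly 7-8
minutes; no public data exist, so every downstream module is exercised
against simulated sessions instead. A session is driven by a per-angle
*event schedule*: each joint angle holds a stable level, jumps at discrete
repositioning events (a Poisson-like process thinned to keep every dwell
detectable), and is observed with additive Gaussian measurement noise in
angle space. Two rendering paths exist:

* the **fast path** (:func:`generate_angle_series`) turns schedules
  directly into 12 independent :class:`~napscope.movement_indices.AngleSeries`
  — the workhorse for statistical suites;
* the **geometric path** (:func:`generate_session`) places the 12
  landmarks of a canonical supine skeleton so that the shoulder, elbow,
  hip and knee triplets realize their scheduled angles exactly (terminal
  point rotated about the vertex, proximal joints placed before distal
  ones). Wrist and ankle angles are then emergent — their triplets close
  against already-placed landmarks — and are recorded in the noise-free
  ground-truth table rather than scheduled.

A *study* is n_subjects x 3 conditions (negative / neutral / positive)
of such sessions, with optional condition effects (multipliers on event
rate and shift magnitude) and a negative coupling between body weight and
event rate, emulating heavier sleepers repositioning less often.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ConfigError
from .movement_indices import AngleSeries, DEFAULT_FPS
from .nonparametric_stats import CONDITIONS, StudyTable
from .pose_topology import ANGLE_ORDER, Landmark, PoseFrame

__all__ = [
    "SimConfig",
    "StudyConfig",
    "EventSchedule",
    "SessionData",
    "StudyData",
    "CONTROLLED_ANGLES",
    "generate_schedule",
    "generate_angle_series",
    "generate_session",
    "generate_study",
    "place_frame",
    "study_table_from_indices",
]

#: Angles the geometric renderer can realize exactly (vertex rotation with a
#: free terminal point); wrist/ankle angles are emergent from these.
CONTROLLED_ANGLES: tuple[Landmark, ...] = (
    Landmark.SHR, Landmark.SHL, Landmark.ELR, Landmark.ELL,
    Landmark.HR, Landmark.HL, Landmark.KR, Landmark.KL,
)


@dataclass(frozen=True)
class SimConfig:
    """One session's generative parameters.

    ``duration_s=None`` samples the nap length from N(460 s, 50 s)
    truncated above 60 s, matching the durations such naps actually span;
    ``events_per_angle`` is the Poisson mean of repositioning events per
    angle (``events_fixed`` pins the count instead); level shifts are
    uniform in [min_shift_deg, max_shift_deg] and dwells are thinned to at
    least ``min_dwell_s`` so every scheduled event is in principle
    detectable.
    """

    seed: int
    duration_s: float | None = None
    fps: float = DEFAULT_FPS
    noise_sigma_deg: float = 1.0
    events_per_angle: float = 5.0
    events_fixed: int | None = None
    level_range: tuple[float, float] = (20.0, 160.0)
    min_shift_deg: float = 20.0
    max_shift_deg: float = 60.0
    min_dwell_s: float = 4.0
    gap_rate_per_s: float = 0.0
    gap_mean_s: float = 1.0
    width_px: int = 640
    height_px: int = 480

    def __post_init__(self):
        if self.fps <= 0:
            raise ConfigError("fps must be positive")
        if self.duration_s is not None and self.duration_s <= 0:
            raise ConfigError("duration_s must be positive")
        if self.noise_sigma_deg < 0:
            raise ConfigError("noise_sigma_deg must be non-negative")
        lo, hi = self.level_range
        if not (0.0 <= lo < hi <= 180.0):
            raise ConfigError(f"level_range must be an interval within [0, 180], got {self.level_range}")
        if not (0.0 < self.min_shift_deg <= self.max_shift_deg):
            raise ConfigError("need 0 < min_shift_deg <= max_shift_deg")
        if self.max_shift_deg > hi - lo:
            raise ConfigError("max_shift_deg exceeds the level range width")
        if self.min_dwell_s <= 0:
            raise ConfigError("min_dwell_s must be positive")
        if self.gap_rate_per_s < 0 or self.gap_mean_s <= 0:
            raise ConfigError("invalid occlusion model")
        if self.width_px <= 0 or self.height_px <= 0:
            raise ConfigError("frame dimensions must be positive")


@dataclass
class EventSchedule:
    """Ground-truth schedule: initial level + (time, new level) events per angle."""

    duration_s: float
    initial_level_deg: dict[Landmark, float]
    events: dict[Landmark, list[tuple[float, float]]]

    def angles(self) -> list[Landmark]:
        return list(self.initial_level_deg)

    def levels_at(self, angle: Landmark, times: np.ndarray) -> np.ndarray:
        """Noise-free step-function values at the given times."""
        evts = self.events[angle]
        breaks = np.array([t for t, _ in evts])
        levels = np.array([self.initial_level_deg[angle]] + [lv for _, lv in evts])
        idx = np.searchsorted(breaks, times, side="right")
        return levels[idx]

    def n_events(self, angle: Landmark) -> int:
        return len(self.events[angle])

    def dwell_times(self, angle: Landmark) -> np.ndarray:
        """Durations of the stable periods, including first and last."""
        ts = [0.0] + [t for t, _ in self.events[angle]] + [self.duration_s]
        return np.diff(np.array(ts))

    def truth_indices(self, angle: Landmark) -> dict:
        """The movement indices implied by the schedule (noise-free)."""
        levels = np.array(
            [self.initial_level_deg[angle]] + [lv for _, lv in self.events[angle]]
        )
        dwells = self.dwell_times(angle)
        return {
            "angle": angle.value,
            "n_changes": len(levels) - 1,
            "max_change_deg": float(levels.max() - levels.min()),
            "max_event_change_deg": float(np.max(np.abs(np.diff(levels)))) if levels.size > 1 else 0.0,
            "max_stable_s": float(dwells.max()),
            "min_stable_s": float(dwells.min()),
            "duration_s": self.duration_s,
        }


def _sample_duration(config: SimConfig, rng: np.random.Generator) -> float:
    if config.duration_s is not None:
        return float(config.duration_s)
    while True:  # truncated N(460, 50), > 60 s
        d = rng.normal(460.0, 50.0)
        if d > 60.0:
            return float(d)


def _event_times(
    n: int, duration: float, min_dwell: float, rng: np.random.Generator
) -> np.ndarray:
    """n event times in (0, duration) with all dwells >= min_dwell."""
    if n == 0:
        return np.empty(0)
    slack = duration - (n + 1) * min_dwell
    if slack < 0:
        raise ConfigError(
            f"{n} events with min dwell {min_dwell}s do not fit in {duration:.1f}s"
        )
    u = np.sort(rng.uniform(0.0, slack, size=n))
    return u + min_dwell * np.arange(1, n + 1)


def _level_walk(
    n_levels: int,
    config: SimConfig,
    rng: np.random.Generator,
    magnitude_multiplier: float = 1.0,
) -> np.ndarray:
    lo, hi = config.level_range
    levels = [rng.uniform(lo, hi)]
    for _ in range(n_levels - 1):
        mag = rng.uniform(config.min_shift_deg, config.max_shift_deg) * magnitude_multiplier
        up_ok = levels[-1] + mag <= hi
        down_ok = levels[-1] - mag >= lo
        if up_ok and down_ok:
            sign = 1.0 if rng.random() < 0.5 else -1.0
        elif up_ok:
            sign = 1.0
        elif down_ok:
            sign = -1.0
        else:  # magnitude wider than remaining room on both sides: jump across
            sign = 1.0 if levels[-1] < (lo + hi) / 2 else -1.0
            mag = (hi - levels[-1]) if sign > 0 else (levels[-1] - lo)
        levels.append(levels[-1] + sign * mag)
    return np.array(levels)


def generate_schedule(
    config: SimConfig,
    rng: np.random.Generator | None = None,
    angles: Iterable[Landmark] = ANGLE_ORDER,
    duration_s: float | None = None,
    events_mean: float | None = None,
    magnitude_multiplier: float = 1.0,
) -> EventSchedule:
    """Draw one session's ground-truth event schedule.

    Event counts are Poisson(``events_mean``) per angle (or the fixed
    count), capped at what the minimum dwell allows; event times keep
    every dwell at least ``min_dwell_s`` long.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    duration = duration_s if duration_s is not None else _sample_duration(config, rng)
    mean = config.events_per_angle if events_mean is None else events_mean
    n_max = int(duration / config.min_dwell_s) - 1
    initial, events = {}, {}
    for angle in angles:
        if config.events_fixed is not None:
            n = config.events_fixed
        else:
            n = int(rng.poisson(mean))
        n = max(0, min(n, n_max))
        times = _event_times(n, duration, config.min_dwell_s, rng)
        levels = _level_walk(n + 1, config, rng, magnitude_multiplier)
        initial[angle] = float(levels[0])
        events[angle] = [(float(t), float(lv)) for t, lv in zip(times, levels[1:])]
    return EventSchedule(duration_s=duration, initial_level_deg=initial, events=events)


def generate_angle_series(
    config: SimConfig,
    schedule: EventSchedule | None = None,
    angles: Iterable[Landmark] = ANGLE_ORDER,
) -> tuple[dict[Landmark, AngleSeries], EventSchedule]:
    """Fast path: schedules -> noisy angle series for all requested angles.

    Noise is i.i.d. Gaussian in angle space (``noise_sigma_deg``), clipped
    to [0, 180]; no landmark geometry is involved.
    """
    rng = np.random.default_rng(config.seed)
    if schedule is None:
        schedule = generate_schedule(config, rng, angles=tuple(angles))
    n_frames = int(round(schedule.duration_s * config.fps))
    times = np.arange(n_frames) / config.fps
    series = {}
    for angle in schedule.angles():
        clean = schedule.levels_at(angle, times)
        noisy = clean + rng.normal(0.0, config.noise_sigma_deg, size=n_frames) \
            if config.noise_sigma_deg > 0 else clean.copy()
        np.clip(noisy, 0.0, 180.0, out=noisy)
        series[angle] = AngleSeries(angle=angle, times_s=times, values_deg=noisy, fps=config.fps)
    return series, schedule


# ---------------------------------------------------------------------------
# Geometric rendering

# Canonical supine skeleton, body axis along x, in frame-width/height units.
_TORSO = {
    Landmark.SHR: (0.32, 0.45),
    Landmark.SHL: (0.32, 0.55),
    Landmark.HR: (0.52, 0.455),
    Landmark.HL: (0.52, 0.545),
}
_LEN_UPPER_ARM = 0.10   # of frame width
_LEN_FOREARM = 0.085
_LEN_THIGH = 0.13
_LEN_SHANK = 0.11


def _rotate(ux: float, uy: float, deg: float) -> tuple[float, float]:
    a = math.radians(deg)
    c, s = math.cos(a), math.sin(a)
    return (c * ux - s * uy, s * ux + c * uy)


def place_frame(
    angles_deg: dict[Landmark, float], width_px: int, height_px: int
) -> dict[Landmark, tuple[float, float]]:
    """Place all 12 landmarks (normalized coords) realizing the given
    shoulder/elbow/hip/knee angles exactly.

    ``angles_deg`` maps each of :data:`CONTROLLED_ANGLES` to its target
    joint angle in [0, 180]. Placement happens in pixel space (so the
    realized pixel-space angles equal the targets regardless of aspect
    ratio) and is normalized at the end.
    """
    for a in CONTROLLED_ANGLES:
        th = angles_deg.get(a)
        if th is None or not (0.0 <= th <= 180.0):
            raise ConfigError(f"angle {a.value} missing or outside [0, 180]: {th!r}")
    w, h = float(width_px), float(height_px)
    px: dict[Landmark, tuple[float, float]] = {
        lm: (x * w, y * h) for lm, (x, y) in _TORSO.items()
    }

    for side, sign in (("R", -1.0), ("L", 1.0)):
        sh = px[Landmark.parse("SH" + side)]
        hip = px[Landmark.parse("H" + side)]
        # hip: A=shoulder, B=hip, C=knee
        ux, uy = hip[0] - sh[0], hip[1] - sh[1]
        norm = math.hypot(ux, uy)
        ux, uy = ux / norm, uy / norm
        kx, ky = _rotate(ux, uy, sign * angles_deg[Landmark.parse("H" + side)])
        knee = (hip[0] + _LEN_THIGH * w * kx, hip[1] + _LEN_THIGH * w * ky)
        px[Landmark.parse("K" + side)] = knee
        # knee: A=hip, B=knee, C=ankle
        ux, uy = knee[0] - hip[0], knee[1] - hip[1]
        norm = math.hypot(ux, uy)
        ux, uy = ux / norm, uy / norm
        ax, ay = _rotate(ux, uy, sign * angles_deg[Landmark.parse("K" + side)])
        px[Landmark.parse("AN" + side)] = (
            knee[0] + _LEN_SHANK * w * ax, knee[1] + _LEN_SHANK * w * ay
        )
        # shoulder: A=hip, B=shoulder, C=elbow
        ux, uy = sh[0] - hip[0], sh[1] - hip[1]
        norm = math.hypot(ux, uy)
        ux, uy = ux / norm, uy / norm
        ex, ey = _rotate(ux, uy, sign * angles_deg[Landmark.parse("SH" + side)])
        elbow = (sh[0] + _LEN_UPPER_ARM * w * ex, sh[1] + _LEN_UPPER_ARM * w * ey)
        px[Landmark.parse("EL" + side)] = elbow
        # elbow: A=shoulder, B=elbow, C=wrist
        ux, uy = elbow[0] - sh[0], elbow[1] - sh[1]
        norm = math.hypot(ux, uy)
        ux, uy = ux / norm, uy / norm
        wx, wy = _rotate(ux, uy, sign * angles_deg[Landmark.parse("EL" + side)])
        px[Landmark.parse("W" + side)] = (
            elbow[0] + _LEN_FOREARM * w * wx, elbow[1] + _LEN_FOREARM * w * wy
        )

    out = {}
    for lm, (x, y) in px.items():
        xn, yn = x / w, y / h
        if not (0.0 <= xn <= 1.0 and 0.0 <= yn <= 1.0):
            raise ConfigError(
                f"landmark {lm.value} left the frame ({xn:.3f}, {yn:.3f}); "
                "frame too narrow for the canonical skeleton"
            )
        out[lm] = (xn, yn)
    return out


@dataclass
class SessionData:
    """A rendered session: landmark frames + schedule + noise-free truth."""

    frames: list[PoseFrame]
    schedule: EventSchedule
    truth: pd.DataFrame  # time_s + one noise-free column per angle (all 12)
    config: SimConfig


def _occlusion_mask(
    config: SimConfig, n_frames: int, duration: float, rng: np.random.Generator
) -> dict[Landmark, np.ndarray]:
    """Boolean per-frame visibility mask per landmark (True = visible)."""
    times = np.arange(n_frames) / config.fps
    masks = {}
    for lm in Landmark:
        mask = np.ones(n_frames, dtype=bool)
        if config.gap_rate_per_s > 0:
            n_gaps = rng.poisson(config.gap_rate_per_s * duration)
            for _ in range(n_gaps):
                start = rng.uniform(0.0, duration)
                length = rng.exponential(config.gap_mean_s)
                mask &= ~((times >= start) & (times < start + length))
        masks[lm] = mask
    return masks


def generate_session(config: SimConfig, schedule: EventSchedule | None = None) -> SessionData:
    """Render a full landmark stream for one session.

    Deterministic given the seed. With zero noise and no occlusion,
    re-measuring the controlled angles from the emitted frames reproduces
    the schedule at every frame (round-trip identity); the truth table
    additionally records the emergent wrist/ankle angles. An externally
    generated ``schedule`` (e.g. a study session's ground truth) may be
    supplied; only its controlled-angle entries are rendered.
    """
    from .angle_engine import frame_angles  # local import to avoid cycle

    rng = np.random.default_rng(config.seed)
    if schedule is None:
        schedule = generate_schedule(config, rng, angles=CONTROLLED_ANGLES)
    else:
        missing = [a.value for a in CONTROLLED_ANGLES if a not in schedule.initial_level_deg]
        if missing:
            raise ConfigError(f"supplied schedule lacks controlled angles: {missing}")
    n_frames = int(round(schedule.duration_s * config.fps))
    times = np.arange(n_frames) / config.fps

    clean = {a: schedule.levels_at(a, times) for a in CONTROLLED_ANGLES}
    if config.noise_sigma_deg > 0:
        noisy = {
            a: np.clip(v + rng.normal(0.0, config.noise_sigma_deg, n_frames), 0.0, 180.0)
            for a, v in clean.items()
        }
    else:
        noisy = clean
    masks = _occlusion_mask(config, n_frames, schedule.duration_s, rng)

    frames: list[PoseFrame] = []
    truth_rows = np.empty((n_frames, len(ANGLE_ORDER)))
    for i in range(n_frames):
        pts = place_frame(
            {a: float(noisy[a][i]) for a in CONTROLLED_ANGLES},
            config.width_px, config.height_px,
        )
        visible = {lm: xy for lm, xy in pts.items() if masks[lm][i]}
        frames.append(
            PoseFrame(
                frame_index=i,
                time_s=float(times[i]),
                width_px=config.width_px,
                height_px=config.height_px,
                points=visible,
                visibility={lm: 1.0 for lm in visible},
            )
        )
        # noise-free truth for all 12 angles (controlled = schedule; emergent
        # measured from a noise-free placement)
        clean_pts = place_frame(
            {a: float(clean[a][i]) for a in CONTROLLED_ANGLES},
            config.width_px, config.height_px,
        )
        clean_frame = PoseFrame(
            frame_index=i, time_s=float(times[i]),
            width_px=config.width_px, height_px=config.height_px,
            points=clean_pts,
        )
        for j, s in enumerate(frame_angles(clean_frame)):
            truth_rows[i, j] = s.theta_deg if s.theta_deg is not None else np.nan

    truth = pd.DataFrame(truth_rows, columns=[a.value for a in ANGLE_ORDER])
    truth.insert(0, "time_s", times)
    return SessionData(frames=frames, schedule=schedule, truth=truth, config=config)


# ---------------------------------------------------------------------------
# Studies

@dataclass(frozen=True)
class StudyConfig:
    """A subjects x conditions study of simulated nap sessions.

    ``event_rate_multipliers`` / ``magnitude_multipliers`` scale the event
    mean and shift magnitude per condition (optionally restricted to
    ``affected_angles``); all multipliers 1 with coupling 0 gives an
    exchangeable null study. ``weight_event_coupling`` is the elasticity
    of the event rate in the body-weight z-score (negative = heavier
    subjects move less).
    """

    seed: int
    n_subjects: int = 10
    conditions: tuple[str, ...] = CONDITIONS
    event_rate_multipliers: dict[str, float] = field(default_factory=dict)
    magnitude_multipliers: dict[str, float] = field(default_factory=dict)
    affected_angles: tuple[str, ...] | None = None
    weight_mean_kg: float = 75.0
    weight_sd_kg: float = 12.0
    weight_event_coupling: float = 0.0
    session: SimConfig = field(default_factory=lambda: SimConfig(seed=0))

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ConfigError("need at least 2 subjects")
        for d in (self.event_rate_multipliers, self.magnitude_multipliers):
            for c, m in d.items():
                if c not in self.conditions:
                    raise ConfigError(f"multiplier for unknown condition {c!r}")
                if m <= 0:
                    raise ConfigError(f"multipliers must be positive, got {c}={m}")
        if self.affected_angles is not None:
            for a in self.affected_angles:
                Landmark.parse(a)


@dataclass
class StudyData:
    """Generated study: design table, per-session schedules, truth indices."""

    config: StudyConfig
    design: pd.DataFrame  # subject, condition, body_weight_kg, session_seed, duration_s
    schedules: dict[tuple[str, str], EventSchedule]
    truth_indices: pd.DataFrame  # subject, condition, + index columns per angle row

    def session_config(self, subject: str, condition: str) -> SimConfig:
        row = self.design[
            (self.design["subject"] == subject) & (self.design["condition"] == condition)
        ].iloc[0]
        return replace(
            self.config.session,
            seed=int(row["session_seed"]),
            duration_s=float(row["duration_s"]),
        )

    def angle_series(self, subject: str, condition: str) -> dict[Landmark, AngleSeries]:
        """Render one session's noisy angle series (fast path)."""
        cfg = self.session_config(subject, condition)
        series, _ = generate_angle_series(cfg, schedule=self.schedules[(subject, condition)])
        return series


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def generate_study(config: StudyConfig) -> StudyData:
    """Generate a full study: one session per subject x condition.

    Per-session event means are ``events_per_angle x rate_mult(condition)
    x exp(coupling x weight z-score)``; magnitudes are scaled by the
    condition's magnitude multiplier (restricted to ``affected_angles``
    when set). Deterministic given the study seed.
    """
    root = np.random.SeedSequence(config.seed)
    ss_design, ss_sessions = root.spawn(2)
    rng = np.random.default_rng(ss_design)

    subjects = [f"S{i + 1:02d}" for i in range(config.n_subjects)]
    weights = np.maximum(rng.normal(config.weight_mean_kg, config.weight_sd_kg, config.n_subjects), 40.0)
    z = (weights - config.weight_mean_kg) / config.weight_sd_kg

    session_ss = ss_sessions.spawn(config.n_subjects * len(config.conditions))
    design_rows, schedules, truth_rows = [], {}, []
    affected = (
        None if config.affected_angles is None
        else {Landmark.parse(a) for a in config.affected_angles}
    )
    k = 0
    for si, subject in enumerate(subjects):
        for condition in config.conditions:
            seed = _child_seed(session_ss[k]); k += 1
            srng = np.random.default_rng(seed)
            cfg = replace(config.session, seed=seed)
            duration = _sample_duration(cfg, srng)
            rate_mult = config.event_rate_multipliers.get(condition, 1.0)
            mag_mult = config.magnitude_multipliers.get(condition, 1.0)
            coupling = math.exp(config.weight_event_coupling * z[si])
            base_mean = cfg.events_per_angle * coupling

            # per-angle schedule: multipliers restricted to affected angles
            initial, events = {}, {}
            for angle in ANGLE_ORDER:
                hit = affected is None or angle in affected
                mean = base_mean * (rate_mult if hit else 1.0)
                mag = mag_mult if hit else 1.0
                sub = generate_schedule(
                    cfg, srng, angles=(angle,), duration_s=duration,
                    events_mean=mean, magnitude_multiplier=mag,
                )
                initial[angle] = sub.initial_level_deg[angle]
                events[angle] = sub.events[angle]
            sched = EventSchedule(duration_s=duration, initial_level_deg=initial, events=events)
            schedules[(subject, condition)] = sched
            design_rows.append(
                {
                    "subject": subject, "condition": condition,
                    "body_weight_kg": float(weights[si]),
                    "session_seed": seed, "duration_s": duration,
                }
            )
            for angle in ANGLE_ORDER:
                row = sched.truth_indices(angle)
                row.update({"subject": subject, "condition": condition})
                truth_rows.append(row)

    design = pd.DataFrame(design_rows)
    truth = pd.DataFrame(truth_rows)[
        ["subject", "condition", "angle", "n_changes", "max_change_deg",
         "max_event_change_deg", "max_stable_s", "min_stable_s", "duration_s"]
    ]
    return StudyData(config=config, design=design, schedules=schedules, truth_indices=truth)


def study_table_from_indices(
    indices: pd.DataFrame, design: pd.DataFrame, index_names: Iterable[str] | None = None
) -> StudyTable:
    """Reshape an indices table (one row per subject x condition x angle)
    into the long :class:`StudyTable` consumed by the analysis."""
    id_cols = ["subject", "condition", "angle"]
    if index_names is None:
        index_names = [
            c for c in indices.columns
            if c not in id_cols + ["flag", "duration_s"]
        ]
    long = indices.melt(
        id_vars=id_cols, value_vars=list(index_names),
        var_name="index", value_name="value",
    )
    weights = {}
    if "body_weight_kg" in design.columns:
        weights = (
            design.drop_duplicates("subject").set_index("subject")["body_weight_kg"].to_dict()
        )
    return StudyTable(data=long, body_weight=weights)
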