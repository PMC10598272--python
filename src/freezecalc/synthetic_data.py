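"""Synthetic VR fear-conditioning sessions with ground truth.

Emulates the recordings the downstream analyses consume: a head-fixed mouse
traversing a 200 cm virtual track at 15.49 Hz for ~322 s per session, with
context/day-dependent freezing, 1.5 s teleport pauses between traversals,
post-shock sprinting, freeze-tuned axonal calcium transients recorded on a
green activity channel alongside a structural red channel, and pupil traces
contaminated by blinks.

Behavior is a two-state semi-Markov process: running bouts end with a
constant per-second hazard of freezing, and freeze-epoch lengths are drawn
from a gamma law (floored at the 12-frame detectability limit).  Ground
truth (epoch labels, transient times, latent firing drive) is returned so
recovery can be tested exactly.

The calcium model: during a freezing epoch the latent transient rate
follows a 5-level "bow" profile over freeze progress (rapid ramp, plateau,
fall); elsewhere it sits at a low baseline.  Transients are Bernoulli
events convolved with a single-exponential indicator kernel (GCaMP6s-like,
tau = 1 s).  A shared low-pass motion artifact enters both channels of every
ROI, which makes the red channel a valid regressor for artifact removal by
construction; one axon is split across several correlated ROI segments and
extra ROIs carry noise only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .behavior_features import (
    MIN_FREEZE_FRAMES,
    EpochTable,
    SessionTimeseries,
    epochs_from_labels,
)
from .exceptions import AlignmentError, ConfigError

DAYS = ("pre", "d1", "d2", "d3")
CONTEXTS = ("shocked", "control")


@dataclass
class GeneratorConfig:
    """Knobs of the session generator; defaults mirror the study paradigm."""

    frame_rate_hz: float = 15.49
    session_len_s: float = 322.0
    track_len_cm: float = 200.0
    freeze_hazard_per_s: float = 0.025
    freeze_len_mean_s: float = 2.0
    freeze_len_shape: float = 2.0
    run_speed_mean_cms: float = 20.0
    run_speed_sd_cms: float = 4.0
    teleport_pause_s: float = 1.5
    n_shocks: int = 0
    shock_gap_s: tuple[float, float] = (20.0, 26.0)
    shock_sprint_s: float = 2.0
    shock_sprint_gain: float = 3.0
    tuning_amp: float = 0.0  # transient rate (events/s) at bow peak during freezes
    baseline_rate_per_s: float = 0.05
    bow_profile: tuple[float, ...] = (0.2, 1.0, 1.0, 1.0, 0.6)
    transient_amp: float = 1.0
    indicator_tau_s: float = 1.0
    motion_amp: float = 0.05
    noise_sd: float = 0.02
    n_axon_segments: int = 3
    n_noise_rois: int = 2
    inhibition_factor: float = 1.0
    blink_rate_per_s: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        positive = (
            "frame_rate_hz",
            "session_len_s",
            "track_len_cm",
            "freeze_len_mean_s",
            "freeze_len_shape",
            "run_speed_mean_cms",
            "teleport_pause_s",
            "indicator_tau_s",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive")
        nonneg = (
            "freeze_hazard_per_s",
            "tuning_amp",
            "baseline_rate_per_s",
            "motion_amp",
            "noise_sd",
            "blink_rate_per_s",
            "n_shocks",
        )
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if len(self.bow_profile) != 5:
            raise ConfigError("bow_profile must have exactly 5 levels")
        if self.inhibition_factor < 1:
            raise ConfigError("inhibition_factor must be >= 1")
        if self.n_axon_segments < 1:
            raise ConfigError("need at least one axon segment")

    @property
    def n_frames(self) -> int:
        return int(round(self.session_len_s * self.frame_rate_hz))

    def with_freeze_occupancy(self, occupancy: float, mean_len_s: float | None = None) -> "GeneratorConfig":
        """Config whose expected freeze occupancy (of non-teleport time) is ``occupancy``.

        In the two-state renewal model the long-run freeze fraction is
        L / (L + 1/h) for mean epoch length L and hazard h, so
        h = occupancy / ((1 - occupancy) * L).
        """
        if not 0 < occupancy < 1:
            raise ConfigError("occupancy must be in (0, 1)")
        mean_len = self.freeze_len_mean_s if mean_len_s is None else mean_len_s
        hazard = occupancy / ((1.0 - occupancy) * mean_len * self.inhibition_factor)
        return replace(self, freeze_hazard_per_s=hazard, freeze_len_mean_s=mean_len)


@dataclass
class GroundTruth:
    """Generator-side truth for recovery tests."""

    true_epochs: EpochTable
    freeze_mask: np.ndarray
    true_transient_frames: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    true_tuning_state: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class RoiTraceSet:
    """Per-ROI two-channel fluorescence (green activity, red structural)."""

    roi_ids: list[str]
    green: np.ndarray  # (n_rois, n_frames)
    red: np.ndarray
    frame_rate_hz: float

    def validate(self) -> None:
        if self.green.shape != self.red.shape or self.green.shape[0] != len(self.roi_ids):
            raise AlignmentError("green/red/roi_ids shapes disagree")
        if len(self.roi_ids) < 1:
            raise ConfigError("need at least one ROI")


@dataclass
class PupilTraces:
    """FaceMap-style pupil outputs on the imaging frame clock."""

    area: np.ndarray
    x: np.ndarray
    y: np.ndarray
    blink_area: np.ndarray
    frame_rate_hz: float


def generate_session(config: GeneratorConfig, seed: int | None = None) -> tuple[SessionTimeseries, GroundTruth]:
    """Simulate one behavioral session.

    Running bouts at the configured mean speed alternate with freeze epochs
    drawn from the hazard/gamma law (velocity clamped to exactly 0 during
    freezes, so ground-truth freeze frames are precisely the sub-threshold
    frames).  Position wraps 0 -> 200 cm with a teleport-flagged 1.5 s pause
    at the end of each traversal.  If ``n_shocks`` > 0, shocks arrive 20-26 s
    apart, each followed by a 2 s sprint at 3x the baseline speed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    fs = config.frame_rate_hz
    dt = 1.0 / fs
    n = config.n_frames
    pause_frames = int(round(config.teleport_pause_s * fs))

    shock_frames: list[int] = []
    if config.n_shocks > 0:
        lo, hi = config.shock_gap_s
        t_shock = 0.0
        for _ in range(config.n_shocks):
            t_shock += rng.uniform(lo, hi)
            shock_frames.append(int(round(t_shock * fs)))
    shock_frames = [f for f in shock_frames if f < n]
    next_shock = 0  # pointer into shock_frames; delivery deferred past teleports

    vel = np.zeros(n)
    pos = np.zeros(n)
    teleport = np.zeros(n, dtype=bool)
    labels = np.empty(n, dtype=object)
    shock_times, shock_positions = [], []

    x = 0.0
    freeze_left = 0
    pause_left = 0
    sprint_left = 0
    p_freeze = config.freeze_hazard_per_s * dt
    for i in range(n):
        if next_shock < len(shock_frames) and i >= shock_frames[next_shock] and pause_left == 0:
            next_shock += 1
            shock_times.append(i * dt)
            shock_positions.append(x)
            sprint_left = int(round(config.shock_sprint_s * fs))
            freeze_left = 0
        if pause_left > 0:
            teleport[i] = True
            labels[i] = "teleport"
            vel[i] = 0.0
            pos[i] = x
            pause_left -= 1
            continue
        if freeze_left > 0:
            labels[i] = "freeze"
            vel[i] = 0.0
            pos[i] = x
            freeze_left -= 1
            continue
        if sprint_left == 0 and rng.random() < p_freeze:
            length_s = rng.gamma(
                config.freeze_len_shape,
                config.freeze_len_mean_s * config.inhibition_factor / config.freeze_len_shape,
            )
            freeze_left = max(MIN_FREEZE_FRAMES, int(round(length_s * fs)))
            labels[i] = "freeze"
            vel[i] = 0.0
            pos[i] = x
            freeze_left -= 1
            continue
        if sprint_left > 0:
            v = config.shock_sprint_gain * config.run_speed_mean_cms + rng.normal(0.0, config.run_speed_sd_cms)
            sprint_left -= 1
        else:
            v = rng.normal(config.run_speed_mean_cms, config.run_speed_sd_cms)
        v = max(1.0, v)
        labels[i] = "run"
        vel[i] = v
        x_new = x + v * dt
        if x_new >= config.track_len_cm:
            pos[i] = config.track_len_cm
            x = 0.0
            pause_left = pause_frames
        else:
            pos[i] = x_new
            x = x_new

    session = SessionTimeseries(
        mouse_id="m0",
        day_id="pre",
        context_id="control",
        t=np.arange(n) * dt,
        position_cm=pos,
        velocity_cms=vel,
        teleport_flag=teleport,
        shock_times_s=np.asarray(shock_times),
        shock_positions_cm=np.asarray(shock_positions),
        frame_rate_hz=fs,
    )
    truth = GroundTruth(
        true_epochs=epochs_from_labels(labels, fs),
        freeze_mask=(labels == "freeze"),
    )
    return session, truth


def bow_rate(progress: np.ndarray, bow_profile: Iterable[float], tuning_amp: float) -> np.ndarray:
    """Latent transient rate (events/s) at a given freeze progress.

    The 5 profile levels sit at the bin centers 0.1, 0.3, ..., 0.9 of freeze
    progress and are linearly interpolated between them.
    """
    centers = np.linspace(0.1, 0.9, 5)
    return tuning_amp * np.interp(progress, centers, np.asarray(list(bow_profile), dtype=float))


def indicator_kernel(tau_s: float, frame_rate_hz: float) -> np.ndarray:
    """Single-exponential indicator decay kernel, truncated at 5 tau."""
    n = max(2, int(round(5 * tau_s * frame_rate_hz)))
    t = np.arange(n) / frame_rate_hz
    return np.exp(-t / tau_s)


def generate_axon_rois(
    config: GeneratorConfig, truth: GroundTruth, seed: int | None = None
) -> RoiTraceSet:
    """Two-channel ROI traces for one axon plus unrelated noise ROIs.

    The latent drive is the bow profile evaluated at freeze progress inside
    ground-truth freeze epochs and ``baseline_rate_per_s`` elsewhere.
    Bernoulli transients drawn from the drive are convolved with the
    exponential indicator kernel; the resulting signal is shared (with
    per-segment gain) across ``n_axon_segments`` green traces.  A common
    low-pass motion artifact enters the green and red channels of every ROI;
    the red channel is otherwise constant.  Fills in
    ``truth.true_transient_frames`` and ``truth.true_tuning_state``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    n = truth.true_epochs.n_frames
    if len(truth.freeze_mask) != n:
        raise AlignmentError("ground truth arrays disagree on frame count")
    fs = config.frame_rate_hz

    rate = np.full(n, config.baseline_rate_per_s)
    for row in truth.true_epochs.epochs_of("freeze").itertuples():
        length = row.end - row.start
        progress = np.arange(length) / max(length - 1, 1)
        # freeze drive rides on the baseline so an untuned axon (amp 0)
        # keeps its sparse spontaneous activity during freezes
        rate[row.start : row.end] = config.baseline_rate_per_s + bow_rate(
            progress, config.bow_profile, config.tuning_amp
        )
    truth.true_tuning_state = rate

    events = rng.random(n) < rate / fs
    amps = np.zeros(n)
    amps[events] = config.transient_amp * rng.uniform(0.8, 1.2, events.sum())
    truth.true_transient_frames = np.flatnonzero(events)

    kernel = indicator_kernel(config.indicator_tau_s, fs)
    signal = np.convolve(amps, kernel)[:n]

    motion = rng.normal(0.0, 1.0, n)
    motion = gaussian_filter1d(motion, sigma=0.5 * fs)
    sd = motion.std()
    motion = config.motion_amp * (motion / sd if sd > 0 else motion)

    n_rois = config.n_axon_segments + config.n_noise_rois
    green = np.empty((n_rois, n))
    red = np.empty((n_rois, n))
    roi_ids = []
    for k in range(config.n_axon_segments):
        gain = rng.uniform(0.8, 1.2)
        green[k] = 1.0 + gain * signal + motion + rng.normal(0.0, config.noise_sd, n)
        roi_ids.append(f"axon_seg{k}")
    for k in range(config.n_axon_segments, n_rois):
        green[k] = 1.0 + motion + rng.normal(0.0, config.noise_sd, n)
        roi_ids.append(f"noise_roi{k - config.n_axon_segments}")
    for k in range(n_rois):
        red[k] = 1.0 + motion + rng.normal(0.0, config.noise_sd, n)

    return RoiTraceSet(roi_ids=roi_ids, green=green, red=red, frame_rate_hz=fs)


def generate_pupil(config: GeneratorConfig, seed: int | None = None) -> PupilTraces:
    """Slow-varying pupil area/x/y plus a blink-area trace with blink drops.

    Blink events arrive at ``blink_rate_per_s`` and last 2-4 frames; during a
    blink the blinking area collapses well below mean - 2 SD and the pupil
    area reads artifactually low, which is what the cleaning step removes.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    n = config.n_frames
    fs = config.frame_rate_hz

    def slow(scale: float, base: float) -> np.ndarray:
        trace = gaussian_filter1d(rng.normal(0.0, 1.0, n), sigma=2.0 * fs)
        sd = trace.std()
        return base + scale * (trace / sd if sd > 0 else trace)

    area = slow(5.0, 50.0)
    x = slow(1.0, 0.0)
    y = slow(1.0, 0.0)
    blink_area = 10.0 + rng.normal(0.0, 0.3, n)

    n_blinks = rng.poisson(config.blink_rate_per_s * n / fs)
    for _ in range(n_blinks):
        start = int(rng.integers(0, max(1, n - 4)))
        length = int(rng.integers(2, 5))
        blink_area[start : start + length] = 2.0 + rng.normal(0.0, 0.2, min(length, n - start))
        area[start : start + length] *= 0.3
    return PupilTraces(area=area, x=x, y=y, blink_area=blink_area, frame_rate_hz=fs)


# Default per-day/context behavioral conditions for cohort generation:
# (freeze occupancy of non-teleport time, mean freeze length in seconds).
# The pre-shock day shows sparse short spontaneous pauses; the shocked
# context on retrieval day 1 combines the printed ~5.9 s mean epoch length
# with ~37% freeze occupancy, the control context ~4.6 s and ~13%, both
# decaying toward baseline across extinction days.
COHORT_FREEZE_TABLE: dict[tuple[str, str], tuple[float, float]] = {
    ("pre", "shocked"): (0.05, 2.0),
    ("pre", "control"): (0.05, 2.0),
    ("d1", "shocked"): (0.37, 5.9),
    ("d1", "control"): (0.13, 4.6),
    ("d2", "shocked"): (0.27, 5.0),
    ("d2", "control"): (0.09, 4.0),
    ("d3", "shocked"): (0.16, 3.5),
    ("d3", "control"): (0.07, 3.0),
    ("d1", "dark"): (0.04, 2.0),
    ("d2", "dark"): (0.04, 2.0),
    ("d3", "dark"): (0.04, 2.0),
}

#: Peak transient rate (events/s) during freezes once the axon is tuned.
POST_SHOCK_TUNING_AMP = 0.8

# Freeze occupancy on the day the silencing agent is on board (retrieval
# day 1): silencing the thalamo-hippocampal pathway lengthens freeze epochs
# and raises total freezing in both contexts.
INHIBITED_D1_OCCUPANCY: dict[str, float] = {"shocked": 0.60, "control": 0.35}


@dataclass
class CohortDesign:
    """Mice x days x contexts layout of a simulated experiment."""

    n_mice: int = 10
    days: tuple[str, ...] = DAYS
    contexts: tuple[str, ...] = CONTEXTS
    inhibited: bool = False
    inhibition_factor: float = 2.7
    base_config: GeneratorConfig = field(default_factory=GeneratorConfig)

    def validate(self) -> None:
        if self.n_mice < 1:
            raise ConfigError("need at least one mouse")
        cells = [(d, c) for d in self.days for c in self.contexts]
        if len(set(cells)) != len(cells):
            raise ConfigError("duplicate day x context cells")


@dataclass
class SessionBundle:
    """One generated mouse x day x context cell with its ground truth."""

    session: SessionTimeseries
    truth: GroundTruth
    rois: RoiTraceSet
    pupil: PupilTraces
    config: GeneratorConfig


def cell_config(design: CohortDesign, day: str, context: str) -> GeneratorConfig:
    """Generator config for one day x context cell of the design."""
    if (day, context) not in COHORT_FREEZE_TABLE:
        raise ConfigError(f"no behavioral condition for ({day}, {context})")
    occupancy, mean_len = COHORT_FREEZE_TABLE[(day, context)]
    cfg = design.base_config
    if design.inhibited and day == "d1" and context != "dark":
        cfg = replace(cfg, inhibition_factor=design.inhibition_factor)
        occupancy = INHIBITED_D1_OCCUPANCY[context]
    cfg = cfg.with_freeze_occupancy(occupancy, mean_len)
    tuning = 0.0 if day == "pre" or context == "dark" else POST_SHOCK_TUNING_AMP
    return replace(cfg, tuning_amp=tuning, n_shocks=0)


def generate_cohort(design: CohortDesign, seed: int = 0) -> dict[tuple[str, str, str], SessionBundle]:
    """Generate every mouse x day x context session of a design.

    Returns a dict keyed by (mouse_id, day_id, context_id); per-cell seeds
    are spawned deterministically from ``seed``.
    """
    design.validate()
    root = np.random.SeedSequence(seed)
    out: dict[tuple[str, str, str], SessionBundle] = {}
    for m in range(design.n_mice):
        mouse_id = f"m{m}"
        for day in design.days:
            for context in design.contexts:
                key = (mouse_id, day, context)
                sub = np.random.SeedSequence(entropy=root.entropy, spawn_key=(m, design.days.index(day), design.contexts.index(context)))
                s_beh, s_roi, s_pup = [int(s) for s in sub.generate_state(3) % (2**31)]
                cfg = cell_config(design, day, context)
                session, truth = generate_session(cfg, seed=s_beh)
                session.mouse_id, session.day_id, session.context_id = key
                rois = generate_axon_rois(cfg, truth, seed=s_roi)
                pupil = generate_pupil(cfg, seed=s_pup)
                out[key] = SessionBundle(session=session, truth=truth, rois=rois, pupil=pupil, config=cfg)
    return out
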