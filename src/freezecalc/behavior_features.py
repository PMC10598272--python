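"""Behavioral epoch detection and per-frame feature engineering.

A head-fixed mouse runs on a treadmill through a 200 cm virtual track at a
fixed imaging frame rate (15.49 Hz).  Fearful freezing is read out from the
velocity trace: a freezing epoch is a maximal run of frames with speed below
0.001 cm/s lasting at least 12 consecutive frames (~0.75 s).  Sub-threshold
runs shorter than 12 frames are neither freezing nor running and are
discarded from analysis; running epochs are maximal runs of above-threshold
forward velocity sustained for at least 2 frames; sustained backward motion
is labelled backtracking.  Teleport frames (the 1.5 s pause at the end of
each traversal) are kept out of all behavioral states.

From the epoch partition this module derives the per-frame predictors used
by the encoding model (sawtooth elapsed/remaining counters, progress
fractions, velocity offsets, acceleration, 1 cm location bins, smoothed
pupil signals) and the per-session behavioral summaries (% time freezing,
baseline deltas, discrimination index, freeze-length statistics).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .exceptions import AlignmentError, ConfigError, DegenerateTraceError

#: Velocity magnitude (cm/s) below which a frame is a freeze candidate.
FREEZE_VELOCITY_THRESHOLD_CMS = 0.001
#: Minimum length (frames) of a below-threshold run to count as freezing.
MIN_FREEZE_FRAMES = 12
#: Minimum length (frames) of an above-threshold run to count as running.
MIN_RUN_FRAMES = 2

EPOCH_KINDS = ("freeze", "run", "backtrack", "discarded", "teleport")

#: Columns of the per-frame feature matrix, in model-input order.
FEATURE_COLUMNS = [
    "freeze",
    "is_freezing",
    "freeze_elapsed",
    "freeze_remaining",
    "freeze_progress",
    "is_postfreeze",
    "is_running",
    "running_elapsed",
    "running_remaining",
    "running_progress",
    "is_backtracking",
    "interval_elapsed",
    "interval_remaining",
    "interval_progress",
    "recorded_velocity",
    "velocity_back_15",
    "velocity_back_8",
    "velocity_fwd_8",
    "velocity_fwd_15",
    "acceleration",
    "location",
    "pupil_area",
    "pupil_x",
    "pupil_y",
]


@dataclass
class SessionTimeseries:
    """One mouse x day x context behavioral recording at a fixed frame rate."""

    mouse_id: str
    day_id: str
    context_id: str
    t: np.ndarray
    position_cm: np.ndarray
    velocity_cms: np.ndarray
    teleport_flag: np.ndarray
    shock_times_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    shock_positions_cm: np.ndarray = field(default_factory=lambda: np.empty(0))
    frame_rate_hz: float = 15.49

    @property
    def n_frames(self) -> int:
        return len(self.t)

    def validate(self) -> None:
        n = self.n_frames
        if n == 0:
            raise ConfigError("empty session")
        for name in ("position_cm", "velocity_cms", "teleport_flag"):
            if len(getattr(self, name)) != n:
                raise AlignmentError(f"{name} length != t length")
        dt = np.diff(self.t)
        if n > 1 and not np.allclose(dt, 1.0 / self.frame_rate_hz, rtol=1e-6):
            raise ConfigError("frame spacing is not uniform at 1/frame_rate")


@dataclass
class EpochTable:
    """Labeled, non-overlapping behavioral epochs partitioning a session.

    ``df`` has one row per epoch with columns ``kind`` (one of
    :data:`EPOCH_KINDS`), half-open ``start``/``end`` frame indices,
    ``n_frames``, ``duration_s`` and a 1-based ``ordinal`` within kind.
    """

    df: pd.DataFrame
    n_frames: int
    frame_rate_hz: float

    def validate(self) -> None:
        df = self.df.sort_values("start")
        if len(df) == 0:
            raise ConfigError("empty epoch table")
        if df["start"].iloc[0] != 0 or df["end"].iloc[-1] != self.n_frames:
            raise ConfigError("epochs do not cover the session")
        if not np.array_equal(df["end"].to_numpy()[:-1], df["start"].to_numpy()[1:]):
            raise ConfigError("epochs overlap or leave gaps")
        if not df["kind"].isin(EPOCH_KINDS).all():
            raise ConfigError("unknown epoch kind")
        freeze = df[df["kind"] == "freeze"]
        if (freeze["end"] - freeze["start"] < MIN_FREEZE_FRAMES).any():
            raise ConfigError(f"freeze epoch shorter than {MIN_FREEZE_FRAMES} frames")
        run = df[df["kind"] == "run"]
        if (run["end"] - run["start"] < MIN_RUN_FRAMES).any():
            raise ConfigError(f"run epoch shorter than {MIN_RUN_FRAMES} frames")

    def labels(self) -> np.ndarray:
        """Per-frame epoch kind as an object array of strings."""
        out = np.empty(self.n_frames, dtype=object)
        for row in self.df.itertuples():
            out[row.start : row.end] = row.kind
        return out

    def frames_of(self, kind: str) -> int:
        sel = self.df[self.df["kind"] == kind]
        return int((sel["end"] - sel["start"]).sum())

    def epochs_of(self, kind: str) -> pd.DataFrame:
        return self.df[self.df["kind"] == kind].reset_index(drop=True)


def _candidate_labels(velocity: np.ndarray, teleport: np.ndarray) -> np.ndarray:
    """Frame-wise state candidates before the minimum-length rules."""
    labels = np.empty(len(velocity), dtype=object)
    labels[:] = "freeze"
    labels[velocity >= FREEZE_VELOCITY_THRESHOLD_CMS] = "run"
    labels[velocity <= -FREEZE_VELOCITY_THRESHOLD_CMS] = "backtrack"
    labels[teleport.astype(bool)] = "teleport"
    return labels


def _runs(labels: np.ndarray) -> list[tuple[str, int, int]]:
    """Maximal runs of identical labels as (label, start, end) half-open."""
    out = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            out.append((labels[start], start, i))
            start = i
    return out


def epochs_from_labels(
    labels: np.ndarray, frame_rate_hz: float, apply_min_lengths: bool = True
) -> EpochTable:
    """Build an :class:`EpochTable` from per-frame state labels.

    With ``apply_min_lengths`` (the default), below-threshold runs shorter
    than 12 frames and run/backtrack runs shorter than 2 frames are
    relabelled ``discarded``.
    """
    rows = []
    for kind, start, end in _runs(labels):
        n = end - start
        if apply_min_lengths:
            if kind == "freeze" and n < MIN_FREEZE_FRAMES:
                kind = "discarded"
            elif kind in ("run", "backtrack") and n < MIN_RUN_FRAMES:
                kind = "discarded"
        rows.append((kind, start, end, n, n / frame_rate_hz))
    df = pd.DataFrame(rows, columns=["kind", "start", "end", "n_frames", "duration_s"])
    # merge adjacent rows that collapsed to the same kind (e.g. discarded runs)
    merged = []
    for row in df.itertuples(index=False):
        if merged and merged[-1][0] == row.kind:
            prev = merged[-1]
            merged[-1] = (row.kind, prev[1], row.end, row.end - prev[1], (row.end - prev[1]) / frame_rate_hz)
        else:
            merged.append(tuple(row))
    df = pd.DataFrame(merged, columns=["kind", "start", "end", "n_frames", "duration_s"])
    df["ordinal"] = df.groupby("kind").cumcount() + 1
    return EpochTable(df=df, n_frames=int(df["end"].iloc[-1]), frame_rate_hz=frame_rate_hz)


def detect_epochs(session: SessionTimeseries) -> EpochTable:
    """Partition a session into freeze/run/backtrack/discarded/teleport epochs.

    Maximal runs of |v| < 0.001 cm/s lasting >=12 frames are freezing;
    shorter sub-threshold runs are discarded.  Maximal runs of forward
    velocity >= 0.001 cm/s sustained >=2 frames are running (a single
    isolated above-threshold frame is discarded), and the mirrored rule on
    v <= -0.001 cm/s yields backtracking.  Teleport-flagged frames form
    their own epochs and never enter the behavioral states.
    """
    session.validate()
    if session.n_frames == 0:
        raise ConfigError("empty session")
    labels = _candidate_labels(session.velocity_cms, session.teleport_flag)
    table = epochs_from_labels(labels, session.frame_rate_hz)
    table.validate()
    return table


def _sawtooth(table: EpochTable, kind: str, n: int):
    """Elapsed/remaining/progress sawtooths plus membership for one kind.

    Elapsed counts frames since epoch start (0-based), remaining counts down
    to 0 at the last frame, so elapsed + remaining = epoch length - 1, and
    progress = elapsed / (length - 1) runs from 0 at the first frame to 1 at
    the last.
    """
    is_kind = np.zeros(n)
    elapsed = np.zeros(n)
    remaining = np.zeros(n)
    progress = np.zeros(n)
    ordinal = np.zeros(n)
    for row in table.df[table.df["kind"] == kind].itertuples():
        length = row.end - row.start
        idx = np.arange(length)
        is_kind[row.start : row.end] = 1.0
        elapsed[row.start : row.end] = idx
        remaining[row.start : row.end] = length - 1 - idx
        progress[row.start : row.end] = idx / (length - 1) if length > 1 else 0.0
        ordinal[row.start : row.end] = row.ordinal
    return is_kind, elapsed, remaining, progress, ordinal


def _velocity_offset(v: np.ndarray, offset: int) -> np.ndarray:
    """Velocity shifted by ``offset`` frames (positive = future velocity).

    Frames whose shifted index falls outside the session are filled with the
    mean of the 15 boundary frames (the mean of the last 15 frames for a
    future offset, of the first 15 for a past offset) held constant.
    """
    n = len(v)
    out = np.empty(n)
    k = min(15, n)
    if offset >= 0:
        out[: n - offset] = v[offset:]
        out[n - offset :] = v[-k:].mean()
    else:
        out[-offset:] = v[:offset]
        out[: -offset] = v[:k].mean()
    return out


def compute_frame_features(
    session: SessionTimeseries,
    epochs: EpochTable,
    pupil: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Per-frame predictor matrix for the encoding model.

    Returns a DataFrame with :data:`FEATURE_COLUMNS`: epoch ordinals and
    binary state indicators, sawtooth elapsed/remaining counters (frames) and
    progress fractions for freezing and running, the combined freeze/run
    "interval" sawtooths that reset at every state switch, recorded velocity
    with past/future offsets at 8 and 15 frames (~0.5 s and ~1 s), frame-wise
    acceleration (first difference x frame rate), 1 cm location bins, and
    the cleaned pupil area / x / y traces (zeros when no pupil is supplied).
    """
    n = session.n_frames
    if epochs.n_frames != n:
        raise AlignmentError("epoch table and session have different frame counts")

    is_fr, fr_el, fr_re, fr_pr, fr_ord = _sawtooth(epochs, "freeze", n)
    is_ru, ru_el, ru_re, ru_pr, _ = _sawtooth(epochs, "run", n)
    is_bt = epochs.labels() == "backtrack"

    # the epoch immediately following each freeze is flagged post-freeze
    is_post = np.zeros(n)
    df = epochs.df.sort_values("start").reset_index(drop=True)
    for i in range(len(df) - 1):
        if df.loc[i, "kind"] == "freeze" and df.loc[i + 1, "kind"] != "teleport":
            is_post[df.loc[i + 1, "start"] : df.loc[i + 1, "end"]] = 1.0

    # interval sawtooths: freeze and run streams merged, resetting at switches
    iv_el = fr_el * is_fr + ru_el * is_ru
    iv_re = fr_re * is_fr + ru_re * is_ru
    iv_pr = fr_pr * is_fr + ru_pr * is_ru

    v = np.asarray(session.velocity_cms, dtype=float)
    accel = np.empty(n)
    accel[1:] = np.diff(v) * session.frame_rate_hz
    accel[0] = 0.0

    location = np.clip(np.floor(session.position_cm), 0, None)

    out = pd.DataFrame(
        {
            "freeze": fr_ord,
            "is_freezing": is_fr,
            "freeze_elapsed": fr_el,
            "freeze_remaining": fr_re,
            "freeze_progress": fr_pr,
            "is_postfreeze": is_post,
            "is_running": is_ru,
            "running_elapsed": ru_el,
            "running_remaining": ru_re,
            "running_progress": ru_pr,
            "is_backtracking": is_bt.astype(float),
            "interval_elapsed": iv_el,
            "interval_remaining": iv_re,
            "interval_progress": iv_pr,
            "recorded_velocity": v,
            "velocity_back_15": _velocity_offset(v, -15),
            "velocity_back_8": _velocity_offset(v, -8),
            "velocity_fwd_8": _velocity_offset(v, 8),
            "velocity_fwd_15": _velocity_offset(v, 15),
            "acceleration": accel,
            "location": location,
        }
    )
    for key in ("pupil_area", "pupil_x", "pupil_y"):
        short = key.removeprefix("pupil_")
        if pupil is not None and short in pupil:
            trace = np.asarray(pupil[short], dtype=float)
            if len(trace) != n:
                raise AlignmentError(f"pupil trace {short!r} length != session frames")
            out[key] = trace
        else:
            out[key] = 0.0
    if not np.isfinite(out.to_numpy()).all():
        raise ValueError("non-finite value in feature matrix")
    return out[FEATURE_COLUMNS]


def percent_time_freezing(epochs: EpochTable) -> float:
    """Percent of non-teleport frames spent in freezing epochs.

    The denominator is freeze + run + backtrack + discarded frames; the
    teleport pause is dropped, mirroring how traversal timing drops it.
    """
    denom = epochs.n_frames - epochs.frames_of("teleport")
    if denom == 0:
        raise ConfigError("session has no non-teleport frames")
    return 100.0 * epochs.frames_of("freeze") / denom


def baseline_delta(pct_day: float, pct_baseline: float) -> float:
    """Signed change in %freezing from the pre-shock baseline day."""
    return pct_day - pct_baseline


def discrimination_index(pct_shocked: float, pct_control: float) -> float:
    """Context discrimination index.

    DI = (%freezing shocked - %freezing control) / (sum of the two),
    bounded in [-1, 1]; undefined when the mouse froze in neither context.
    """
    total = pct_shocked + pct_control
    if total == 0:
        raise ConfigError("discrimination index undefined: no freezing in either context")
    return (pct_shocked - pct_control) / total


def relative_change(reference: float, comparison: float) -> float:
    """Percent increase of ``comparison`` over ``reference`` (> 0)."""
    if reference <= 0:
        raise ConfigError("relative change requires a positive reference")
    return 100.0 * (comparison - reference) / reference


@dataclass
class FreezeLengthStats:
    """Freeze-epoch duration summary; ``count == 0`` signals no epochs."""

    mean_s: float
    count: int
    lengths_s: np.ndarray


def freeze_length_stats(epochs: EpochTable) -> FreezeLengthStats:
    """Mean and per-epoch list of freeze durations in seconds."""
    lengths = epochs.epochs_of("freeze")["duration_s"].to_numpy()
    if len(lengths) == 0:
        return FreezeLengthStats(mean_s=float("nan"), count=0, lengths_s=lengths)
    return FreezeLengthStats(mean_s=float(lengths.mean()), count=len(lengths), lengths_s=lengths)


def blink_mask(blink_area: np.ndarray) -> np.ndarray:
    """Frames whose blinking area falls below mean - 2 x SD (blink frames)."""
    ba = np.asarray(blink_area, dtype=float)
    return ba < ba.mean() - 2.0 * ba.std()


def clean_pupil(
    area: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    blink_area: np.ndarray,
    source_rate_hz: float,
    target_rate_hz: float = 15.49,
    sg_window: int = 15,
    sg_order: int = 3,
) -> dict[str, np.ndarray]:
    """Blink-clean, resample, and smooth pupil traces.

    Blink frames (blinking area < mean - 2 SD) are removed and the gaps
    linearly interpolated; traces are then resampled onto the imaging frame
    clock and Savitzky-Golay smoothed (window 15 frames, order 3 by
    default).  Returns ``area``/``x``/``y`` plus the pre-interpolation
    ``blink_mask``.
    """
    area = np.asarray(area, dtype=float)
    n = len(area)
    if not (len(x) == len(y) == len(blink_area) == n):
        raise AlignmentError("pupil traces must be time-aligned")
    mask = blink_mask(blink_area)
    good = ~mask
    if not good.any():
        raise DegenerateTraceError("every pupil frame is a blink frame")

    t_src = np.arange(n) / source_rate_hz
    duration = n / source_rate_hz
    t_out = np.arange(int(round(duration * target_rate_hz))) / target_rate_hz

    out: dict[str, np.ndarray] = {"blink_mask": mask}
    for name, trace in (("area", area), ("x", np.asarray(x, float)), ("y", np.asarray(y, float))):
        interp = np.interp(t_src, t_src[good], trace[good])
        resampled = np.interp(t_out, t_src, interp)
        window = min(sg_window, len(resampled) - (1 - len(resampled) % 2))
        if window > sg_order:
            resampled = savgol_filter(resampled, window, sg_order)
        out[name] = resampled
    return out
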