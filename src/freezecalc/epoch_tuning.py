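"""Axonal activity quantified relative to behavioral epochs.

Three complementary views of freeze tuning, each robust to the fact that
successful conditioning changes the behavior itself (more and longer
freezes):

1. per-epoch mean normalized peak dF/F, split by state (freeze vs run) --
   compares activity between states without assuming matched epoch lengths;
2. length-binned transition alignment -- freezing epochs are grouped into
   1 s total-length bins (1-2 s ... 6-7 s; epochs over 7 s dropped) and the
   normalized trace aligned to each epoch's freeze -> run transition, so
   pre- and post-conditioning activity is compared at matched epoch length;
3. 5-bin progress profile -- each freezing epoch is divided into five
   equal-duration bins and peak activity averaged within bins, stretching
   or shrinking every epoch onto a common 0-100% progress axis.  This is
   the view in which the ramp/plateau/fall ("bow") shape appears.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .behavior_features import EpochTable
from .exceptions import AlignmentError
from .trace_processing import AxonTrace, PeakSet

LENGTH_BINS_S = [(lo, lo + 1.0) for lo in range(1, 7)]  # "1-2 s" ... "6-7 s"


@dataclass
class StateMeans:
    """Per-epoch mean normalized peak dF/F with state labels."""

    per_epoch: pd.DataFrame  # kind, ordinal, start, end, n_peaks, mean_norm_height
    freeze_mean: float  # grand mean over freeze epochs that contain peaks
    run_mean: float


@dataclass
class AlignedBin:
    """Transition-aligned activity for one epoch-length bin."""

    label: str
    matrix: np.ndarray  # (n_epochs, width), NaN-padded
    transition_index: int  # column of the first post-freeze frame
    mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_epochs: int


@dataclass
class ProgressProfile:
    """Peak activity across five equal-duration bins of freeze progress."""

    bin_means: np.ndarray  # (5,)
    bin_sem: np.ndarray
    per_epoch: np.ndarray  # (n_epochs, 5); zero where an epoch bin had no peak
    n_epochs: int


def _norm_heights(peaks: PeakSet, axon: AxonTrace) -> np.ndarray:
    """Peak heights on the day-normalized scale (apex value of ``norm``)."""
    return axon.norm[peaks.peak_frames]


def state_peak_means(peaks: PeakSet, epochs: EpochTable, axon: AxonTrace) -> StateMeans:
    """Mean normalized peak dF/F per freeze and run epoch.

    A peak belongs to the epoch containing its apex frame.  Epochs without
    peaks appear in ``per_epoch`` with NaN mean and are excluded from the
    grand state means.
    """
    if len(axon.norm) != epochs.n_frames:
        raise AlignmentError("axon trace and epoch table disagree on frame count")
    heights = _norm_heights(peaks, axon)
    rows = []
    for kind in ("freeze", "run"):
        for row in epochs.epochs_of(kind).itertuples():
            inside = (peaks.peak_frames >= row.start) & (peaks.peak_frames < row.end)
            n_peaks = int(inside.sum())
            mean_h = float(heights[inside].mean()) if n_peaks else np.nan
            rows.append((kind, row.ordinal, row.start, row.end, n_peaks, mean_h))
    per_epoch = pd.DataFrame(
        rows, columns=["kind", "ordinal", "start", "end", "n_peaks", "mean_norm_height"]
    )

    def grand(kind: str) -> float:
        vals = per_epoch.loc[per_epoch["kind"] == kind, "mean_norm_height"].dropna()
        return float(vals.mean()) if len(vals) else np.nan

    return StateMeans(per_epoch=per_epoch, freeze_mean=grand("freeze"), run_mean=grand("run"))


def length_binned_alignment(
    axon: AxonTrace,
    epochs: EpochTable,
    bins_s: list[tuple[float, float]] | None = None,
) -> dict[str, AlignedBin]:
    """Freeze->run transition-aligned traces grouped by epoch length.

    For every freezing epoch whose duration falls in a bin, the window is
    the full epoch on the freeze side plus an equal-length stretch of the
    following frames on the run side (NaN-padded past the session end).
    Rows are right-aligned on the transition so column ``transition_index``
    is the first post-freeze frame in every row.  Empty bins are omitted.
    """
    if len(axon.norm) != epochs.n_frames:
        raise AlignmentError("axon trace and epoch table disagree on frame count")
    bins_s = LENGTH_BINS_S if bins_s is None else bins_s
    n = epochs.n_frames
    out: dict[str, AlignedBin] = {}
    freeze = epochs.epochs_of("freeze")
    for lo, hi in bins_s:
        rows = freeze[(freeze["duration_s"] >= lo) & (freeze["duration_s"] < hi)]
        if len(rows) == 0:
            continue
        max_len = int((rows["end"] - rows["start"]).max())
        width = 2 * max_len
        matrix = np.full((len(rows), width), np.nan)
        for i, row in enumerate(rows.itertuples()):
            length = row.end - row.start
            left = axon.norm[row.start : row.end]
            right_end = min(n, row.end + length)
            right = axon.norm[row.end : right_end]
            matrix[i, max_len - length : max_len] = left
            matrix[i, max_len : max_len + len(right)] = right
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(matrix, axis=0)
            counts = np.sum(~np.isnan(matrix), axis=0)
            sd = np.nanstd(matrix, axis=0)
        sem = np.where(counts > 0, sd / np.sqrt(np.maximum(counts, 1)), np.nan)
        label = f"{lo:g}-{hi:g} s"
        out[label] = AlignedBin(
            label=label,
            matrix=matrix,
            transition_index=max_len,
            mean=mean,
            ci_low=mean - 1.96 * sem,
            ci_high=mean + 1.96 * sem,
            n_epochs=len(rows),
        )
    return out


def progress_profile(
    peaks: PeakSet,
    epochs: EpochTable,
    axon: AxonTrace,
    n_bins: int = 5,
    kind: str = "freeze",
) -> ProgressProfile:
    """Mean normalized peak dF/F across equal-duration progress bins.

    Each epoch of the requested kind is split into ``n_bins`` equal-duration
    bins; peaks are assigned to bins by apex frame and averaged within each
    bin, a bin without peaks contributing zero (so the profile reflects both
    peak amplitude and peak occurrence).  Epochs shorter than ``n_bins``
    frames are excluded.
    """
    if len(axon.norm) != epochs.n_frames:
        raise AlignmentError("axon trace and epoch table disagree on frame count")
    heights = _norm_heights(peaks, axon)
    per_epoch = []
    for row in epochs.epochs_of(kind).itertuples():
        length = row.end - row.start
        if length < n_bins:
            continue
        edges = np.linspace(row.start, row.end, n_bins + 1)
        vec = np.zeros(n_bins)
        for b in range(n_bins):
            inside = (peaks.peak_frames >= edges[b]) & (peaks.peak_frames < edges[b + 1])
            if inside.any():
                vec[b] = heights[inside].mean()
        per_epoch.append(vec)
    if not per_epoch:
        empty = np.full(n_bins, np.nan)
        return ProgressProfile(bin_means=empty, bin_sem=empty, per_epoch=np.empty((0, n_bins)), n_epochs=0)
    mat = np.vstack(per_epoch)
    sem = mat.std(axis=0) / np.sqrt(len(mat)) if len(mat) > 1 else np.full(n_bins, np.nan)
    return ProgressProfile(
        bin_means=mat.mean(axis=0), bin_sem=sem, per_epoch=mat, n_epochs=len(mat)
    )


def multiday_axon_summary(
    days: dict[str, tuple[AxonTrace, PeakSet, EpochTable]],
) -> dict[str, dict]:
    """Per-day tuning summaries for one axon tracked across days.

    Applies the state means, length-binned alignment, and progress profile
    to each day of a multi-day tracked axon, keyed by day id, which is what
    the day-3 tuning-decay comparison reads.
    """
    out: dict[str, dict] = {}
    for day, (axon, peaks, epochs) in days.items():
        out[day] = {
            "state_means": state_peak_means(peaks, epochs, axon),
            "aligned": length_binned_alignment(axon, epochs),
            "profile": progress_profile(peaks, epochs, axon),
        }
    return out
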