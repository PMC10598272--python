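"""HDF5 session container with lossless round-tripping.

Layout (schema version stamped as a root attribute):

    /behavior   t, position_cm, velocity_cms, teleport_flag,
                shock_times_s, shock_positions_cm
                attrs: mouse_id, day_id, context_id, frame_rate_hz
    /traces     green (n_rois, n), red (n_rois, n), roi_ids
    /pupil      area, x, y, blink_area
    /truth      freeze_mask, transient_frames, tuning_state,
                epoch_{kind,start,end}

Missing optional groups (/traces, /pupil, /truth) load as None.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .behavior_features import SessionTimeseries, epochs_from_labels
from .exceptions import SchemaError
from .synthetic_data import GroundTruth, PupilTraces, RoiTraceSet, SessionBundle

SCHEMA_ATTR = "freezecalc_schema"
SCHEMA_VERSION = 1


def save_session(
    path: str | Path,
    session: SessionTimeseries,
    rois: RoiTraceSet | None = None,
    pupil: PupilTraces | None = None,
    truth: GroundTruth | None = None,
) -> None:
    """Write a session (and optional traces/pupil/truth) to one HDF5 file."""
    with h5py.File(path, "w") as f:
        f.attrs[SCHEMA_ATTR] = SCHEMA_VERSION
        beh = f.create_group("behavior")
        for name in ("t", "position_cm", "velocity_cms", "shock_times_s", "shock_positions_cm"):
            beh.create_dataset(name, data=np.asarray(getattr(session, name), dtype=float))
        beh.create_dataset("teleport_flag", data=np.asarray(session.teleport_flag, dtype=bool))
        for name in ("mouse_id", "day_id", "context_id"):
            beh.attrs[name] = getattr(session, name)
        beh.attrs["frame_rate_hz"] = session.frame_rate_hz

        if rois is not None:
            grp = f.create_group("traces")
            grp.create_dataset("green", data=rois.green)
            grp.create_dataset("red", data=rois.red)
            grp.create_dataset("roi_ids", data=np.array(rois.roi_ids, dtype="S64"))
        if pupil is not None:
            grp = f.create_group("pupil")
            for name in ("area", "x", "y", "blink_area"):
                grp.create_dataset(name, data=getattr(pupil, name))
        if truth is not None:
            grp = f.create_group("truth")
            grp.create_dataset("freeze_mask", data=truth.freeze_mask.astype(bool))
            grp.create_dataset("transient_frames", data=truth.true_transient_frames.astype(np.int64))
            grp.create_dataset("tuning_state", data=np.asarray(truth.true_tuning_state, dtype=float))
            labels = truth.true_epochs.labels()
            grp.create_dataset("epoch_labels", data=np.array([str(s) for s in labels], dtype="S12"))


def load_session(path: str | Path) -> SessionBundle:
    """Read a session container back; optional groups come back as None."""
    try:
        f = h5py.File(path, "r")
    except OSError as exc:
        raise SchemaError(f"not a readable HDF5 container: {path}") from exc
    with f:
        if f.attrs.get(SCHEMA_ATTR) != SCHEMA_VERSION:
            raise SchemaError(
                f"container schema {f.attrs.get(SCHEMA_ATTR)!r} != expected {SCHEMA_VERSION}"
            )
        if "behavior" not in f:
            raise SchemaError("container is missing the /behavior group")
        beh = f["behavior"]
        session = SessionTimeseries(
            mouse_id=str(beh.attrs["mouse_id"]),
            day_id=str(beh.attrs["day_id"]),
            context_id=str(beh.attrs["context_id"]),
            t=beh["t"][:],
            position_cm=beh["position_cm"][:],
            velocity_cms=beh["velocity_cms"][:],
            teleport_flag=beh["teleport_flag"][:],
            shock_times_s=beh["shock_times_s"][:],
            shock_positions_cm=beh["shock_positions_cm"][:],
            frame_rate_hz=float(beh.attrs["frame_rate_hz"]),
        )
        rois = pupil = truth = None
        if "traces" in f:
            grp = f["traces"]
            rois = RoiTraceSet(
                roi_ids=[s.decode() for s in grp["roi_ids"][:]],
                green=grp["green"][:],
                red=grp["red"][:],
                frame_rate_hz=session.frame_rate_hz,
            )
        if "pupil" in f:
            grp = f["pupil"]
            pupil = PupilTraces(
                area=grp["area"][:],
                x=grp["x"][:],
                y=grp["y"][:],
                blink_area=grp["blink_area"][:],
                frame_rate_hz=session.frame_rate_hz,
            )
        if "truth" in f:
            grp = f["truth"]
            labels = np.array([s.decode() for s in grp["epoch_labels"][:]], dtype=object)
            truth = GroundTruth(
                true_epochs=epochs_from_labels(labels, session.frame_rate_hz, apply_min_lengths=False),
                freeze_mask=grp["freeze_mask"][:].astype(bool),
                true_transient_frames=grp["transient_frames"][:],
                true_tuning_state=grp["tuning_state"][:],
            )
    from .synthetic_data import GeneratorConfig

    return SessionBundle(session=session, truth=truth, rois=rois, pupil=pupil, config=GeneratorConfig())
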