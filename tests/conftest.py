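import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from freezecalc import behavior_features as bf
from freezecalc import synthetic_data as sd
from freezecalc import trace_processing as tp


@pytest.fixture(scope="session")
def tuned_bundle():
    """One post-conditioning (tuned) session, fully processed."""
    cfg = sd.cell_config(sd.CohortDesign(), "d1", "shocked")
    session, truth = sd.generate_session(cfg, seed=101)
    rois = sd.generate_axon_rois(cfg, truth, seed=102)
    epochs = bf.detect_epochs(session)
    axon, peaks, roi_ids = tp.process_roi_set(rois, n_shuffles=300, seed=103)
    return dict(
        config=cfg, session=session, truth=truth, rois=rois,
        epochs=epochs, axon=axon, peaks=peaks, roi_ids=roi_ids,
    )


@pytest.fixture(scope="session")
def untuned_bundle():
    """One pre-conditioning (untuned) session, fully processed."""
    cfg = sd.cell_config(sd.CohortDesign(), "pre", "shocked")
    session, truth = sd.generate_session(cfg, seed=201)
    rois = sd.generate_axon_rois(cfg, truth, seed=202)
    epochs = bf.detect_epochs(session)
    axon, peaks, roi_ids = tp.process_roi_set(rois, n_shuffles=300, seed=203)
    return dict(
        config=cfg, session=session, truth=truth, rois=rois,
        epochs=epochs, axon=axon, peaks=peaks, roi_ids=roi_ids,
    )


def make_session(velocity, teleport=None, frame_rate_hz=15.49, **kwargs):
    """Hand-built SessionTimeseries around a velocity trace."""
    velocity = np.asarray(velocity, dtype=float)
    n = len(velocity)
    teleport = np.zeros(n, dtype=bool) if teleport is None else np.asarray(teleport, bool)
    dt = 1.0 / frame_rate_hz
    position = np.clip(np.cumsum(np.where(teleport, 0.0, velocity)) * dt, 0.0, 200.0)
    defaults = dict(mouse_id="m0", day_id="pre", context_id="control")
    defaults.update(kwargs)
    return bf.SessionTimeseries(
        t=np.arange(n) * dt,
        position_cm=position,
        velocity_cms=velocity,
        teleport_flag=teleport,
        frame_rate_hz=frame_rate_hz,
        **defaults,
    )
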