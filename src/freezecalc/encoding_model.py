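"""Gradient-boosted-trees encoding model of axonal activity.

Predicts the normalized axon trace frame-by-frame from the behavioral
feature matrix with XGBoost regression trees.  The train/test unit is a
traversal ("lap"): frames are grouped by lap, laps are partitioned 80/20 at
random on every draw, and no frame of a test lap ever enters training.
Early stopping is evaluated against the held-out laps.  Goodness of fit is
the coefficient of determination r^2 = 1 - RSS/TSS computed on the test
laps (negative when the model is worse than predicting the mean).  Chance
level comes from refitting after permuting the target trace across laps.
Feature importances use the summed split gain, reported as fractions over
six behaviorally meaningful groups (freezing, velocities, running,
interval, location, pupil).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb

from .behavior_features import SessionTimeseries
from .exceptions import ConfigError, DegenerateTraceError

#: Behavioral feature groups used for gain-fraction reporting.
FEATURE_GROUPS: dict[str, list[str]] = {
    "freezing": [
        "freeze",
        "is_freezing",
        "freeze_remaining",
        "is_postfreeze",
        "freeze_progress",
        "freeze_elapsed",
    ],
    "velocities": [
        "recorded_velocity",
        "velocity_back_15",
        "velocity_back_8",
        "velocity_fwd_8",
        "velocity_fwd_15",
        "acceleration",
    ],
    "running": [
        "is_running",
        "running_progress",
        "running_remaining",
        "is_backtracking",
        "running_elapsed",
    ],
    "interval": ["interval_elapsed", "interval_remaining", "interval_progress"],
    "location": ["location"],
    "pupil": ["pupil_area", "pupil_x", "pupil_y"],
}


@dataclass
class ModelSpec:
    """Hyperparameters and run regime of the encoding model."""

    gamma: float = 1.0
    learning_rate: float = 0.01
    n_estimators: int = 1000
    base_score: float = 1.0
    early_stopping_rounds: int = 5
    seed: int = 42
    train_fraction: float = 0.8
    n_draws: int = 100

    def validate(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ConfigError("train_fraction must be in (0, 1)")
        if min(self.n_estimators, self.early_stopping_rounds, self.n_draws) < 1:
            raise ConfigError("counts must be positive")


@dataclass
class EncodingRunResult:
    """One train/test draw of the encoding model."""

    r2: float
    y_pred: np.ndarray  # predictions on test frames, in frame order
    test_frames: np.ndarray
    gains: dict[str, float]
    group_fractions: dict[str, float]
    null_r2: float | None = None
    best_iteration: int | None = None


def r_squared(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Coefficient of determination 1 - RSS/TSS (may be negative)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or len(y_true) < 2:
        raise ConfigError("need two equal-length vectors of >= 2 points")
    tss = float(np.sum((y_true - y_true.mean()) ** 2))
    if tss == 0:
        raise DegenerateTraceError("r^2 undefined for a constant target")
    rss = float(np.sum((y_true - y_pred) ** 2))
    return 1.0 - rss / tss


def lap_index(session: SessionTimeseries) -> np.ndarray:
    """Per-frame lap (traversal) index, delimited by teleport events.

    The lap counter advances when a teleport block ends; teleport frames are
    assigned to the lap they terminate, so every frame carries a lap id and
    lap-wise splits keep the teleport pause with its own traversal.
    """
    tel = np.asarray(session.teleport_flag, dtype=bool)
    laps = np.zeros(len(tel), dtype=int)
    lap = 0
    for i in range(1, len(tel)):
        if tel[i - 1] and not tel[i]:
            lap += 1
        laps[i] = lap
    return laps


def split_laps(
    lap_ids: np.ndarray, spec: ModelSpec, draw_seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Random 80/20 partition of lap identities for one draw."""
    spec.validate()
    laps = np.unique(lap_ids)
    if len(laps) < 5:
        raise ConfigError(f"need >= 5 laps to form a test set, got {len(laps)}")
    rng = np.random.default_rng(draw_seed)
    perm = rng.permutation(laps)
    n_test = max(1, int(round(len(laps) * (1 - spec.train_fraction))))
    return np.sort(perm[n_test:]), np.sort(perm[:n_test])


def shuffle_target_by_lap(
    y: np.ndarray, lap_ids: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Chance-level target: the trace permuted across laps.

    Each lap's frames receive the target values of another lap (a random
    derangement-free permutation), resized to the lap length, which destroys
    the frame-level behavior/activity correspondence while preserving the
    within-lap autocorrelation structure.
    """
    y = np.asarray(y, dtype=float)
    out = np.empty_like(y)
    laps = np.unique(lap_ids)
    perm = rng.permutation(laps)
    for lap, src in zip(laps, perm):
        mask = lap_ids == lap
        out[mask] = np.resize(y[lap_ids == src], mask.sum())
    return out


def _group_fractions(gains: dict[str, float]) -> dict[str, float]:
    totals = {
        group: sum(gains.get(name, 0.0) for name in names)
        for group, names in FEATURE_GROUPS.items()
    }
    grand = sum(totals.values())
    if grand <= 0:
        return {group: 0.0 for group in totals}
    return {group: v / grand for group, v in totals.items()}


def fit_predict(
    features: pd.DataFrame,
    target: np.ndarray,
    lap_ids: np.ndarray,
    train_laps: np.ndarray,
    test_laps: np.ndarray,
    spec: ModelSpec,
) -> EncodingRunResult:
    """Train on the train laps, early-stop and score on the test laps.

    Uses the configured boosted-trees hyperparameters; importances are the
    per-feature summed split gain, also aggregated into group fractions.
    Raises on a constant test-lap target (r^2 undefined).
    """
    spec.validate()
    target = np.asarray(target, dtype=float)
    if not np.isfinite(features.to_numpy()).all() or not np.isfinite(target).all():
        raise ConfigError("features and target must be finite")
    train_mask = np.isin(lap_ids, train_laps)
    test_mask = np.isin(lap_ids, test_laps)
    if np.intersect1d(train_laps, test_laps).size:
        raise ConfigError("train and test laps overlap")
    assert not (train_mask & test_mask).any(), "a frame appears in both splits"

    model = xgb.XGBRegressor(
        gamma=spec.gamma,
        learning_rate=spec.learning_rate,
        n_estimators=spec.n_estimators,
        base_score=spec.base_score,
        early_stopping_rounds=spec.early_stopping_rounds,
        random_state=spec.seed,
        verbosity=0,
    )
    X_train, X_test = features[train_mask], features[test_mask]
    y_train, y_test = target[train_mask], target[test_mask]
    model.fit(X_train, y_train, eval_set=[(X_test, y_test)], verbose=False)
    y_pred = model.predict(X_test)
    gains = model.get_booster().get_score(importance_type="total_gain")
    return EncodingRunResult(
        r2=r_squared(y_test, y_pred),
        y_pred=y_pred,
        test_frames=np.flatnonzero(test_mask),
        gains=gains,
        group_fractions=_group_fractions(gains),
        best_iteration=getattr(model, "best_iteration", None),
    )


def run_session(
    features: pd.DataFrame,
    target: np.ndarray,
    lap_ids: np.ndarray,
    spec: ModelSpec,
    n_draws: int | None = None,
    base_seed: int = 0,
    with_null: bool = True,
) -> pd.DataFrame:
    """Repeated encoding-model draws for one session.

    Each draw redraws the lap partition; with ``with_null`` the same split
    is refit on a lap-shuffled target to give the paired chance-level r^2.
    Returns one row per draw with r2, null_r2, and group gain fractions.
    """
    n_draws = spec.n_draws if n_draws is None else n_draws
    rows = []
    for draw in range(n_draws):
        draw_seed = base_seed + draw
        train_laps, test_laps = split_laps(lap_ids, spec, draw_seed)
        res = fit_predict(features, target, lap_ids, train_laps, test_laps, spec)
        null_r2 = np.nan
        if with_null:
            rng = np.random.default_rng(draw_seed + 1_000_003)
            y_null = shuffle_target_by_lap(target, lap_ids, rng)
            null = fit_predict(features, y_null, lap_ids, train_laps, test_laps, spec)
            null_r2 = null.r2
        row = {"draw": draw, "r2": res.r2, "null_r2": null_r2}
        row.update({f"gain_{g}": v for g, v in res.group_fractions.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def planned_runs(n_mice: int, n_days: int, n_contexts: int, n_draws: int) -> int:
    """Total model runs in a full per-mouse/day/context regime."""
    return n_mice * n_days * n_contexts * n_draws


def run_experiment(
    sessions: dict[tuple[str, str, str], tuple[pd.DataFrame, np.ndarray, np.ndarray]],
    spec: ModelSpec,
    n_draws: int | None = None,
    base_seed: int = 0,
    with_null: bool = True,
) -> pd.DataFrame:
    """Encoding-model runs over a cohort.

    ``sessions`` maps (mouse, day, context) to (features, target, lap_ids);
    sessions with too few laps are skipped with a notice column rather than
    aborting the cohort.  Returns the concatenated per-draw result table.
    """
    frames = []
    for i, (key, (features, target, lap_ids)) in enumerate(sorted(sessions.items())):
        mouse, day, context = key
        try:
            df = run_session(
                features, target, lap_ids, spec,
                n_draws=n_draws, base_seed=base_seed + 10_000 * i, with_null=with_null,
            )
        except ConfigError:
            continue
        df.insert(0, "mouse", mouse)
        df.insert(1, "day", day)
        df.insert(2, "context", context)
        frames.append(df)
    if not frames:
        raise ConfigError("no session could be fit")
    return pd.concat(frames, ignore_index=True)
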