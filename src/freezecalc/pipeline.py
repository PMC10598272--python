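"""End-to-end pipeline: simulate -> behavior -> traces -> tune -> encode -> report.

Stages operate on a generated cohort and write human-readable CSV tables
plus a JSON report stamped with the configuration hash and global seed.
Every stage can be toggled; disabling one simply omits its section from the
report.  All randomness derives from the single global seed, so a config +
seed pair reproduces the report bit-for-bit (timestamps aside).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior_features as bf
from . import encoding_model as em
from . import epoch_tuning as et
from . import synthetic_data as sd
from . import trace_processing as tp
from .exceptions import ConfigError
from .io import save_session

log = logging.getLogger("freezecalc")

DEFAULT_STAGES = ("simulate", "behavior", "traces", "tune", "encode")


@dataclass
class PipelineConfig:
    """Design, generator settings, stage toggles, output directory, seed."""

    n_mice: int = 4
    days: tuple[str, ...] = sd.DAYS
    contexts: tuple[str, ...] = sd.CONTEXTS
    inhibited: bool = False
    stages: tuple[str, ...] = DEFAULT_STAGES
    out_dir: str = "freezecalc_out"
    seed: int = 0
    n_draws: int = 5
    session_len_s: float = 322.0
    save_containers: bool = False
    generator_overrides: dict = field(default_factory=dict)

    def validate(self) -> None:
        unknown = set(self.stages) - set(DEFAULT_STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        for name in ("days", "contexts", "stages"):
            if name in known:
                known[name] = tuple(known[name])
        return cls(**known)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _design(config: PipelineConfig) -> sd.CohortDesign:
    base = sd.GeneratorConfig(session_len_s=config.session_len_s, **config.generator_overrides)
    return sd.CohortDesign(
        n_mice=config.n_mice,
        days=config.days,
        contexts=config.contexts,
        inhibited=config.inhibited,
        base_config=base,
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order and write the report bundle.

    Returns the report dict; artifacts land in ``config.out_dir``
    (behavior_summary.csv, tuning_summary.csv, encoding_results.csv,
    report.json, optional per-session HDF5 containers).
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_hash": config.config_hash(), "seed": config.seed}

    if "simulate" not in config.stages:
        raise ConfigError("the simulate stage is required to source data")
    log.info("simulate: generating %d-mouse cohort", config.n_mice)
    cohort = sd.generate_cohort(_design(config), seed=config.seed)
    if config.save_containers:
        for (mouse, day, context), bundle in cohort.items():
            save_session(
                out_dir / f"session_{mouse}_{day}_{context}.h5",
                bundle.session, bundle.rois, bundle.pupil, bundle.truth,
            )

    processed: dict[tuple[str, str, str], dict] = {}
    for key, bundle in cohort.items():
        entry: dict = {"bundle": bundle}
        if "behavior" in config.stages:
            entry["epochs"] = bf.detect_epochs(bundle.session)
        if "traces" in config.stages:
            axon, peaks, roi_ids = tp.process_roi_set(bundle.rois, seed=config.seed)
            entry.update(axon=axon, peaks=peaks, roi_ids=roi_ids)
        processed[key] = entry

    if "behavior" in config.stages:
        rows = []
        for (mouse, day, context), entry in processed.items():
            epochs = entry["epochs"]
            stats = bf.freeze_length_stats(epochs)
            rows.append(
                {
                    "mouse": mouse,
                    "day": day,
                    "context": context,
                    "pct_freezing": bf.percent_time_freezing(epochs),
                    "n_freeze_epochs": stats.count,
                    "mean_freeze_len_s": stats.mean_s,
                }
            )
        beh = pd.DataFrame(rows)
        base = beh[beh["day"] == "pre"].set_index(["mouse", "context"])["pct_freezing"]
        beh["delta_from_baseline"] = [
            bf.baseline_delta(r.pct_freezing, base.get((r.mouse, r.context), np.nan))
            for r in beh.itertuples()
        ]
        di_rows = []
        for (mouse, day), grp in beh.groupby(["mouse", "day"]):
            by_ctx = grp.set_index("context")["pct_freezing"]
            if {"shocked", "control"} <= set(by_ctx.index):
                try:
                    di = bf.discrimination_index(by_ctx["shocked"], by_ctx["control"])
                except ConfigError:
                    di = np.nan
                di_rows.append({"mouse": mouse, "day": day, "di": di})
        di = pd.DataFrame(di_rows)
        beh.to_csv(out_dir / "behavior_summary.csv", index=False)
        di.to_csv(out_dir / "discrimination_index.csv", index=False)
        by_cell = beh.groupby(["day", "context"])["pct_freezing"].mean().round(3)
        report["behavior"] = {
            "mean_pct_freezing_by_cell": {f"{d}/{c}": v for (d, c), v in by_cell.items()},
            "mean_di_by_day": di.groupby("day")["di"].mean().round(4).to_dict() if len(di) else {},
        }

    if "tune" in config.stages:
        if "traces" not in config.stages or "behavior" not in config.stages:
            raise ConfigError("tune requires the behavior and traces stages")
        rows = []
        for (mouse, day, context), entry in processed.items():
            sm = et.state_peak_means(entry["peaks"], entry["epochs"], entry["axon"])
            prof = et.progress_profile(entry["peaks"], entry["epochs"], entry["axon"])
            row = {
                "mouse": mouse, "day": day, "context": context,
                "freeze_mean": sm.freeze_mean, "run_mean": sm.run_mean,
                "n_freeze_epochs": prof.n_epochs,
            }
            row.update({f"profile_bin{i + 1}": v for i, v in enumerate(prof.bin_means)})
            rows.append(row)
        tune = pd.DataFrame(rows)
        tune.to_csv(out_dir / "tuning_summary.csv", index=False)
        post = tune[tune["day"] != "pre"]
        report["tuning"] = {
            "post_freeze_mean": round(float(post["freeze_mean"].mean()), 4),
            "post_run_mean": round(float(post["run_mean"].mean()), 4),
        }

    if "encode" in config.stages:
        if "traces" not in config.stages or "behavior" not in config.stages:
            raise ConfigError("encode requires the behavior and traces stages")
        spec = em.ModelSpec(n_draws=config.n_draws)
        sessions = {}
        for key, entry in processed.items():
            bundle = entry["bundle"]
            features = bf.compute_frame_features(
                bundle.session, entry["epochs"],
                pupil={"area": bundle.pupil.area, "x": bundle.pupil.x, "y": bundle.pupil.y},
            )
            sessions[key] = (features, entry["axon"].norm, em.lap_index(bundle.session))
        enc = em.run_experiment(sessions, spec, base_seed=config.seed, with_null=True)
        enc.to_csv(out_dir / "encoding_results.csv", index=False)
        pre = enc[enc["day"] == "pre"]["r2"]
        post = enc[enc["day"] != "pre"]["r2"]
        report["encoding"] = {
            "n_runs": int(len(enc)),
            "median_r2_pre": round(float(pre.median()), 4) if len(pre) else None,
            "median_r2_post": round(float(post.median()), 4) if len(post) else None,
            "median_null_r2": round(float(enc["null_r2"].median()), 4),
        }

    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    log.info("report written to %s", out_dir / "report.json")
    return report
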