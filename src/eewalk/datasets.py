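"""On-disk dataset layout: per-trial CSVs plus a JSON manifest.

Layout under a dataset directory::

    manifest.json                         subjects, trials, config hash
    imu/<trial>_<location>.csv            t_s,ax,ay,az,gx,gy,gz   (SI units)
    breath/<trial>.csv                    t_s,vo2_ml_min,vco2_ml_min

The manifest records each trial's condition, file paths, the simulator's
latent plateau (``latent_ee_w``) and the extracted steady-state ground
truth (``ee_truth_w``).  Loading reconstructs full ``Trial`` objects, so a
directory written by ``save_dataset`` round-trips through the entire
pipeline.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from . import metabolic
from .simulator import (
    Activity,
    BodyLocation,
    BreathSeries,
    IMURecording,
    Subject,
    Trial,
    TrialCondition,
)

__all__ = ["save_dataset", "load_dataset", "config_hash"]

MANIFEST = "manifest.json"


def config_hash(config: dict) -> str:
    """Stable short hash of a JSON-serializable configuration."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def save_dataset(trials: Sequence[Trial], out_dir, config: Optional[dict] = None) -> Path:
    """Write trials as CSVs plus a manifest; returns the manifest path."""
    out = Path(out_dir)
    (out / "imu").mkdir(parents=True, exist_ok=True)
    (out / "breath").mkdir(parents=True, exist_ok=True)

    subjects = {}
    trial_entries = []
    for trial in trials:
        s = trial.subject
        subjects[s.id] = {"id": s.id, "weight_kg": s.weight_kg, "height_m": s.height_m}

        imu_files = {}
        for loc, rec in trial.recordings.items():
            t = np.arange(rec.n_samples) / rec.sample_rate_hz
            df = pd.DataFrame(
                np.column_stack([t, rec.accel, rec.gyro]),
                columns=["t_s", "ax", "ay", "az", "gx", "gy", "gz"],
            )
            rel = f"imu/{trial.id}_{loc.value}.csv"
            df.to_csv(out / rel, index=False, float_format="%.6f")
            imu_files[loc.value] = rel

        breath_rel = f"breath/{trial.id}.csv"
        pd.DataFrame({
            "t_s": trial.breaths.times_s,
            "vo2_ml_min": trial.breaths.vo2_ml_min,
            "vco2_ml_min": trial.breaths.vco2_ml_min,
        }).to_csv(out / breath_rel, index=False, float_format="%.6f")

        cond = trial.condition
        trial_entries.append({
            "id": trial.id,
            "subject": s.id,
            "activity": cond.activity.value,
            "speed_kph": cond.speed_kph,
            "incline_pct": cond.incline_pct,
            "duration_s": cond.duration_s,
            "standing_margin_s": cond.standing_margin_s,
            "imu_files": imu_files,
            "breath_file": breath_rel,
            "latent_ee_w": trial.latent_ee_w,
            "ee_truth_w": metabolic.trial_ground_truth(trial.breaths, cond).ee_w,
        })

    manifest = {
        "subjects": sorted(subjects.values(), key=lambda d: d["id"]),
        "trials": trial_entries,
        "config_hash": config_hash(config or {}),
        "config": config or {},
    }
    path = out / MANIFEST
    path.write_text(json.dumps(manifest, indent=1))
    return path


def load_dataset(data_dir) -> List[Trial]:
    """Reconstruct Trial objects from a dataset directory."""
    root = Path(data_dir)
    manifest = json.loads((root / MANIFEST).read_text())
    subjects = {
        d["id"]: Subject(id=d["id"], weight_kg=d["weight_kg"], height_m=d["height_m"])
        for d in manifest["subjects"]
    }
    trials = []
    for entry in manifest["trials"]:
        cond = TrialCondition(
            activity=Activity(entry["activity"]),
            speed_kph=entry["speed_kph"],
            incline_pct=entry["incline_pct"],
            duration_s=entry["duration_s"],
            standing_margin_s=entry["standing_margin_s"],
        )
        recordings = {}
        for loc_name, rel in entry["imu_files"].items():
            df = pd.read_csv(root / rel)
            t = df["t_s"].to_numpy()
            fs = float(round(1.0 / np.median(np.diff(t)))) if len(t) > 1 else 100.0
            recordings[BodyLocation(loc_name)] = IMURecording(
                location=BodyLocation(loc_name),
                sample_rate_hz=fs,
                accel=df[["ax", "ay", "az"]].to_numpy(),
                gyro=df[["gx", "gy", "gz"]].to_numpy(),
            )
        bdf = pd.read_csv(root / entry["breath_file"])
        breaths = BreathSeries(
            times_s=bdf["t_s"].to_numpy(),
            vo2_ml_min=bdf["vo2_ml_min"].to_numpy(),
            vco2_ml_min=bdf["vco2_ml_min"].to_numpy(),
        )
        trials.append(Trial(
            subject=subjects[entry["subject"]],
            condition=cond,
            recordings=recordings,
            breaths=breaths,
            latent_ee_w=entry["latent_ee_w"],
            id=entry["id"],
        ))
    return trials
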