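"""CSV/YAML interchange.

One RFC-4180-style CSV per trial (columns ``time_s, emg_1..emg_8, fx, fy,
fz, mx, my, mz``), a dataset manifest CSV mapping trial files to participant,
class and clinical scores, and a YAML configuration mirroring the generator
and pipeline settings.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .core import TaskClass
from .preprocessing import RigidBodyGeometry, default_geometry
from .synthetic import GeneratorConfig, TrialRecording

TRIAL_COLUMNS = (["time_s"] + [f"emg_{i + 1}" for i in range(8)]
                 + ["fx", "fy", "fz", "mx", "my", "mz"])
_FLOAT_FMT = "%.10g"


def write_trial_csv(trial: TrialRecording, path) -> None:
    n = trial.emg.shape[0]
    t = np.arange(n) / trial.fs
    df = pd.DataFrame(np.column_stack([t, trial.emg, trial.loadcell]),
                      columns=TRIAL_COLUMNS)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_trial_csv(path, participant_id: str, task: TaskClass, fs: float,
                   acquisition_index: int = 0,
                   clinical_scores: dict | None = None) -> TrialRecording:
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return TrialRecording(
        participant_id=participant_id, task=task, fs=fs,
        emg=df[TRIAL_COLUMNS[1:9]].to_numpy(),
        loadcell=df[TRIAL_COLUMNS[9:]].to_numpy(),
        acquisition_index=acquisition_index, clinical_scores=clinical_scores)


def write_dataset(trials: Sequence[TrialRecording], out_dir) -> Path:
    """Write one CSV per trial plus ``manifest.csv``; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for trial in trials:
        fname = (f"{trial.participant_id}_{trial.task.code}"
                 f"_{trial.acquisition_index}.csv")
        write_trial_csv(trial, out_dir / fname)
        row = {"trial_file": fname, "participant_id": trial.participant_id,
               "class": trial.task.code, "fs": trial.fs,
               "acquisition_index": trial.acquisition_index}
        if trial.clinical_scores:
            row.update(trial.clinical_scores)
        rows.append(row)
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False, float_format=_FLOAT_FMT)
    return manifest


def read_dataset(manifest_path) -> list[TrialRecording]:
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path)
    score_cols = [c for c in df.columns
                  if c not in ("trial_file", "participant_id", "class", "fs",
                               "acquisition_index")]
    trials = []
    for _, row in df.iterrows():
        scores = {c: row[c] for c in score_cols if pd.notna(row[c])} or None
        if scores and "ue_fma" in scores:
            scores["ue_fma"] = int(scores["ue_fma"])
        trials.append(read_trial_csv(
            manifest_path.parent / row["trial_file"],
            participant_id=str(row["participant_id"]),
            task=TaskClass.from_code(row["class"]), fs=float(row["fs"]),
            acquisition_index=int(row.get("acquisition_index", 0)),
            clinical_scores=scores))
    return trials


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def geometry_to_dict(geom: RigidBodyGeometry) -> dict:
    return {"rotation": [float(v) for v in geom.rotation.ravel()],
            "lever_arm_shoulder": [float(v) for v in geom.lever_arm_shoulder],
            "lever_arm_elbow": [float(v) for v in geom.lever_arm_elbow],
            "axis_map": {k: list(v) for k, v in geom.axis_map.items()}}


def geometry_from_dict(d: dict) -> RigidBodyGeometry:
    kwargs = {"rotation": np.array(d["rotation"], float).reshape(3, 3),
              "lever_arm_shoulder": np.array(d["lever_arm_shoulder"], float),
              "lever_arm_elbow": np.array(d["lever_arm_elbow"], float)}
    if "axis_map" in d:
        kwargs["axis_map"] = {k: (v[0], int(v[1]), int(v[2]))
                              for k, v in d["axis_map"].items()}
    return RigidBodyGeometry(**kwargs)


def generator_config_to_dict(cfg: GeneratorConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["torque_direction_matrix"] = cfg.torque_direction_matrix.tolist()
    d["activation_matrix"] = cfg.activation_matrix.tolist()
    d["geometry"] = geometry_to_dict(cfg.geometry)
    return d


def generator_config_from_dict(d: dict) -> GeneratorConfig:
    d = dict(d)
    if "geometry" in d:
        d["geometry"] = geometry_from_dict(d["geometry"])
    else:
        d["geometry"] = default_geometry()
    for key in ("torque_direction_matrix", "activation_matrix"):
        if key in d:
            d[key] = np.array(d[key], float)
    return GeneratorConfig(**d)


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def save_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)


def config_hash(config: dict) -> str:
    """Short stable digest of a config mapping, for output provenance."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, header_comment: str,
                index: bool = True) -> None:
    """Write a CSV with a leading ``#`` provenance comment line."""
    with open(path, "w") as fh:
        fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=index, float_format=_FLOAT_FMT)
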