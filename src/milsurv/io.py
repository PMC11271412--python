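"""Tabular/report I/O and model checkpoints."""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd

from .model import Model, ModelConfig
from .synthetic import MOL_CLASSES, STAGES

RECORD_COLUMNS = ("patient_id", "time_years", "event", "mol_class", "stage")
CHECKPOINT_VERSION = 1


def read_records(path) -> pd.DataFrame:
    """Read and validate the patient record CSV.

    Required columns: patient_id, time_years, event, mol_class, stage;
    optional: treatment. Malformed rows raise with their line number
    (1-based, counting the header as line 1).
    """
    df = pd.read_csv(path)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"records file lacks column(s): {', '.join(missing)}")

    def bad(mask, msg):
        if mask.any():
            line = int(np.flatnonzero(mask)[0]) + 2
            raise ValueError(f"line {line}: {msg}")

    times = pd.to_numeric(df["time_years"], errors="coerce")
    bad(times.isna() | (times <= 0), "time_years must be a positive number")
    events = pd.to_numeric(df["event"], errors="coerce")
    bad(~events.isin([0, 1]), "event must be 0 or 1")
    bad(~df["mol_class"].isin(MOL_CLASSES),
        f"mol_class must be one of {MOL_CLASSES}")
    bad(~df["stage"].isin(STAGES), f"stage must be one of {STAGES}")
    if "treatment" in df.columns:
        treat = pd.to_numeric(df["treatment"], errors="coerce")
        bad(~treat.isin([0, 1]), "treatment must be 0 or 1")
        df["treatment"] = treat.astype(np.int64)
    df["time_years"] = times.astype(np.float64)
    df["event"] = events.astype(np.int64)
    return df


def write_records(records: pd.DataFrame, path) -> None:
    records.to_csv(path, index=False, float_format="%.9g")


def _round_floats(obj):
    """Fixed 9-significant-digit floats for diffable reports."""
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return float(f"{float(obj):.9g}")
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist())
    return obj


def write_report(report: dict, path) -> None:
    with open(path, "w") as f:
        json.dump(_round_floats(report), f, indent=2, sort_keys=True)
        f.write("\n")


def read_report(path) -> dict:
    with open(path) as f:
        return json.load(f)


def save_checkpoint(model: Model, path, extra: dict | None = None) -> None:
    """Versioned binary checkpoint: config header + parameter arrays."""
    header = {
        "version": CHECKPOINT_VERSION,
        "config": dataclasses.asdict(model.cfg),
        "extra": extra or {},
    }
    np.savez(path, __header__=np.frombuffer(
        json.dumps(header).encode(), dtype=np.uint8), **model.params)


def load_checkpoint(path) -> tuple[Model, dict]:
    with np.load(path) as data:
        if "__header__" not in data:
            raise ValueError("not a model checkpoint: missing header")
        header = json.loads(bytes(data["__header__"]).decode())
        if header.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {header.get('version')}")
        cfgd = header["config"]
        for key in ("encoder_dims", "fused_hidden", "modalities"):
            cfgd[key] = tuple(cfgd[key])
        cfg = ModelConfig(**cfgd)
        params = {k: data[k] for k in data.files if k != "__header__"}
    return Model(cfg, params), header.get("extra", {})
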