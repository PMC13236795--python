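"""Plain-text serialization: per-trial signal tables, schedules, config.

Records are tab-separated tables with a ``# key\tvalue`` header block
(sampling rate, face onset, mass, trial metadata) followed by the four signal
columns ``time_s  Fy_N  Fz_N  Mx_Nm``. Everything is human-readable text.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import ForcePlateRecord

_META_KEYS = (
    "participant_id",
    "face_id",
    "emotion",
    "condition",
    "group",
    "trial_type",
    "presentation_index",
    "stepping_limb",
    "dominant_limb",
    "artifact",
)


def write_record(record: ForcePlateRecord, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# sampling_rate\t{record.sampling_rate}\n")
        fh.write(f"# face_onset\t{record.face_onset}\n")
        fh.write(f"# mass\t{record.mass}\n")
        fh.write(f"# z_offset\t{record.z_offset}\n")
        for k in _META_KEYS:
            if k in record.meta and record.meta[k] is not None:
                fh.write(f"# {k}\t{record.meta[k]}\n")
        fh.write("time_s\tFy_N\tFz_N\tMx_Nm\n")
        np.savetxt(
            fh,
            np.column_stack([record.time, record.fy, record.fz, record.mx]),
            fmt="%.6f\t%.6f\t%.6f\t%.6f",
        )


def read_record(path: str | Path) -> ForcePlateRecord:
    path = Path(path)
    header: dict[str, str] = {}
    n_header = 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("# "):
                break
            key, _, val = line[2:].rstrip("\n").partition("\t")
            header[key] = val
            n_header += 1
    data = np.loadtxt(path, skiprows=n_header + 1)
    meta = {k: header[k] for k in _META_KEYS if k in header}
    if "presentation_index" in meta:
        meta["presentation_index"] = int(meta["presentation_index"])
    return ForcePlateRecord(
        time=data[:, 0],
        fy=data[:, 1],
        fz=data[:, 2],
        mx=data[:, 3],
        sampling_rate=float(header["sampling_rate"]),
        face_onset=float(header["face_onset"]),
        mass=float(header["mass"]),
        z_offset=float(header.get("z_offset", 0.0)),
        meta=meta,
    )


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def load_config(path: str | Path) -> dict:
    """Flat key-value run configuration (YAML)."""
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a flat key-value mapping")
    return cfg


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with Path(path).open("w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
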