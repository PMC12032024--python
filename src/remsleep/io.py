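"""On-disk formats: hypnogram CSV dialect, event CSV, clinical CSV, metrics CSV.

The hypnogram dialect is a CSV with header ``epoch,stage`` (0-based epoch
index, stage token) preceded by ``#key=value`` comment lines carrying the
session metadata (``subject_id``, ``night``, ``lights_out``, ``lights_on``
as HH:MM:SS).  Stage tokens pass through the configurable stage map, so
AASM-labelled files (N1/N2/N3, R) read directly.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import MalformedFile
from .events import EyeMovementEvent
from .hypnogram import Hypnogram, map_stages


def _parse_time(s: str) -> _dt.time:
    return _dt.time.fromisoformat(s.strip())


def read_hypnogram_file(path, stage_map: Optional[dict] = None) -> Hypnogram:
    """Read the hypnogram CSV dialect; unknown stage tokens raise with the
    offending rows listed."""
    path = Path(path)
    meta: dict[str, str] = {}
    header_seen = False
    epochs: list[tuple[int, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "=" in line:
                    k, v = line[1:].split("=", 1)
                    meta[k.strip()] = v.strip()
                continue
            if not header_seen:
                if line.lower().replace(" ", "") != "epoch,stage":
                    raise MalformedFile(
                        f"{path}:{lineno}: expected header 'epoch,stage', got {line!r}"
                    )
                header_seen = True
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise MalformedFile(f"{path}:{lineno}: expected two fields, got {line!r}")
            epochs.append((int(parts[0]), parts[1]))
    if not header_seen or not epochs:
        raise MalformedFile(f"{path}: no epoch rows found")
    epochs.sort(key=lambda r: r[0])
    if [e for e, _ in epochs] != list(range(len(epochs))):
        raise MalformedFile(f"{path}: epoch indices must be 0..n-1 without gaps")
    try:
        stages = map_stages([s for _, s in epochs], stage_map)
    except ValueError as exc:
        raise MalformedFile(f"{path}: {exc}") from exc
    lo = _parse_time(meta["lights_out"]) if "lights_out" in meta else None
    lon = _parse_time(meta["lights_on"]) if "lights_on" in meta else None
    return Hypnogram(
        stages=tuple(stages),
        subject_id=meta.get("subject_id", path.stem),
        night=meta.get("night", "baseline"),
        lights_out=lo,
        lights_on=lon,
    )


def write_hypnogram_file(hyp: Hypnogram, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"#subject_id={hyp.subject_id}\n#night={hyp.night}\n")
        if hyp.lights_out is not None:
            fh.write(f"#lights_out={hyp.lights_out.isoformat()}\n")
        if hyp.lights_on is not None:
            fh.write(f"#lights_on={hyp.lights_on.isoformat()}\n")
        fh.write("epoch,stage\n")
        for i, s in enumerate(hyp.stages):
            fh.write(f"{i},{s}\n")


def read_events_file(path) -> list[EyeMovementEvent]:
    """Event CSV: ``time_s,amplitude_uv,channel``."""
    df = pd.read_csv(path)
    required = {"time_s", "amplitude_uv", "channel"}
    if not required.issubset(df.columns):
        raise MalformedFile(f"{path}: expected columns {sorted(required)}")
    return [
        EyeMovementEvent(float(r.time_s), float(r.amplitude_uv), str(r.channel))
        for r in df.itertuples()
    ]


def write_events_file(events: list[EyeMovementEvent], path) -> None:
    pd.DataFrame(
        {
            "time_s": [e.time_s for e in events],
            "amplitude_uv": [e.amplitude_uv for e in events],
            "channel": [e.channel for e in events],
        }
    ).to_csv(path, index=False)


def read_clinical_file(path) -> pd.DataFrame:
    """Clinical CSV: ``subject_id,group,hamd_baseline,hamd_day1``."""
    df = pd.read_csv(path)
    required = {"subject_id", "group", "hamd_baseline"}
    if not required.issubset(df.columns):
        raise MalformedFile(f"{path}: expected columns {sorted(required)}")
    if "hamd_day1" not in df.columns:
        df["hamd_day1"] = np.nan
    return df


def write_metrics_file(metrics: pd.DataFrame, path) -> None:
    metrics.to_csv(path, index=False)


def read_metrics_file(path) -> pd.DataFrame:
    return pd.read_csv(path)
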