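"""CSV formats, run configuration, and reproducibility sidecars.

Conventions used by every file the package reads or writes: timestamps are
ISO-8601, glucose is mg/dl, insulin is U, carbohydrate is g.  Output files
embed the seed and a hash of the configuration that produced them as
``#``-prefixed header comments, which the readers skip.
"""

from __future__ import annotations

import csv
import dataclasses
import datetime as dt
import hashlib
import json
import warnings
from pathlib import Path

import pandas as pd
import yaml

from .pig import PigParams, REFERENCE_PIGS, SensorModel, SimTrace
from .protocol import ChallengeSchedule

__all__ = [
    "TraceFormatError",
    "read_trace",
    "write_trace",
    "write_events",
    "RunConfig",
    "load_run_config",
    "config_hash",
    "BASE_TIME",
]

#: Reference wall-clock for converting simulation minutes to timestamps
#: (simulations start at 01:00).
BASE_TIME = dt.datetime(2019, 8, 1, 1, 0, 0)


class TraceFormatError(ValueError):
    """A glucose-trace CSV is malformed; the message names the line."""


def read_trace(path) -> pd.DataFrame:
    """Read a glucose trace CSV: header + (ISO-8601 timestamp, mg/dl) rows.

    Returns a DataFrame with columns ``time`` (datetime) and
    ``glucose_mgdl`` (float), sorted by time.  Unsorted input is sorted
    with a warning; duplicate timestamps are an error.
    """
    path = Path(path)
    times: list[dt.datetime] = []
    values: list[float] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header_seen = False
        for lineno, row in enumerate(reader, start=1):
            if not row or row[0].lstrip().startswith("#"):
                continue
            if not header_seen:
                header_seen = True  # column names are free; order is fixed
                continue
            if len(row) < 2:
                raise TraceFormatError(f"{path} line {lineno}: expected 2 columns")
            try:
                t = dt.datetime.fromisoformat(row[0].strip())
            except ValueError as exc:
                raise TraceFormatError(
                    f"{path} line {lineno}: bad timestamp {row[0]!r}"
                ) from exc
            try:
                v = float(row[1])
            except ValueError as exc:
                raise TraceFormatError(
                    f"{path} line {lineno}: bad glucose {row[1]!r}"
                ) from exc
            times.append(t)
            values.append(v)
    if not header_seen:
        raise TraceFormatError(f"{path}: missing header row")
    df = pd.DataFrame({"time": times, "glucose_mgdl": values})
    if df["time"].duplicated().any():
        dup = df["time"][df["time"].duplicated()].iloc[0]
        raise TraceFormatError(f"{path}: duplicate timestamp {dup.isoformat()}")
    if not df["time"].is_monotonic_increasing:
        warnings.warn(f"{path}: readings were not time-ordered; sorting",
                      stacklevel=2)
        df = df.sort_values("time", ignore_index=True)
    return df


def _header_comments(fh, seed, cfg_hash) -> None:
    if seed is not None:
        fh.write(f"# seed={seed}\n")
    if cfg_hash is not None:
        fh.write(f"# config={cfg_hash}\n")


def write_trace(df: pd.DataFrame, path, seed=None, cfg_hash=None) -> None:
    """Write a readings DataFrame (time, glucose_mgdl) with sidecar comments."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        _header_comments(fh, seed, cfg_hash)
        fh.write("time,glucose_mgdl\n")
        for _, row in df.iterrows():
            fh.write(f"{row['time'].isoformat()},{row['glucose_mgdl']:.1f}\n")


def write_events(trace: SimTrace, path, seed=None, cfg_hash=None,
                 base_time: dt.datetime = BASE_TIME) -> None:
    """Write the dose/carb event log of a trace as CSV."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        _header_comments(fh, seed, cfg_hash)
        fh.write("time,kind,amount,unit,note\n")
        for ev in trace.events:
            ts = (base_time + dt.timedelta(minutes=float(ev.time))).isoformat()
            fh.write(f"{ts},{ev.kind},{ev.amount:.4f},{ev.unit},{ev.note}\n")


def trace_frame(trace: SimTrace, base_time: dt.datetime = BASE_TIME,
                cgm: bool = True) -> pd.DataFrame:
    """CGM readings (default) or minute ground truth as a (time, mg/dl) frame."""
    if cgm:
        minutes, values = trace.cgm_times, trace.cgm_values
    else:
        minutes, values = trace.true_minutes, trace.true_glucose
    times = [base_time + dt.timedelta(minutes=float(m)) for m in minutes]
    return pd.DataFrame({"time": times, "glucose_mgdl": values})


# -- run configuration ---------------------------------------------------

_ALLOWED_KEYS = {
    "pigs", "controller", "controller_overrides", "days", "seed",
    "sensor", "schedule", "outdir",
}
_PIG_KEYS = {"id", "basal_rate", "isf", "icr"}
_SENSOR_KEYS = {"interval", "noise_sd", "bias", "floor", "ceiling"}
_SCHEDULE_KEYS = {f.name for f in dataclasses.fields(ChallengeSchedule)}


@dataclasses.dataclass
class RunConfig:
    """Validated simulation run configuration."""

    pigs: tuple[PigParams, ...] = REFERENCE_PIGS
    controller: str = "oref1"
    controller_overrides: dict = dataclasses.field(default_factory=dict)
    days: int = 3
    seed: int = 0
    sensor: SensorModel = dataclasses.field(default_factory=SensorModel)
    schedule: ChallengeSchedule = dataclasses.field(default_factory=ChallengeSchedule)
    outdir: str = "."


def _reject_unknown(mapping: dict, allowed: set, where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ValueError(f"unknown {where} keys: {sorted(unknown)}")


def load_run_config(path) -> RunConfig:
    """Load and validate a YAML run configuration; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    _reject_unknown(raw, _ALLOWED_KEYS, "config")
    cfg = RunConfig()
    if "pigs" in raw and raw["pigs"] != "reference":
        pigs = []
        for entry in raw["pigs"]:
            _reject_unknown(entry, _PIG_KEYS, "pig")
            pigs.append(PigParams(str(entry["id"]), float(entry["basal_rate"]),
                                  float(entry["isf"]), float(entry["icr"])))
        cfg.pigs = tuple(pigs)
    if "controller" in raw:
        if raw["controller"] not in ("oref1", "loop"):
            raise ValueError(f"controller must be 'oref1' or 'loop', "
                             f"got {raw['controller']!r}")
        cfg.controller = raw["controller"]
    if "controller_overrides" in raw:
        cfg.controller_overrides = dict(raw["controller_overrides"])
    if "days" in raw:
        cfg.days = int(raw["days"])
        if cfg.days < 1:
            raise ValueError("days must be >= 1")
    if "seed" in raw:
        cfg.seed = int(raw["seed"])
    if "sensor" in raw:
        _reject_unknown(raw["sensor"], _SENSOR_KEYS, "sensor")
        cfg.sensor = dataclasses.replace(SensorModel(), **raw["sensor"])
    if "schedule" in raw:
        _reject_unknown(raw["schedule"], _SCHEDULE_KEYS, "schedule")
        cfg.schedule = dataclasses.replace(ChallengeSchedule(), **raw["schedule"])
    if "outdir" in raw:
        cfg.outdir = str(raw["outdir"])
    return cfg


def config_hash(cfg: RunConfig) -> str:
    """Short stable hash of a run configuration."""
    payload = {
        "pigs": [dataclasses.asdict(p) for p in cfg.pigs],
        "controller": cfg.controller,
        "controller_overrides": cfg.controller_overrides,
        "days": cfg.days,
        "seed": cfg.seed,
        "sensor": dataclasses.asdict(cfg.sensor),
        "schedule": dataclasses.asdict(cfg.schedule),
    }
    digest = hashlib.sha256(json.dumps(payload, sort_keys=True).encode())
    return digest.hexdigest()[:12]
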