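"""File formats and run manifests.

Everything is plain text: event streams and binned series as CSV (with a
JSON sidecar for event-stream metadata), trajectories as CSV, configurations
as YAML, manifests as JSON. Floats are written with a fixed format so a
rerun with the same seed produces byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import RunConfig
from .gating import BinnedSeries
from .instrument import EventStream
from .reactor import Trajectory

__all__ = [
    "write_event_stream", "read_event_stream",
    "write_binned_series", "read_binned_series",
    "write_trajectory", "read_trajectory",
    "write_config", "RunManifest", "sha256_of",
]

_FLOAT_FMT = "%.10g"


def write_event_stream(stream: EventStream, path: str | Path) -> Path:
    """Write events to CSV (time_ms, fl1, fl3) plus a JSON metadata sidecar."""
    path = Path(path)
    pd.DataFrame({"time_ms": stream.time_ms, "fl1": stream.fl1,
                  "fl3": stream.fl3}).to_csv(path, index=False,
                                             float_format=_FLOAT_FMT)
    meta = dict(stream.metadata)
    meta["staining_mode"] = stream.staining_mode
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return path


def read_event_stream(path: str | Path) -> EventStream:
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    mode = meta.get("staining_mode", "SG")
    return EventStream(staining_mode=mode,
                       time_ms=df["time_ms"].to_numpy(float),
                       fl1=df["fl1"].to_numpy(float),
                       fl3=df["fl3"].to_numpy(float),
                       metadata=meta)


def write_binned_series(series: BinnedSeries, path: str | Path) -> Path:
    path = Path(path)
    df = series.to_frame()
    df.insert(0, "staining_mode", series.staining_mode)
    df["bin_width_s"] = series.bin_width_s
    df["alignment_offset_min"] = series.alignment_offset_min
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_binned_series(path: str | Path) -> BinnedSeries:
    df = pd.read_csv(path)
    return BinnedSeries(
        staining_mode=str(df["staining_mode"].iloc[0]),
        bin_width_s=float(df["bin_width_s"].iloc[0]),
        bin_start_min=df["bin_start_min"].to_numpy(float),
        lna_count=df["lna_count"].to_numpy(int),
        hna_count=df["hna_count"].to_numpy(int),
        background_count=df["background_count"].to_numpy(int),
        concentration=df["concentration"].to_numpy(float),
        pct_lna=df["pct_lna"].to_numpy(float),
        pct_hna=df["pct_hna"].to_numpy(float),
        fingerprint_defined=df["fingerprint_defined"].to_numpy(bool),
        alignment_offset_min=float(df["alignment_offset_min"].iloc[0]),
    )


def write_trajectory(traj: Trajectory, path: str | Path) -> Path:
    path = Path(path)
    traj.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_trajectory(path: str | Path) -> Trajectory:
    return Trajectory.from_frame(pd.read_csv(path))


def write_config(config: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(config.model_dump(mode="json"),
                                   sort_keys=True))
    return path


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Record of one replay: inputs, seed, outputs and their checksums."""

    seed: int
    config_path: str | None = None
    package_version: str = __version__
    files: dict[str, str] = field(default_factory=dict)   # role -> path
    checksums: dict[str, str] = field(default_factory=dict)
    completed_stages: list[str] = field(default_factory=list)
    failed_stage: str | None = None

    def add_file(self, role: str, path: str | Path) -> None:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"manifest file missing: {path}")
        self.files[role] = str(path)
        self.checksums[role] = sha256_of(path)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "seed": self.seed,
            "config_path": self.config_path,
            "package_version": self.package_version,
            "files": self.files,
            "checksums": self.checksums,
            "completed_stages": self.completed_stages,
            "failed_stage": self.failed_stage,
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        return path

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        d = json.loads(Path(path).read_text())
        return cls(seed=d["seed"], config_path=d.get("config_path"),
                   package_version=d.get("package_version", ""),
                   files=d.get("files", {}), checksums=d.get("checksums", {}),
                   completed_stages=d.get("completed_stages", []),
                   failed_stage=d.get("failed_stage"))
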