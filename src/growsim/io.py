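"""Configuration files, trajectory/state readers and writers, run manifests.

All numeric output is plain text at full double precision (17 significant
digits), so every file the package writes can be read back bit-exactly.
A trajectory CSV is never written without a JSON manifest sidecar carrying
the fully resolved configuration, version, wall times, and SHA-256
checksums of the written files — the manifest alone suffices to reproduce
a run.  Coordinates are dimensionless model units throughout.
"""

from __future__ import annotations

import dataclasses
import difflib
import hashlib
import io as _io
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .geometry import OrganState
from .simulate import SimulationConfig, TrajectoryRecord

__all__ = [
    "ConfigError",
    "RunManifest",
    "load_config",
    "save_state",
    "load_state",
    "write_trajectory",
    "read_trajectory",
]

_FLOAT_FMT = "%.17g"

_CONFIG_FIELDS = {f.name: f for f in dataclasses.fields(SimulationConfig)}


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


@dataclasses.dataclass
class RunManifest:
    """Sidecar metadata identifying a written trajectory."""

    config: dict
    version: str
    start_time: float
    end_time: float
    files: dict  # filename -> {"sha256": ..., "bytes": ...}
    units: str = "dimensionless model units"

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


def _coerce(name: str, raw):
    """Coerce a raw config value to the type of the corresponding field."""
    default = _CONFIG_FIELDS[name].default
    if isinstance(raw, str):
        try:
            raw = yaml.safe_load(raw)
        except yaml.YAMLError:
            pass
    if name in ("stimulus_direction", "source_point", "line_base", "line_direction"):
        vec = tuple(float(x) for x in raw)
        if len(vec) != 3:
            raise ConfigError(f"{name} must have 3 components, got {len(vec)}")
        return vec
    if isinstance(default, bool):
        if isinstance(raw, bool):
            return raw
        raise ConfigError(f"{name} must be a boolean, got {raw!r}")
    if isinstance(default, int) and not isinstance(default, bool):
        if isinstance(raw, float) and raw != int(raw):
            raise ConfigError(f"{name} must be an integer, got {raw!r}")
        return int(raw)
    if isinstance(default, float) or name == "omega":
        if raw is None:
            return None
        return float(raw)
    if name == "random_seed":
        return None if raw is None else int(raw)
    return raw


def load_config(
    path: str | Path | None = None, overrides: list[str] | dict | None = None
) -> SimulationConfig:
    """Build a fully resolved configuration from a YAML file plus overrides.

    ``overrides`` may be a dict or a list of ``key=value`` strings (CLI
    style).  Unknown keys are rejected with the nearest valid key
    suggested; the step-size constraint ``ds = Lgz * Edot * dt`` is
    enforced at this stage.
    """
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        values.update(loaded)
    if overrides:
        if isinstance(overrides, dict):
            values.update(overrides)
        else:
            for item in overrides:
                if "=" not in item:
                    raise ConfigError(f"override {item!r} is not of the form key=value")
                key, _, val = item.partition("=")
                values[key.strip()] = val.strip()

    kwargs = {}
    for key, raw in values.items():
        if key not in _CONFIG_FIELDS:
            hint = difflib.get_close_matches(key, _CONFIG_FIELDS, n=1)
            suggestion = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ConfigError(f"unknown config key {key!r}{suggestion}")
        kwargs[key] = _coerce(key, raw)
    try:
        return SimulationConfig(**kwargs)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


# ---------------------------------------------------------------------------
# organ state serialization: CSV table with a JSON header comment line


def save_state(state: OrganState, path: str | Path) -> None:
    """Write an organ state as CSV (n, kappa1, kappa2) with a JSON header line."""
    header = {
        "ds": state.ds,
        "radius": state.radius,
        "growth_zone_length": state.growth_zone_length,
        "base_frame": state.base_frame.tolist(),
        "base_position": state.base_position.tolist(),
    }
    df = pd.DataFrame(
        {
            "n": np.arange(state.n_segments),
            "kappa1": state.kappa1,
            "kappa2": state.kappa2,
        }
    )
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(header) + "\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def load_state(path: str | Path) -> OrganState:
    """Read back a state written by :func:`save_state` (bit-exact round trip)."""
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# "):
            raise ValueError(f"{path} is missing the JSON header line")
        header = json.loads(first[2:])
        df = pd.read_csv(fh, float_precision="round_trip")
    return OrganState(
        kappa1=df["kappa1"].to_numpy(),
        kappa2=df["kappa2"].to_numpy(),
        ds=header["ds"],
        base_frame=np.asarray(header["base_frame"]),
        base_position=np.asarray(header["base_position"]),
        growth_zone_length=header["growth_zone_length"],
        radius=header["radius"],
    )


# ---------------------------------------------------------------------------
# trajectory CSV + manifest


def _record_frame(record: TrajectoryRecord) -> pd.DataFrame:
    rows = []
    for snap in record.snapshots:
        n = snap.state.n_segments
        rows.append(
            pd.DataFrame(
                {
                    "step": snap.step,
                    "time": snap.time,
                    "n": np.arange(n),
                    "x": snap.positions[:n, 0],
                    "y": snap.positions[:n, 1],
                    "z": snap.positions[:n, 2],
                    "kappa1": snap.state.kappa1,
                    "kappa2": snap.state.kappa2,
                    "kappa": snap.kappa,
                    "phi": snap.phi,
                    "tau": snap.tau,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def write_trajectory(record: TrajectoryRecord, path: str | Path) -> RunManifest:
    """Write trajectory CSV plus its JSON manifest sidecar.

    The manifest path is the CSV path with ``.manifest.json`` appended to
    the stem.  Returns the manifest.
    """
    if not record.snapshots:
        raise ValueError("cannot write an empty trajectory record")
    path = Path(path)
    start = time.time()
    df = _record_frame(record)
    buf = _io.StringIO()
    df.to_csv(buf, index=False, float_format=_FLOAT_FMT)
    data = buf.getvalue().encode()
    path.write_bytes(data)
    manifest = RunManifest(
        config=record.config.to_dict(),
        version=__version__,
        start_time=start,
        end_time=time.time(),
        files={
            path.name: {
                "sha256": hashlib.sha256(data).hexdigest(),
                "bytes": len(data),
            }
        },
    )
    manifest_path(path).write_text(manifest.to_json())
    return manifest


def manifest_path(trajectory_path: str | Path) -> Path:
    trajectory_path = Path(trajectory_path)
    return trajectory_path.with_name(trajectory_path.stem + ".manifest.json")


def read_trajectory(path: str | Path) -> tuple[pd.DataFrame, RunManifest]:
    """Read a trajectory CSV and its manifest, verifying the checksum."""
    path = Path(path)
    data = path.read_bytes()
    raw = json.loads(manifest_path(path).read_text())
    manifest = RunManifest(**raw)
    expected = manifest.files[path.name]["sha256"]
    actual = hashlib.sha256(data).hexdigest()
    if actual != expected:
        raise ValueError(
            f"checksum mismatch for {path.name}: manifest {expected}, file {actual}"
        )
    return pd.read_csv(_io.BytesIO(data), float_precision="round_trip"), manifest
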