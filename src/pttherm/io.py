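"""Reading and writing thermograph stacks, temperature traces and result tables.

Interchange formats are deliberately plain: multi-page TIFF (float32 °C per
pixel, or uint16 counts plus a linear scale/offset in a JSON sidecar), CSV
temperature traces, and CSV result tables with a schema-version header line.
Proprietary radiometric camera formats are out of scope; calibration to °C is
assumed to happen upstream.

Time convention: t = 0 is laser-on. Frames recorded before the laser fires
carry negative times so baseline extraction can use them.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

RESULTS_SCHEMA_HEADER = "# pttherm-results v1"

TRACE_COLUMNS = ["time_s", "temp_mean_C", "temp_sd_C", "animal_id", "group"]


@dataclass
class ThermalFrameStack:
    """Time-ordered stack of temperature-calibrated frames.

    frames are indexed (frame, row, col) and hold temperature in °C.
    ``laser_on_index`` is the frame at which the exposure starts, so frame k
    corresponds to time ``(k - laser_on_index) * frame_period_s``.
    """

    frames: np.ndarray
    frame_period_s: float
    laser_on_index: int = 0
    source_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be 3-D (frame, row, col), got ndim={self.frames.ndim}")
        if self.frame_period_s <= 0:
            raise ValueError(f"frame_period_s must be positive, got {self.frame_period_s}")
        if not 0 <= self.laser_on_index < self.frames.shape[0]:
            raise ValueError(
                f"laser_on_index {self.laser_on_index} outside [0, {self.frames.shape[0]})"
            )
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("stack contains non-finite temperatures")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, cols) of a single frame."""
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Per-frame time in seconds relative to laser-on."""
        k = np.arange(self.n_frames)
        return (k - self.laser_on_index) * self.frame_period_s


@dataclass
class TemperatureTrace:
    """ROI mean ± SD temperature versus time for one animal.

    ``temp_sd`` is the spatial spread over the ROI per frame (population SD),
    not the uncertainty of the mean. ``group`` is (wavelength nm, injection).
    ``meta`` carries non-serialized annotations such as simulation ground
    truth; it is never written to CSV.
    """

    times: np.ndarray
    temp_mean: np.ndarray
    temp_sd: np.ndarray
    animal_id: str = ""
    group: tuple[int, str] | None = None
    meta: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.temp_mean = np.asarray(self.temp_mean, dtype=np.float64)
        self.temp_sd = np.asarray(self.temp_sd, dtype=np.float64)
        n = len(self.times)
        if len(self.temp_mean) != n or len(self.temp_sd) != n:
            raise ValueError("times, temp_mean and temp_sd must have equal lengths")
        if n > 1 and not np.all(np.diff(self.times) > 0):
            bad = int(np.flatnonzero(np.diff(self.times) <= 0)[0]) + 1
            raise ValueError(
                f"times must be strictly increasing (violation at sample {bad}, "
                f"animal_id={self.animal_id!r})"
            )
        if np.any(self.temp_sd < 0):
            raise ValueError("temp_sd must be non-negative")

    def __len__(self) -> int:
        return len(self.times)

    def window(self, t_min: float = 0.0, t_max: float | None = None) -> "TemperatureTrace":
        """Sub-trace restricted to t_min ≤ t ≤ t_max (t_max=None keeps the tail)."""
        sel = self.times >= t_min
        if t_max is not None:
            sel &= self.times <= t_max
        return TemperatureTrace(
            self.times[sel], self.temp_mean[sel], self.temp_sd[sel],
            animal_id=self.animal_id, group=self.group, meta=self.meta,
        )


@dataclass
class RunConfig:
    """Configuration of an end-to-end analysis run."""

    roi_diameter_px: int = 30
    exposure_s: float = 90.0
    seed: int = 0
    simulate: bool = True
    stacks: bool = False
    traces_path: str | None = None
    outdir: str = "results"
    span_floor_C: float = 1.0
    weighted_fit: bool = False
    alpha: float = 0.05
    groups: list | None = None  # list of synth.SimGroupParams; None → study defaults
    camera: dict = field(default_factory=dict)
    scene: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.roi_diameter_px < 1:
            raise ValueError("roi_diameter_px must be ≥ 1")
        if self.exposure_s <= 0:
            raise ValueError("exposure_s must be positive")


def _group_to_str(group: tuple[int, str] | None) -> str:
    if group is None:
        return ""
    return f"{group[0]}nm_{group[1]}"


def parse_group(label: str) -> tuple[int, str] | None:
    """Parse a '808nm_GNR'-style group label back to (wavelength, injection)."""
    if not label:
        return None
    wl, injection = label.split("nm_", 1)
    return int(wl), injection


# ---------------------------------------------------------------------------
# Thermograph stacks


def _sidecar_path(path: Path, metadata_path: str | Path | None) -> Path:
    if metadata_path is not None:
        return Path(metadata_path)
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack: ThermalFrameStack, path: str | Path,
                metadata_path: str | Path | None = None) -> None:
    """Write a stack as a float32 multi-page TIFF plus a JSON sidecar.

    The sidecar records the frame period and the laser-on frame index so the
    time axis survives the round trip.
    """
    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype(np.float32), photometric="minisblack")
    meta = {
        "frame_period_s": stack.frame_period_s,
        "laser_on_index": stack.laser_on_index,
        "source_id": stack.source_id,
        "units": "C",
    }
    _sidecar_path(path, metadata_path).write_text(json.dumps(meta, indent=1))


def read_stack(path: str | Path, metadata_path: str | Path | None = None) -> ThermalFrameStack:
    """Read a thermograph stack, calibrating to °C.

    Float pages are taken as °C directly. Integer pages require ``scale`` and
    ``offset`` keys in the JSON sidecar and are converted as
    ``temp = counts * scale + offset``.
    """
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    meta: dict = {}
    sidecar = _sidecar_path(path, metadata_path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    if np.issubdtype(frames.dtype, np.integer):
        missing = [k for k in ("scale", "offset") if k not in meta]
        if missing:
            raise ValueError(
                f"integer-count stack {path} needs calibration keys {missing} "
                f"in sidecar {sidecar}"
            )
        frames = frames.astype(np.float64) * float(meta["scale"]) + float(meta["offset"])
    return ThermalFrameStack(
        frames=frames.astype(np.float64),
        frame_period_s=float(meta.get("frame_period_s", 1.0 / 6.0)),
        laser_on_index=int(meta.get("laser_on_index", 0)),
        source_id=str(meta.get("source_id", path.stem)),
    )


# ---------------------------------------------------------------------------
# Temperature traces


def write_traces(traces: Sequence[TemperatureTrace], path: str | Path) -> None:
    """Write traces to a single CSV (columns: time_s, temp_mean_C, temp_sd_C, animal_id, group)."""
    rows = []
    for tr in traces:
        rows.append(pd.DataFrame({
            "time_s": tr.times,
            "temp_mean_C": tr.temp_mean,
            "temp_sd_C": tr.temp_sd,
            "animal_id": tr.animal_id,
            "group": _group_to_str(tr.group),
        }))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False, float_format="%.6f")


def read_traces(path: str | Path) -> list[TemperatureTrace]:
    """Read a trace CSV into one TemperatureTrace per animal, rows sorted by time."""
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trace CSV {path} is missing columns {missing}")
    traces = []
    for animal_id, sub in df.groupby("animal_id", sort=True):
        sub = sub.sort_values("time_s")
        times = sub["time_s"].to_numpy()
        dup = np.flatnonzero(np.diff(times) == 0)
        if dup.size:
            raise ValueError(
                f"duplicate time {times[dup[0]]} s for animal {animal_id!r} "
                f"(CSV row {sub.index[dup[0] + 1] + 2})"
            )
        group_labels = sub["group"].astype(str).unique()
        traces.append(TemperatureTrace(
            times=times,
            temp_mean=sub["temp_mean_C"].to_numpy(),
            temp_sd=sub["temp_sd_C"].to_numpy(),
            animal_id=str(animal_id),
            group=parse_group(group_labels[0]) if group_labels[0] != "nan" else None,
        ))
    return traces


# ---------------------------------------------------------------------------
# Result tables


def write_results(table: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as CSV preceded by a schema-version header line."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(RESULTS_SCHEMA_HEADER + "\n")
        table.to_csv(fh, index=False, float_format="%.6f")


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a result table written by :func:`write_results`."""
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("# pttherm-results"):
            raise ValueError(f"{path} lacks the pttherm results schema header")
        return pd.read_csv(fh)


def config_from_yaml(path: str | Path) -> RunConfig:
    """Load a RunConfig from a YAML file (unknown keys rejected)."""
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys {sorted(unknown)} in {path}")
    if "groups" in raw and raw["groups"] is not None:
        from pttherm.synth import SimGroupParams

        raw["groups"] = [SimGroupParams(**g) for g in raw["groups"]]
    return RunConfig(**raw)
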