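"""Plain-text serialization of traces, spectra, thermogram stacks and plates.

Formats
-------
* Thermal trace: CSV with columns ``time_s,temp_C`` plus a JSON sidecar
  carrying ``ambient_temp_C``, ``laser_on_s``, ``laser_off_s`` and any
  experiment metadata (laser power, absorbance, component inventory).
* Spectrum: CSV with columns ``wavelength_nm,extinction``.
* Thermogram stack: a directory of ``frame_0000.csv`` row-major matrices
  plus ``manifest.json`` (``timestamps_s``, ``pixel_pitch_mm``,
  ``ambient_temp_C``).  Infrared-camera vendor exports are proprietary;
  this plain-text dialect is the package's interchange format.
* MTT plate: CSV with columns ``well,group,od570,od670,irradiated``.
* ROI: JSON, either a rectangle ``{"type": "rect", "row0": .., "row1": ..,
  "col0": .., "col1": ..}`` or a row-major run-length mask
  ``{"type": "rle", "shape": [ny, nx], "runs": [n0, n1, ...]}`` whose runs
  alternate false/true starting with false.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .lumped import HeatCapacityComponent, ThermalTrace
from .spectra import SpectrumRecord
from .thermography import RoiMask, ThermogramStack
from .viability import MttPlate, PLATE_COLUMNS

__all__ = [
    "write_trace",
    "read_trace",
    "write_spectrum",
    "read_spectrum",
    "write_stack",
    "read_stack",
    "write_plate",
    "read_plate",
    "read_roi",
    "components_from_meta",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_trace(trace: ThermalTrace, csv_path: str | Path) -> Path:
    """Write a trace as CSV + JSON sidecar; returns the sidecar path."""
    csv_path = Path(csv_path)
    pd.DataFrame({"time_s": trace.times, "temp_C": trace.temps}).to_csv(
        csv_path, index=False
    )
    meta: dict[str, Any] = {
        "ambient_temp_C": trace.ambient_temp,
        "laser_on_s": trace.laser_on_time,
        "laser_off_s": trace.laser_off_time,
    }
    meta.update(_jsonable(trace.metadata))
    side = _sidecar(csv_path)
    side.write_text(json.dumps(meta, indent=1))
    return side


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def read_trace(csv_path: str | Path, meta_path: str | Path | None = None) -> ThermalTrace:
    """Read a trace CSV and its JSON sidecar (defaulting to ``<stem>.json``)."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    meta_path = Path(meta_path) if meta_path is not None else _sidecar(csv_path)
    meta: dict[str, Any] = {}
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
    extra = {
        k: v
        for k, v in meta.items()
        if k not in ("ambient_temp_C", "laser_on_s", "laser_off_s")
    }
    return ThermalTrace(
        times=df["time_s"].to_numpy(),
        temps=df["temp_C"].to_numpy(),
        ambient_temp=float(meta.get("ambient_temp_C", df["temp_C"].iloc[0])),
        laser_on_time=float(meta.get("laser_on_s", 0.0)),
        laser_off_time=(
            float(meta["laser_off_s"]) if meta.get("laser_off_s") is not None else None
        ),
        metadata=extra,
    )


def components_from_meta(meta: dict[str, Any]) -> list[HeatCapacityComponent] | None:
    """Component inventory from sidecar metadata, if recorded.

    Expects ``components`` as a list of ``{label, mass_g, specific_heat}``.
    """
    raw = meta.get("components")
    if not raw:
        return None
    return [
        HeatCapacityComponent(c["label"], c["mass_g"], c["specific_heat"]) for c in raw
    ]


def write_spectrum(spectrum: SpectrumRecord, path: str | Path) -> None:
    pd.DataFrame(
        {"wavelength_nm": spectrum.wavelengths, "extinction": spectrum.extinction}
    ).to_csv(path, index=False)


def read_spectrum(path: str | Path, label: str = "") -> SpectrumRecord:
    df = pd.read_csv(path)
    return SpectrumRecord(
        wavelengths=df["wavelength_nm"].to_numpy(),
        extinction=df["extinction"].to_numpy(),
        label=label or Path(path).stem,
    )


def write_stack(stack: ThermogramStack, dirpath: str | Path) -> None:
    """Write frames as ``frame_####.csv`` plus ``manifest.json``."""
    d = Path(dirpath)
    d.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(stack.frames):
        np.savetxt(d / f"frame_{i:04d}.csv", frame, delimiter=",", fmt="%.6f")
    manifest = {
        "timestamps_s": stack.timestamps.tolist(),
        "pixel_pitch_mm": stack.pixel_pitch_mm,
        "ambient_temp_C": stack.ambient_temp,
        "laser_on_s": stack.metadata.get("laser_on_s", 0.0),
        "laser_off_s": stack.metadata.get("laser_off_s"),
    }
    (d / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_stack(dirpath: str | Path) -> ThermogramStack:
    d = Path(dirpath)
    manifest = json.loads((d / "manifest.json").read_text())
    frame_files = sorted(d.glob("frame_*.csv"))
    if not frame_files:
        raise FileNotFoundError(f"no frame_*.csv files in {d}")
    frames = np.array([np.loadtxt(f, delimiter=",") for f in frame_files])
    if frames.ndim == 2:  # single-row frames
        frames = frames[:, None, :]
    return ThermogramStack(
        frames=frames,
        timestamps=np.asarray(manifest["timestamps_s"], dtype=float),
        pixel_pitch_mm=float(manifest.get("pixel_pitch_mm", 1.0)),
        ambient_temp=manifest.get("ambient_temp_C"),
        metadata={
            "laser_on_s": manifest.get("laser_on_s", 0.0),
            "laser_off_s": manifest.get("laser_off_s"),
        },
    )


def write_plate(plate: MttPlate, path: str | Path) -> None:
    plate.data[PLATE_COLUMNS].to_csv(path, index=False)


def read_plate(path: str | Path) -> MttPlate:
    df = pd.read_csv(path)
    df["irradiated"] = df["irradiated"].astype(bool)
    return MttPlate(df)


def read_roi(path: str | Path, shape: tuple[int, int], label: str = "") -> RoiMask:
    """Load an ROI mask (rectangle or run-length JSON) for a frame shape."""
    spec = json.loads(Path(path).read_text())
    kind = spec.get("type", "rect")
    if kind == "rect":
        return RoiMask.rect(
            shape,
            int(spec["row0"]),
            int(spec["row1"]),
            int(spec["col0"]),
            int(spec["col1"]),
            label=spec.get("label", label),
        )
    if kind == "rle":
        runs = spec["runs"]
        flat = np.zeros(int(np.prod(shape)), dtype=bool)
        pos = 0
        value = False
        for run in runs:
            if value:
                flat[pos : pos + run] = True
            pos += run
            value = not value
        if pos != flat.size:
            raise ValueError("run-length mask does not cover the frame")
        return RoiMask(flat.reshape(shape), label=spec.get("label", label))
    raise ValueError(f"unknown ROI type {kind!r}")
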