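"""File formats: NIfTI-1 volumes, BIDS-style events tables, flow tables.

Volumes are 0-indexed, times are in seconds, events are tab-separated
onset/duration columns, corrupted-span tables are half-open 0-based volume
intervals. NIfTI headers carry voxel sizes and the TR in pixdim; the
spatial convention follows the header affine without reorientation.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from neohrf.cbf import FlowMeasurement
from neohrf.synth import StimulusDesign

__all__ = [
    "read_bold",
    "write_bold",
    "read_events",
    "write_events",
    "read_flow_table",
    "write_flow_table",
    "read_spans",
    "write_spans",
    "write_json",
]


def write_bold(
    volume: np.ndarray,
    path: str | Path,
    voxel_sizes: tuple[float, float, float],
    tr: float | None = None,
) -> None:
    """Write a 3D/4D volume as NIfTI-1 with voxel sizes (and TR) in the header."""
    volume = np.asarray(volume)
    affine = np.diag(list(voxel_sizes) + [1.0])
    img = nib.Nifti1Image(volume.astype(np.float32), affine)
    zooms = list(voxel_sizes)
    if volume.ndim == 4:
        zooms.append(tr if tr is not None else 1.0)
        img.header.set_xyzt_units("mm", "sec")
    img.header.set_zooms(zooms)
    nib.save(img, str(path))


def read_bold(
    path: str | Path, require_4d: bool = True
) -> tuple[np.ndarray, tuple[float, float, float], float | None]:
    """Read a NIfTI volume; returns (data, voxel_sizes, tr).

    tr is None for 3D images; 3D input raises when 4D is required.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if require_4d and data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D BOLD image, got {data.ndim}D")
    zooms = img.header.get_zooms()
    voxel_sizes = tuple(float(z) for z in zooms[:3])
    tr = float(zooms[3]) if data.ndim == 4 and len(zooms) > 3 else None
    return data, voxel_sizes, tr


def write_events(design: StimulusDesign, path: str | Path) -> None:
    """Write stimulus timing as a tab-separated onset/duration table (s)."""
    df = pd.DataFrame(
        {"onset": list(design.onsets), "duration": design.durations()}
    )
    df.to_csv(path, sep="\t", index=False)


def read_events(
    path: str | Path,
    tr: float,
    n_volumes: int,
    epoch_duration: float | None = None,
) -> StimulusDesign:
    """Read a tab-separated events table into a stimulus design.

    The acquisition clock (tr, n_volumes) is not stored in the events file
    and must be supplied; epoch_duration defaults to the onset spacing.
    Unsorted or overlapping events are rejected.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("onset", "duration"):
        if col not in df.columns:
            raise ValueError(f"{path}: events table is missing column '{col}'")
    onsets = df["onset"].to_numpy(dtype=float)
    durations = df["duration"].to_numpy(dtype=float)
    if np.any(np.diff(onsets) <= 0):
        raise ValueError(f"{path}: event onsets must be strictly increasing")
    if np.any(onsets[1:] < onsets[:-1] + durations[:-1]):
        raise ValueError(f"{path}: events overlap")
    if np.unique(durations).size > 1:
        raise ValueError(f"{path}: mixed stimulus durations are not supported")
    if epoch_duration is None:
        if onsets.size > 1:
            epoch_duration = float(onsets[1] - onsets[0])
        else:
            epoch_duration = n_volumes * tr - float(onsets[0])
    return StimulusDesign(
        tr=tr,
        n_volumes=n_volumes,
        onsets=tuple(onsets),
        stim_duration=float(durations[0]),
        epoch_duration=epoch_duration,
    )


def write_flow_table(measurements: list[FlowMeasurement], path: str | Path) -> None:
    """Write per-vessel phase-contrast velocities as CSV
    (vessel, phase, velocity_cm_s, area_mm2)."""
    rows = []
    for m in measurements:
        for phase, v in enumerate(m.phase_velocities):
            rows.append(
                {"vessel": m.vessel, "phase": phase,
                 "velocity_cm_s": v, "area_mm2": m.area}
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_flow_table(path: str | Path) -> list[FlowMeasurement]:
    df = pd.read_csv(path)
    required = {"vessel", "phase", "velocity_cm_s", "area_mm2"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: flow table is missing columns {sorted(missing)}")
    out = []
    for vessel, sub in df.groupby("vessel", sort=False):
        sub = sub.sort_values("phase")
        areas = sub["area_mm2"].to_numpy(dtype=float)
        out.append(
            FlowMeasurement(
                vessel=str(vessel),
                phase_velocities=tuple(sub["velocity_cm_s"].to_numpy(dtype=float)),
                area=float(np.mean(areas)),
            )
        )
    return out


def write_spans(spans: list[tuple[int, int]], path: str | Path) -> None:
    """Corrupted volume spans as two-column CSV (start_volume, end_volume),
    0-based, half-open."""
    pd.DataFrame(spans, columns=["start_volume", "end_volume"]).to_csv(
        path, index=False
    )


def read_spans(path: str | Path) -> list[tuple[int, int]]:
    df = pd.read_csv(path)
    return [
        (int(a), int(b))
        for a, b in zip(df["start_volume"], df["end_volume"])
    ]


def write_json(obj: dict, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")
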