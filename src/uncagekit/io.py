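"""Readers and writers for stacks, masks, traces, events and results.

Stacks go to ImageJ-compatible multi-page TIFF (TYX, 16-bit unsigned,
clipped at saturation) with a YAML sidecar carrying acquisition metadata
and, for synthetic data, the generative ground truth.  Masks are 8-bit
label TIFFs (0 = none, 1 = PM, 2 = vesicle, 3 = background).  Tabular data
(traces, events, binned counts, titration results) are plain CSV with a
mandatory header row.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd
import tifffile
import yaml

from .calcium_events import BinnedCounts, Event
from .synth_calcium import CalciumTrace
from .synth_imaging import CompartmentMasks, ImageStack
from .uncaging_quant import TitrationReport, UncagingResult

__all__ = [
    "write_stack",
    "read_stack",
    "write_masks",
    "read_masks",
    "write_traces_csv",
    "read_traces_csv",
    "write_events_csv",
    "write_binned_csv",
    "write_titration_csv",
    "load_yaml",
    "dump_yaml",
]

_UINT16_MAX = 65535


def _sidecar_path(path: str) -> str:
    base, _ = os.path.splitext(path)
    return base + ".yaml"


def write_stack(path: str, stack: ImageStack, extra_meta: dict | None = None) -> None:
    """Write a stack as 16-bit TYX TIFF plus a YAML metadata sidecar."""
    pixels = np.clip(np.round(stack.pixels), 0, _UINT16_MAX).astype(np.uint16)
    tifffile.imwrite(path, pixels, imagej=True, metadata={"axes": "TYX"})
    meta = {
        "frame_interval_s": float(stack.frame_interval_s),
        "uncaging_frame": int(stack.uncaging_frame),
        "laser_level": float(stack.laser_level),
    }
    if extra_meta:
        meta.update(extra_meta)
    dump_yaml(_sidecar_path(path), meta)


def read_stack(
    path: str,
    frame_interval_s: float | None = None,
    uncaging_frame: int | None = None,
) -> ImageStack:
    """Read a TYX single-channel TIFF stack; metadata from sidecar or flags.

    Explicit arguments override the sidecar.  Multi-channel or non-3-D
    files raise a format error.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    pixels = tifffile.imread(path)
    if pixels.ndim == 2:
        pixels = pixels[None]
    if pixels.ndim != 3:
        raise ValueError(f"expected a TYX single-channel stack, got shape {pixels.shape}")
    meta: dict = {}
    sidecar = _sidecar_path(path)
    if os.path.exists(sidecar):
        meta = load_yaml(sidecar)
    interval = frame_interval_s if frame_interval_s is not None else meta.get("frame_interval_s", 1.0)
    k = uncaging_frame if uncaging_frame is not None else meta.get("uncaging_frame", 1)
    return ImageStack(
        pixels=pixels.astype(float),
        frame_interval_s=float(interval),
        uncaging_frame=int(k),
        laser_level=float(meta.get("laser_level", 0.0)),
    )


def write_masks(path: str, masks: CompartmentMasks) -> None:
    """Write masks as an 8-bit label TIFF (0 none, 1 PM, 2 vesicle, 3 background)."""
    labels = np.zeros(masks.pm.shape, dtype=np.uint8)
    labels[masks.pm] = 1
    labels[masks.vesicles] = 2
    labels[masks.background] = 3
    tifffile.imwrite(path, labels)


def read_masks(path: str) -> CompartmentMasks:
    labels = tifffile.imread(path)
    if labels.ndim != 2:
        raise ValueError("label mask must be a single 2-D image")
    return CompartmentMasks(pm=labels == 1, vesicles=labels == 2, background=labels == 3)


def write_traces_csv(path: str, traces: Iterable[CalciumTrace]) -> None:
    """Long-format CSV: cell_id, time_s, value (+ uncaging_time_s)."""
    frames = []
    for trace in traces:
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": trace.cell_id,
                    "time_s": trace.time_s,
                    "value": trace.values,
                    "uncaging_time_s": trace.uncaging_time_s,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_traces_csv(path: str, uncaging_time_s: float | None = None) -> list[CalciumTrace]:
    df = pd.read_csv(path)
    required = {"cell_id", "time_s", "value"}
    if not required <= set(df.columns):
        raise ValueError(f"traces CSV must have columns {sorted(required)}")
    traces = []
    for cell_id, group in df.groupby("cell_id", sort=True):
        group = group.sort_values("time_s")
        t0 = uncaging_time_s
        if t0 is None:
            if "uncaging_time_s" not in group:
                raise ValueError("uncaging_time_s column missing and no override given")
            t0 = float(group["uncaging_time_s"].iloc[0])
        traces.append(
            CalciumTrace(
                time_s=group["time_s"].to_numpy(float),
                values=group["value"].to_numpy(float),
                uncaging_time_s=t0,
                cell_id=int(cell_id),
            )
        )
    return traces


def write_events_csv(path: str, events_per_cell: dict[int, list[Event]]) -> None:
    rows = []
    for cell_id, events in sorted(events_per_cell.items()):
        for e in events:
            rows.append(
                {
                    "cell_id": cell_id,
                    "peak_time_s": e.peak_time_s,
                    "height": e.height,
                    "relative_height": e.relative_height,
                    "fwhm_s": e.width_fwhm_s,
                    "label": e.label,
                }
            )
    pd.DataFrame(
        rows,
        columns=["cell_id", "peak_time_s", "height", "relative_height", "fwhm_s", "label"],
    ).to_csv(path, index=False)


def write_binned_csv(path: str, binned: BinnedCounts) -> None:
    pd.DataFrame(
        {
            "bin_start_s": binned.bin_starts_s,
            "mean": binned.mean,
            "sem": binned.sem,
            "n_cells": binned.n_cells,
        }
    ).to_csv(path, index=False)


def write_titration_csv(path: str, report: TitrationReport) -> None:
    rows = [_result_row(r) for r in report.results]
    pd.DataFrame(rows).to_csv(path, index=False)


def _result_row(r: UncagingResult) -> dict:
    return {
        "level": r.laser_level,
        "dF_pm": r.dF_pm.value,
        "dF_pm_sem": r.dF_pm.sem,
        "dF_ves": r.dF_ves.value,
        "dF_ves_sem": r.dF_ves.sem,
        "ratio": r.efficiency_ratio,
        "ratio_err": r.ratio_err,
        "remaining_pm": r.remaining_pm,
        "complete": r.complete,
    }


def load_yaml(path: str) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return data or {}


def dump_yaml(path: str, data: dict) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=True, default_flow_style=False)
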