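"""Data model and I/O for 2D+t perfusion series.

Two on-disk dialects are supported: directories of single-frame 16-bit
DICOM files, and 8-bit grayscale PNG frame sequences with a JSON sidecar
carrying pixel spacing and per-frame acquisition times.

Conventions: pixel indices are 0-based ``(row, col)``; physical position in
millimetres is ``index * pixel_spacing``. Frame order is acquisition-time
order.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from PIL import Image

from . import _dicom
from .errors import FormatError

DEFAULT_PD_FRAMES = 2


@dataclass
class Frame:
    """One time step of a perfusion series."""

    pixels: np.ndarray
    acquisition_time: float
    is_proton_density: bool = False

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("frame pixels must be 2D")
        if self.acquisition_time < 0:
            raise ValueError("acquisition_time must be non-negative")


@dataclass
class PerfusionSeries:
    """An ordered 2D+t perfusion image series.

    Attributes
    ----------
    frames:
        Time-ordered frames sharing one shape.
    pixel_spacing:
        (row mm, column mm) per pixel; both > 0.
    patient_id, study, slice_level:
        Free-text labels; ``study`` is conventionally ``rest``/``stress``
        and ``slice_level`` one of ``apical``/``mid``/``basal``.
    is_8bit:
        True for series loaded from the 8-bit PNG dialect. Such series are
        non-quantitative across series.
    pd_stripped:
        True once leading proton-density frames were removed.
    """

    frames: list[Frame]
    pixel_spacing: tuple[float, float]
    patient_id: str = ""
    study: str = "rest"
    slice_level: str = "mid"
    is_8bit: bool = False
    pd_stripped: bool = False

    def __post_init__(self):
        if len(self.frames) < 3 and not self.pd_stripped:
            raise ValueError("a perfusion series needs at least 3 frames")
        shape = self.frames[0].pixels.shape
        for i, fr in enumerate(self.frames):
            if fr.pixels.shape != shape:
                raise ValueError(f"frame {i} shape {fr.pixels.shape} != {shape}")
        times = self.times
        if np.any(np.diff(times) <= 0):
            raise ValueError("acquisition times must be strictly increasing")
        if min(self.pixel_spacing) <= 0:
            raise ValueError("pixel spacing must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames[0].pixels.shape

    @property
    def times(self) -> np.ndarray:
        return np.array([f.acquisition_time for f in self.frames], dtype=float)

    def pixel_array(self) -> np.ndarray:
        """Stack frames into a (t, rows, cols) float array."""
        return np.stack([f.pixels for f in self.frames]).astype(float)

    def with_frames(self, frames: list[Frame]) -> "PerfusionSeries":
        return replace(self, frames=frames)

    def check_quantitative(self):
        if self.is_8bit:
            warnings.warn(
                "8-bit PNG series use a per-series intensity mapping and "
                "should not be compared quantitatively across series",
                stacklevel=2,
            )


def strip_proton_density(series: PerfusionSeries, n_pd_frames: int | None = None) -> PerfusionSeries:
    """Return a copy of ``series`` without its leading proton-density frames.

    By convention the first ``n_pd_frames`` frames (default: frames flagged
    PD, else 2) are calibration frames excluded from motion analysis. A
    series already stripped is returned unchanged.
    """
    if series.pd_stripped:
        return series
    if n_pd_frames is None:
        flagged = 0
        for fr in series.frames:
            if fr.is_proton_density:
                flagged += 1
            else:
                break
        n_pd_frames = flagged if flagged else DEFAULT_PD_FRAMES
    if n_pd_frames >= series.n_frames:
        raise ValueError("cannot strip all frames")
    kept = [replace(f, is_proton_density=False) for f in series.frames[n_pd_frames:]]
    return replace(series, frames=kept, pd_stripped=True)


# ---------------------------------------------------------------------------
# DICOM dialect
# ---------------------------------------------------------------------------

def load_dicom_series(
    directory_path: str,
    n_pd_frames: int = DEFAULT_PD_FRAMES,
    patient_id: str = "",
    study: str = "rest",
    slice_level: str = "mid",
) -> PerfusionSeries:
    """Load a directory of single-frame DICOM files as one series.

    Frames are sorted by acquisition time (AcquisitionTime preferred;
    TriggerTime accepted as fallback when AcquisitionTime is absent). The
    first ``n_pd_frames`` frames in time order are flagged proton density.
    """
    names = sorted(
        n for n in os.listdir(directory_path)
        if not n.startswith(".") and not n.endswith(".json")
    )
    if not names:
        raise FormatError(f"{directory_path}: no DICOM files found")
    records = []
    for name in names:
        path = os.path.join(directory_path, name)
        rec = _dicom.read_mr_frame(path)
        t = rec["acquisition_seconds"]
        if t is None:
            t = rec["trigger_seconds"]
        if t is None:
            raise FormatError(f"{path}: no acquisition or trigger time tag")
        records.append((t, rec))
    records.sort(key=lambda item: item[0])
    t0 = records[0][0]
    spacing = records[0][1]["pixel_spacing"]
    for t, rec in records:
        if rec["pixel_spacing"] != spacing:
            raise FormatError(f"{directory_path}: inconsistent pixel spacing across frames")
    frames = [
        Frame(rec["pixels"], t - t0, is_proton_density=(i < n_pd_frames))
        for i, (t, rec) in enumerate(records)
    ]
    pid = patient_id or records[0][1]["patient_id"]
    return PerfusionSeries(frames, spacing, patient_id=pid, study=study, slice_level=slice_level)


def save_dicom_series(series: PerfusionSeries, directory_path: str, base_time: float = 36000.0):
    """Export a series as single-frame 16-bit DICOM files.

    Float intensities are rounded and clipped into the uint16 range; the
    acquisition clock starts at ``base_time`` seconds of day.
    """
    os.makedirs(directory_path, exist_ok=True)
    for i, fr in enumerate(series.frames):
        pix = np.clip(np.round(np.asarray(fr.pixels, dtype=float)), 0, 65535).astype(np.uint16)
        _dicom.write_mr_frame(
            os.path.join(directory_path, f"frame{i:04d}.dcm"),
            pix,
            pixel_spacing=series.pixel_spacing,
            acquisition_seconds=base_time + fr.acquisition_time,
            instance_number=i + 1,
            patient_id=series.patient_id or "phantom",
            series_description=f"{series.study}/{series.slice_level}",
        )


# ---------------------------------------------------------------------------
# PNG + sidecar dialect
# ---------------------------------------------------------------------------

def load_png_series(
    file_list: list[str],
    metadata_path: str,
    strict: bool = False,
) -> PerfusionSeries:
    """Load an 8-bit PNG frame sequence with a JSON sidecar.

    The sidecar must provide ``pixel_spacing`` and ``times`` (seconds,
    series-relative, one per file). RGB images are converted to luminance
    with a warning, or rejected when ``strict`` is set.
    """
    if not os.path.exists(metadata_path):
        raise FormatError(f"missing metadata file {metadata_path}")
    with open(metadata_path) as fh:
        meta = json.load(fh)
    for key in ("pixel_spacing", "times"):
        if key not in meta:
            raise FormatError(f"{metadata_path}: missing {key!r}")
    times = [float(t) for t in meta["times"]]
    if len(times) != len(file_list):
        raise FormatError(
            f"{metadata_path}: {len(times)} times for {len(file_list)} files"
        )
    n_pd = int(meta.get("n_pd_frames", DEFAULT_PD_FRAMES))
    frames = []
    shape = None
    for i, path in enumerate(file_list):
        img = Image.open(path)
        if img.mode not in ("L", "I;16", "I"):
            if strict:
                raise FormatError(f"{path}: mode {img.mode} not allowed in strict mode")
            warnings.warn(f"{path}: converting {img.mode} to luminance", stacklevel=2)
            img = img.convert("L")
        arr = np.asarray(img)
        if shape is None:
            shape = arr.shape
        elif arr.shape != shape:
            raise FormatError(f"{path}: frame shape {arr.shape} != {shape}")
        frames.append(Frame(arr, times[i], is_proton_density=(i < n_pd)))
    spacing = tuple(float(s) for s in meta["pixel_spacing"])
    return PerfusionSeries(
        frames,
        spacing,
        patient_id=str(meta.get("patient_id", "")),
        study=str(meta.get("study", "rest")),
        slice_level=str(meta.get("slice_level", "mid")),
        is_8bit=True,
    )


def save_png_series(series: PerfusionSeries, directory_path: str) -> list[str]:
    """Export a series as 8-bit PNGs plus ``series.json`` sidecar.

    Intensities are linearly mapped to [0, 255] over the series-wide range
    (the mapping is per-series, so the export is non-quantitative).
    """
    os.makedirs(directory_path, exist_ok=True)
    stack = series.pixel_array()
    lo, hi = float(stack.min()), float(stack.max())
    scale = 255.0 / (hi - lo) if hi > lo else 1.0
    paths = []
    for i, fr in enumerate(series.frames):
        arr = np.clip((np.asarray(fr.pixels, float) - lo) * scale, 0, 255).astype(np.uint8)
        path = os.path.join(directory_path, f"frame{i:04d}.png")
        Image.fromarray(arr, mode="L").save(path)
        paths.append(path)
    meta = {
        "pixel_spacing": list(series.pixel_spacing),
        "times": [f.acquisition_time for f in series.frames],
        "n_pd_frames": sum(1 for f in series.frames if f.is_proton_density),
        "patient_id": series.patient_id,
        "study": series.study,
        "slice_level": series.slice_level,
        "intensity_window": [lo, hi],
    }
    meta_path = os.path.join(directory_path, "series.json")
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=1)
    return paths
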