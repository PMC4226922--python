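"""Time-intensity-curve validation of motion compensation.

Three curve families are compared per myocardial section: K_gt from the
per-frame manual masks on the original series (ground truth), K_org from
the unaltered LV-peak key-frame section masks on the original series, and
K_reg from the key-frame masks adjusted by the key frame's transform and
applied to the registered series. Quality is scored with NMSE (lower is
better) and the Pearson coefficient (higher is better; reported under the
conventional R^2 label, signed). A transformed section mask without any
pixel scores a correlation of exactly 0 to flag the failure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segmentation import SegmentationSet, section_masks
from .series_model import PerfusionSeries
from .transforms import TransformField

__all__ = [
    "CurveSet",
    "intensity_curve",
    "build_curves",
    "nmse",
    "pearson",
    "score_curves",
    "summarize",
]


@dataclass
class CurveSet:
    """Per-section K_gt / K_org / K_reg, shaped (n_sections, n_frames)."""

    K_gt: np.ndarray
    K_org: np.ndarray
    K_reg: np.ndarray | None
    key_frame_index: int
    empty_reg_sections: list[int]

    @property
    def n_sections(self) -> int:
        return self.K_gt.shape[0]


def intensity_curve(series: PerfusionSeries, per_frame_masks) -> np.ndarray:
    """Mean intensity over a mask, per frame.

    ``per_frame_masks`` is one mask per frame or one fixed mask reused for
    all frames. Frames with an empty mask yield NaN.
    """
    stack = series.pixel_array()
    n = stack.shape[0]
    masks = per_frame_masks
    if isinstance(masks, np.ndarray) and masks.ndim == 2:
        masks = [masks] * n
    if len(masks) != n:
        raise ValueError(f"{len(masks)} masks for {n} frames")
    out = np.empty(n)
    for t, mask in enumerate(masks):
        out[t] = stack[t][mask].mean() if mask.any() else np.nan
    return out


def build_curves(
    series: PerfusionSeries,
    registered_series: PerfusionSeries | None,
    segset: SegmentationSet,
    transforms: list[TransformField] | None,
    n_sections: int = 12,
) -> CurveSet:
    """Assemble K_gt, K_org and (when a registration is supplied) K_reg.

    ``segset`` must cover every frame of ``series`` and carry the LV-peak
    index, whose frame serves as key frame.
    """
    if segset.lv_peak_index is None:
        raise ValueError("segmentation set lacks the LV-peak frame index")
    if len(segset.frames) != series.n_frames:
        raise ValueError(
            f"{len(segset.frames)} segmentation frames for {series.n_frames} images"
        )
    shape = series.frame_shape
    key = segset.lv_peak_index

    gt_sections = [
        section_masks(frame, shape, n_sections).sections for frame in segset.frames
    ]
    key_sections = section_masks(segset.frames[key], shape, n_sections).sections

    K_gt = np.stack(
        [
            intensity_curve(series, [gt_sections[t][k] for t in range(series.n_frames)])
            for k in range(n_sections)
        ]
    )
    K_org = np.stack(
        [intensity_curve(series, key_sections[k]) for k in range(n_sections)]
    )

    K_reg = None
    empty = []
    if registered_series is not None:
        if transforms is None:
            raise ValueError("registered series given without its transforms")
        adjusted = [transforms[key].apply_to_mask(m) for m in key_sections]
        empty = [k for k, m in enumerate(adjusted) if not m.any()]
        K_reg = np.stack(
            [intensity_curve(registered_series, adjusted[k]) for k in range(n_sections)]
        )
    return CurveSet(K_gt, K_org, K_reg, key, empty)


def nmse(curve: np.ndarray, gt_curve: np.ndarray) -> float:
    """sum((curve - gt)^2) / sum((gt - mean(gt))^2).

    A curve equal to the constant mean of the ground truth scores exactly
    1. Undefined (NaN) for constant ground truth.
    """
    curve = np.asarray(curve, dtype=float)
    gt = np.asarray(gt_curve, dtype=float)
    if curve.shape != gt.shape or curve.size < 2:
        raise ValueError("curves must share a length of at least 2")
    denom = float(np.sum((gt - gt.mean()) ** 2))
    if denom == 0.0:
        return float("nan")
    return float(np.sum((curve - gt) ** 2) / denom)


def pearson(curve: np.ndarray, gt_curve: np.ndarray) -> float:
    """Signed Pearson correlation coefficient in [-1, 1].

    Zero-variance inputs score 0 with a warning (this also covers the
    empty-transformed-mask convention, where failed sections are set to 0).
    """
    curve = np.asarray(curve, dtype=float)
    gt = np.asarray(gt_curve, dtype=float)
    if curve.shape != gt.shape or curve.size < 2:
        raise ValueError("curves must share a length of at least 2")
    a = curve - curve.mean()
    b = gt - gt.mean()
    va, vb = float(np.sum(a * a)), float(np.sum(b * b))
    if va == 0.0 or vb == 0.0:
        warnings.warn("zero-variance curve; correlation set to 0", stacklevel=2)
        return 0.0
    return float(np.sum(a * b) / np.sqrt(va * vb))


def score_curves(
    curves: CurveSet,
    patient: str = "",
    slice_level: str = "",
    study: str = "rest",
    method: str = "method",
) -> pd.DataFrame:
    """Score one curve set into tidy rows.

    One data point per (patient, slice, study, section); phases are
    ``unregistered`` (K_org vs K_gt) and ``method`` (K_reg vs K_gt).
    Sections whose transformed mask was empty score R^2 = 0; their NMSE is
    undefined and omitted.
    """
    rows = []

    def add(phase, k, measure, value):
        rows.append(
            {
                "patient": patient,
                "slice": slice_level,
                "study": study,
                "section": k,
                "phase": phase,
                "measure": measure,
                "value": value,
            }
        )

    for k in range(curves.n_sections):
        gt = curves.K_gt[k]
        if np.isnan(gt).any():
            continue        # defensive: undefined ground truth, drop section
        add("unregistered", k, "NMSE", nmse(curves.K_org[k], gt))
        add("unregistered", k, "R2", pearson(curves.K_org[k], gt))
        if curves.K_reg is None:
            continue
        if k in curves.empty_reg_sections:
            add(method, k, "R2", 0.0)
            continue
        add(method, k, "NMSE", nmse(curves.K_reg[k], gt))
        add(method, k, "R2", pearson(curves.K_reg[k], gt))
    return pd.DataFrame(rows)


def summarize(
    score_table: pd.DataFrame,
    exclude: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Mean / variation (sample SD) / median / min / max per measure and
    phase, split into all / rest / stress blocks.

    ``exclude`` may hold (patient, slice, study) rows of failed series; a
    second set of summary rows ignoring those series is then added with
    the phase suffix ``*``.
    """
    if score_table.empty:
        raise ValueError("empty score table")

    def stats(values: np.ndarray) -> dict:
        values = values[~np.isnan(values)]
        return {
            "mean": float(values.mean()),
            "variation": float(values.std(ddof=1)) if values.size > 1 else 0.0,
            "median": float(np.median(values)),
            "min": float(values.min()),
            "max": float(values.max()),
            "n": int(values.size),
        }

    frames = {"all": score_table}
    for study in ("rest", "stress"):
        sub = score_table[score_table["study"] == study]
        if not sub.empty:
            frames[study] = sub

    tables = {"": score_table}
    if exclude is not None and not exclude.empty:
        mask = pd.Series(False, index=score_table.index)
        for _, row in exclude.iterrows():
            mask |= (
                (score_table["patient"] == row["patient"])
                & (score_table["slice"] == row["slice"])
                & (score_table["study"] == row["study"])
            )
        tables["*"] = score_table[~mask]

    rows = []
    for suffix, table in tables.items():
        for block in ("all", "rest", "stress"):
            sub = table if block == "all" else table[table["study"] == block]
            if sub.empty:
                continue
            for (measure, phase), group in sub.groupby(["measure", "phase"]):
                if suffix == "*" and phase == "unregistered":
                    continue
                rows.append(
                    {
                        "block": block,
                        "measure": measure,
                        "phase": phase + suffix,
                        **stats(group["value"].to_numpy()),
                    }
                )
    return pd.DataFrame(rows)
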