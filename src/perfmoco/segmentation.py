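"""Segmentation sets: XML I/O, mask rasterization, and section division.

A segmentation set holds, per frame, the endo- and epicardial contours plus
a three-point *star* on the epicardial circumcircle whose first ray passes
through the RV insertion point. The myocardium is divided into angular
sections by rotating the LV-centre-to-RV-insertion ray clockwise in equal
increments.

Points are (x, y) = (column, row) in 0-based pixel coordinates, matching
the on-disk XML attributes. Masks are boolean (row, col) grids.
"""

from __future__ import annotations

import math
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field

import numpy as np

from .errors import SegmentationParseError

__all__ = [
    "SegmentationFrame",
    "SegmentationSet",
    "SectionMasks",
    "read_segmentation",
    "write_segmentation",
    "rasterize_contour",
    "myocardium_mask",
    "circumcircle",
    "section_masks",
]


@dataclass
class SegmentationFrame:
    """Per-frame segmentation: star plus endo/epi contours."""

    image_ref: str
    star_center: tuple[float, float]          # (x, y) = LV_c
    star_rays: list[tuple[float, float]]      # 3 points; first = RV_ip
    endocardium: np.ndarray                   # (n, 2) of (x, y)
    epicardium: np.ndarray

    def __post_init__(self):
        if len(self.star_rays) != 3:
            raise ValueError("star needs exactly 3 ray points")
        self.endocardium = np.asarray(self.endocardium, dtype=float)
        self.epicardium = np.asarray(self.epicardium, dtype=float)

    @property
    def rv_insertion_point(self) -> tuple[float, float]:
        return self.star_rays[0]


@dataclass
class SegmentationSet:
    """Ordered per-frame segmentations for one slice level."""

    frames: list[SegmentationFrame]
    rv_peak_index: int | None = None
    lv_peak_index: int | None = None
    slice_level: int = 1                      # 0 apical, 1 middle, 2 basal
    rv_insertion_kind: str = "anterior"       # which insertion point ray 0 uses

    def __post_init__(self):
        n = len(self.frames)
        for name in ("rv_peak_index", "lv_peak_index"):
            idx = getattr(self, name)
            if idx is not None and not (0 <= idx < max(n, 1)):
                raise ValueError(f"{name}={idx} outside frame range 0..{n - 1}")

    def drop_leading(self, n: int) -> "SegmentationSet":
        """Remove the first ``n`` frames, shifting peak indices."""
        def shift(idx):
            return None if idx is None else max(idx - n, 0)
        return SegmentationSet(
            self.frames[n:], shift(self.rv_peak_index), shift(self.lv_peak_index),
            self.slice_level, self.rv_insertion_kind,
        )


@dataclass
class SectionMasks:
    """An angular partition of the myocardium."""

    myocardium_mask: np.ndarray
    sections: list[np.ndarray]
    angular_increment: float

    @property
    def n_sections(self) -> int:
        return len(self.sections)


# ---------------------------------------------------------------------------
# XML dialect
# ---------------------------------------------------------------------------
#
#   <workset sliceLevel="1" rvInsertion="anterior">
#     <description> <RVpeak value="4"/> <LVpeak value="9"/> </description>
#     <frame image="frame0000.png">
#       <star x="..." y="..."> <point x=".." y=".."/> x3 </star>
#       <contour role="endocardium"> <point x=".." y=".."/>... </contour>
#       <contour role="epicardium"> ... </contour>
#     </frame>
#   </workset>
#
# A compatible XSD ships in perfmoco/data/segmentation.xsd.

def _points_of(element, path) -> np.ndarray:
    pts = []
    for i, p in enumerate(element.findall("point")):
        try:
            pts.append((float(p.attrib["x"]), float(p.attrib["y"])))
        except (KeyError, ValueError) as exc:
            raise SegmentationParseError(
                f"bad point attributes: {exc}", f"{path}/point[{i}]"
            ) from exc
    return np.array(pts, dtype=float).reshape(-1, 2)


def read_segmentation(xml_path: str) -> SegmentationSet:
    """Parse a segmentation XML file; raises on schema violations."""
    try:
        tree = ET.parse(xml_path)
    except ET.ParseError as exc:
        raise SegmentationParseError(f"not well-formed XML: {exc}", xml_path) from exc
    root = tree.getroot()
    if root.tag != "workset":
        raise SegmentationParseError(f"root element is {root.tag!r}, expected 'workset'", "/")

    rv_peak = lv_peak = None
    desc = root.find("description")
    if desc is not None:
        for tag, attr in (("RVpeak", "rv"), ("LVpeak", "lv")):
            el = desc.find(tag)
            if el is not None:
                try:
                    value = int(el.attrib["value"])
                except (KeyError, ValueError) as exc:
                    raise SegmentationParseError(
                        f"bad {tag} value", f"/workset/description/{tag}"
                    ) from exc
                if attr == "rv":
                    rv_peak = value
                else:
                    lv_peak = value

    frames = []
    for i, fel in enumerate(root.findall("frame")):
        fpath = f"/workset/frame[{i}]"
        star = fel.find("star")
        if star is None:
            raise SegmentationParseError("frame missing star", fpath)
        try:
            center = (float(star.attrib["x"]), float(star.attrib["y"]))
        except (KeyError, ValueError) as exc:
            raise SegmentationParseError("star missing x/y center", f"{fpath}/star") from exc
        rays = _points_of(star, f"{fpath}/star")
        if rays.shape[0] != 3:
            raise SegmentationParseError(
                f"star has {rays.shape[0]} ray points, expected 3", f"{fpath}/star"
            )
        contours = {}
        for j, cel in enumerate(fel.findall("contour")):
            role = cel.attrib.get("role")
            if role not in ("endocardium", "epicardium"):
                raise SegmentationParseError(
                    f"contour role {role!r} invalid", f"{fpath}/contour[{j}]"
                )
            contours[role] = _points_of(cel, f"{fpath}/contour[{j}]")
        for role in ("endocardium", "epicardium"):
            if role not in contours:
                raise SegmentationParseError(f"frame missing {role} contour", fpath)
        frames.append(
            SegmentationFrame(
                image_ref=fel.attrib.get("image", f"frame{i:04d}"),
                star_center=center,
                star_rays=[tuple(r) for r in rays],
                endocardium=contours["endocardium"],
                epicardium=contours["epicardium"],
            )
        )
    try:
        return SegmentationSet(
            frames,
            rv_peak_index=rv_peak,
            lv_peak_index=lv_peak,
            slice_level=int(root.attrib.get("sliceLevel", 1)),
            rv_insertion_kind=root.attrib.get("rvInsertion", "anterior"),
        )
    except ValueError as exc:
        raise SegmentationParseError(str(exc), "/workset/description") from exc


def write_segmentation(segset: SegmentationSet, xml_path: str):
    """Serialize a segmentation set; output re-validates under the dialect."""
    root = ET.Element(
        "workset",
        sliceLevel=str(segset.slice_level),
        rvInsertion=segset.rv_insertion_kind,
    )
    desc = ET.SubElement(root, "description")
    if segset.rv_peak_index is not None:
        ET.SubElement(desc, "RVpeak", value=str(segset.rv_peak_index))
    if segset.lv_peak_index is not None:
        ET.SubElement(desc, "LVpeak", value=str(segset.lv_peak_index))

    def fmt(v: float) -> str:
        if not math.isfinite(v):
            raise ValueError(f"non-finite coordinate {v!r} in segmentation")
        return repr(float(v))

    for frame in segset.frames:
        fel = ET.SubElement(root, "frame", image=frame.image_ref)
        star = ET.SubElement(
            fel, "star", x=fmt(frame.star_center[0]), y=fmt(frame.star_center[1])
        )
        for x, y in frame.star_rays:
            ET.SubElement(star, "point", x=fmt(x), y=fmt(y))
        for role, contour in (
            ("endocardium", frame.endocardium),
            ("epicardium", frame.epicardium),
        ):
            cel = ET.SubElement(fel, "contour", role=role)
            for x, y in contour:
                ET.SubElement(cel, "point", x=fmt(x), y=fmt(y))
    ET.indent(root)
    ET.ElementTree(root).write(xml_path, encoding="unicode", xml_declaration=True)


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def rasterize_contour(contour: np.ndarray, grid_shape: tuple[int, int]) -> np.ndarray:
    """Even-odd fill of a closed polygon onto a pixel grid.

    A pixel belongs to the mask iff its centre lies inside the polygon
    (even-odd rule). ``contour`` is (n, 2) of (x, y); implicit closure.
    Degenerate (all-collinear) contours yield an empty mask with a warning.
    """
    contour = np.asarray(contour, dtype=float)
    if contour.ndim != 2 or contour.shape[0] < 3:
        raise ValueError("a contour needs at least 3 points")
    if contour.shape[0] > 3 and np.allclose(contour[0], contour[-1]):
        contour = contour[:-1]
    x, y = contour[:, 0], contour[:, 1]
    area2 = np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    mask = np.zeros(grid_shape, dtype=bool)
    if abs(area2) < 1e-12:
        warnings.warn("degenerate (collinear) contour rasterizes to empty mask", stacklevel=2)
        return mask

    nrows, ncols = grid_shape
    cols = np.arange(ncols, dtype=float)
    x2, y2 = np.roll(x, -1), np.roll(y, -1)
    # scanline even-odd: for each pixel-centre row, count edge crossings
    # left of each pixel centre; odd count -> inside.
    for row in range(nrows):
        yc = float(row)
        crosses = (y <= yc) != (y2 <= yc)
        if not np.any(crosses):
            continue
        xi = x[crosses] + (yc - y[crosses]) * (x2[crosses] - x[crosses]) / (
            y2[crosses] - y[crosses]
        )
        parity = (xi[None, :] > cols[:, None]).sum(axis=1) % 2
        mask[row] = parity.astype(bool)
    return mask


def myocardium_mask(frame: SegmentationFrame, grid_shape: tuple[int, int]) -> np.ndarray:
    """Epicardial fill minus endocardial fill."""
    epi = rasterize_contour(frame.epicardium, grid_shape)
    endo = rasterize_contour(frame.endocardium, grid_shape)
    if not (epi | endo == epi).all():
        warnings.warn("endocardial contour not nested inside epicardial contour", stacklevel=2)
    return epi & ~endo


def circumcircle(p1, p2, p3) -> tuple[tuple[float, float], float]:
    """Circumcircle of three non-collinear points, as ((x, y), radius)."""
    (x1, y1), (x2, y2), (x3, y3) = (map(float, p) for p in (p1, p2, p3))
    d = 2.0 * (x1 * (y2 - y3) + x2 * (y3 - y1) + x3 * (y1 - y2))
    scale = max(abs(v) for v in (x1, y1, x2, y2, x3, y3, 1.0))
    if abs(d) < 1e-12 * scale * scale:
        raise ValueError("points are collinear; no circumcircle")
    s1, s2, s3 = x1 * x1 + y1 * y1, x2 * x2 + y2 * y2, x3 * x3 + y3 * y3
    ux = (s1 * (y2 - y3) + s2 * (y3 - y1) + s3 * (y1 - y2)) / d
    uy = (s1 * (x3 - x2) + s2 * (x1 - x3) + s3 * (x2 - x1)) / d
    r = math.hypot(x1 - ux, y1 - uy)
    return (ux, uy), r


def section_masks(
    frame: SegmentationFrame,
    grid_shape: tuple[int, int],
    n_sections: int = 12,
) -> SectionMasks:
    """Divide the myocardium into equal angular sections.

    Section 0 starts at the ray from the star centre LV_c through the RV
    insertion point; subsequent sections follow clockwise (in image
    coordinates, y pointing down) in increments of 360/n_sections degrees.
    Angular intervals are half-open, so every myocardial pixel lands in
    exactly one section.
    """
    if n_sections < 1:
        raise ValueError("n_sections must be >= 1")
    myo = myocardium_mask(frame, grid_shape)
    if not myo.any():
        raise ValueError("myocardium mask is empty; cannot divide into sections")
    cx, cy = frame.star_center
    ipx, ipy = frame.rv_insertion_point
    theta0 = math.atan2(ipy - cy, ipx - cx)

    rows, cols = np.nonzero(myo)
    # with y down, increasing atan2 angle sweeps clockwise on screen
    theta = np.arctan2(rows - cy, cols - cx)
    cw = np.mod(theta - theta0, 2.0 * math.pi)
    increment = 2.0 * math.pi / n_sections
    idx = np.minimum((cw / increment).astype(int), n_sections - 1)
    sections = []
    for k in range(n_sections):
        m = np.zeros(grid_shape, dtype=bool)
        m[rows[idx == k], cols[idx == k]] = True
        sections.append(m)
    return SectionMasks(myo, sections, 360.0 / n_sections)


def circle_contour(center, radius, n_points: int = 36) -> np.ndarray:
    """Closed circular contour around ``center`` = (x, y)."""
    ang = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    return np.column_stack(
        (center[0] + radius * np.cos(ang), center[1] + radius * np.sin(ang))
    )
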