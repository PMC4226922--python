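"""Minimal DICOM codec for single-frame MR grayscale images.

Supports writing and reading uncompressed explicit-VR little-endian files
with the small tag set this package needs (geometry, timing, pixel data).
This is intentionally not a general DICOM implementation; it exists because
the toolkit must round-trip its own exported series without external
dependencies.
"""

from __future__ import annotations

import os
import struct

import numpy as np

from .errors import FormatError

TRANSFER_SYNTAX_EXPLICIT_LE = "1.2.840.10008.1.2.1"
MR_IMAGE_STORAGE = "1.2.840.10008.5.1.4.1.1.4"
_IMPLEMENTATION_UID = "1.2.826.0.1.3680043.10.1462.1"

# VRs that use the 4-byte length encoding with 2 reserved bytes.
_LONG_VRS = {b"OB", b"OW", b"OF", b"SQ", b"UT", b"UN"}

TAG_SOP_CLASS = (0x0008, 0x0016)
TAG_SOP_INSTANCE = (0x0008, 0x0018)
TAG_ACQ_TIME = (0x0008, 0x0032)
TAG_MODALITY = (0x0008, 0x0060)
TAG_PATIENT_ID = (0x0010, 0x0020)
TAG_TRIGGER_TIME = (0x0018, 0x1060)
TAG_SERIES_DESC = (0x0008, 0x103E)
TAG_INSTANCE_NUMBER = (0x0020, 0x0013)
TAG_SAMPLES_PER_PIXEL = (0x0028, 0x0002)
TAG_PHOTOMETRIC = (0x0028, 0x0004)
TAG_ROWS = (0x0028, 0x0010)
TAG_COLS = (0x0028, 0x0011)
TAG_PIXEL_SPACING = (0x0028, 0x0030)
TAG_BITS_ALLOCATED = (0x0028, 0x0100)
TAG_BITS_STORED = (0x0028, 0x0101)
TAG_HIGH_BIT = (0x0028, 0x0102)
TAG_PIXEL_REPRESENTATION = (0x0028, 0x0103)
TAG_PIXEL_DATA = (0x7FE0, 0x0010)


def _pad_even(value: bytes, pad: bytes = b" ") -> bytes:
    return value + pad if len(value) % 2 else value


def _encode_element(group: int, elem: int, vr: bytes, value: bytes) -> bytes:
    pad = b"\x00" if vr in (b"UI", b"OB", b"OW", b"UN") else b" "
    value = _pad_even(value, pad)
    head = struct.pack("<HH", group, elem) + vr
    if vr in _LONG_VRS:
        return head + b"\x00\x00" + struct.pack("<I", len(value)) + value
    return head + struct.pack("<H", len(value)) + value


def _fmt_tm(seconds: float) -> str:
    """Seconds-of-day -> DICOM TM string with microsecond precision."""
    seconds = float(seconds) % 86400.0
    hh = int(seconds // 3600)
    mm = int((seconds - 3600 * hh) // 60)
    ss = seconds - 3600 * hh - 60 * mm
    return f"{hh:02d}{mm:02d}{ss:09.6f}"


def _parse_tm(text: str) -> float:
    text = text.strip()
    if not text:
        raise ValueError("empty TM value")
    hh = int(text[0:2])
    mm = int(text[2:4]) if len(text) >= 4 else 0
    ss = float(text[4:]) if len(text) > 4 else 0.0
    return 3600.0 * hh + 60.0 * mm + ss


def write_mr_frame(
    path: str,
    pixels: np.ndarray,
    *,
    pixel_spacing: tuple[float, float],
    acquisition_seconds: float,
    instance_number: int = 1,
    patient_id: str = "phantom",
    series_description: str = "",
    trigger_time_ms: float | None = None,
    sop_instance_uid: str | None = None,
) -> None:
    """Write a single-frame 16-bit grayscale MR image.

    ``acquisition_seconds`` is encoded into AcquisitionTime as seconds of
    day; ``pixel_spacing`` is (row mm, column mm).
    """
    pixels = np.asarray(pixels)
    if pixels.ndim != 2:
        raise FormatError("DICOM export requires a 2D frame")
    if pixels.dtype != np.uint16:
        raise FormatError("DICOM export requires uint16 pixels")
    if sop_instance_uid is None:
        sop_instance_uid = f"{_IMPLEMENTATION_UID}.{os.getpid()}.{instance_number}"

    body = b""
    body += _encode_element(*TAG_SOP_CLASS, b"UI", MR_IMAGE_STORAGE.encode())
    body += _encode_element(*TAG_SOP_INSTANCE, b"UI", sop_instance_uid.encode())
    body += _encode_element(*TAG_ACQ_TIME, b"TM", _fmt_tm(acquisition_seconds).encode())
    body += _encode_element(*TAG_MODALITY, b"CS", b"MR")
    if series_description:
        body += _encode_element(*TAG_SERIES_DESC, b"LO", series_description.encode())
    body += _encode_element(*TAG_PATIENT_ID, b"LO", patient_id.encode())
    if trigger_time_ms is not None:
        body += _encode_element(*TAG_TRIGGER_TIME, b"DS", f"{trigger_time_ms:.3f}".encode())
    body += _encode_element(*TAG_INSTANCE_NUMBER, b"IS", str(instance_number).encode())
    body += _encode_element(*TAG_SAMPLES_PER_PIXEL, b"US", struct.pack("<H", 1))
    body += _encode_element(*TAG_PHOTOMETRIC, b"CS", b"MONOCHROME2")
    body += _encode_element(*TAG_ROWS, b"US", struct.pack("<H", pixels.shape[0]))
    body += _encode_element(*TAG_COLS, b"US", struct.pack("<H", pixels.shape[1]))
    spacing_str = f"{pixel_spacing[0]:g}\\{pixel_spacing[1]:g}"
    body += _encode_element(*TAG_PIXEL_SPACING, b"DS", spacing_str.encode())
    body += _encode_element(*TAG_BITS_ALLOCATED, b"US", struct.pack("<H", 16))
    body += _encode_element(*TAG_BITS_STORED, b"US", struct.pack("<H", 16))
    body += _encode_element(*TAG_HIGH_BIT, b"US", struct.pack("<H", 15))
    body += _encode_element(*TAG_PIXEL_REPRESENTATION, b"US", struct.pack("<H", 0))
    body += _encode_element(*TAG_PIXEL_DATA, b"OW", pixels.astype("<u2").tobytes())

    meta = b""
    meta += _encode_element(0x0002, 0x0001, b"OB", b"\x00\x01")
    meta += _encode_element(0x0002, 0x0002, b"UI", MR_IMAGE_STORAGE.encode())
    meta += _encode_element(0x0002, 0x0003, b"UI", sop_instance_uid.encode())
    meta += _encode_element(0x0002, 0x0010, b"UI", TRANSFER_SYNTAX_EXPLICIT_LE.encode())
    meta += _encode_element(0x0002, 0x0012, b"UI", _IMPLEMENTATION_UID.encode())
    group_len = _encode_element(0x0002, 0x0000, b"UL", struct.pack("<I", len(meta)))

    with open(path, "wb") as fh:
        fh.write(b"\x00" * 128)
        fh.write(b"DICM")
        fh.write(group_len)
        fh.write(meta)
        fh.write(body)


def _iter_elements(buf: bytes, offset: int):
    n = len(buf)
    while offset + 8 <= n:
        group, elem = struct.unpack_from("<HH", buf, offset)
        vr = buf[offset + 4 : offset + 6]
        if vr in _LONG_VRS:
            (length,) = struct.unpack_from("<I", buf, offset + 8)
            start = offset + 12
        else:
            (length,) = struct.unpack_from("<H", buf, offset + 6)
            start = offset + 8
        if length == 0xFFFFFFFF:
            raise FormatError("undefined-length elements are not supported")
        value = buf[start : start + length]
        yield (group, elem), vr, value
        offset = start + length


def read_mr_frame(path: str) -> dict:
    """Read one single-frame MR file written by this codec (or compatible).

    Returns a dict with keys ``pixels``, ``acquisition_seconds`` (may be
    None), ``trigger_seconds`` (may be None), ``pixel_spacing``,
    ``patient_id``, ``instance_number``.
    """
    with open(path, "rb") as fh:
        buf = fh.read()
    if len(buf) < 132 or buf[128:132] != b"DICM":
        raise FormatError(f"{path}: missing DICM magic (not a DICOM part-10 file)")

    elements: dict[tuple[int, int], tuple[bytes, bytes]] = {}
    for tag, vr, value in _iter_elements(buf, 132):
        if tag[0] == 0x0002 and tag[1] == 0x0010:
            ts = value.rstrip(b"\x00 ").decode()
            if ts != TRANSFER_SYNTAX_EXPLICIT_LE:
                raise FormatError(f"{path}: unsupported transfer syntax {ts!r}")
        if tag[0] != 0x0002:
            elements[tag] = (vr, value)

    def _text(tag):
        if tag not in elements:
            return None
        return elements[tag][1].rstrip(b"\x00 ").decode(errors="replace")

    def _us(tag):
        if tag not in elements:
            raise FormatError(f"{path}: missing required tag {tag}")
        return struct.unpack("<H", elements[tag][1][:2])[0]

    rows = _us(TAG_ROWS)
    cols = _us(TAG_COLS)
    bits = _us(TAG_BITS_ALLOCATED)
    if bits != 16:
        raise FormatError(f"{path}: only 16-bit pixel data is supported")
    if TAG_PIXEL_DATA not in elements:
        raise FormatError(f"{path}: missing pixel data")
    raw = elements[TAG_PIXEL_DATA][1]
    if len(raw) < 2 * rows * cols:
        raise FormatError(f"{path}: truncated pixel data")
    pixels = np.frombuffer(raw[: 2 * rows * cols], dtype="<u2").reshape(rows, cols)

    spacing_text = _text(TAG_PIXEL_SPACING)
    if spacing_text is None:
        raise FormatError(f"{path}: missing pixel spacing")
    parts = spacing_text.split("\\")
    spacing = (float(parts[0]), float(parts[1] if len(parts) > 1 else parts[0]))

    acq = _text(TAG_ACQ_TIME)
    trig = _text(TAG_TRIGGER_TIME)
    acq_s = None
    if acq:
        try:
            acq_s = _parse_tm(acq)
        except ValueError as exc:
            raise FormatError(f"{path}: bad AcquisitionTime {acq!r}") from exc
    trig_s = float(trig) / 1000.0 if trig else None

    inst = _text(TAG_INSTANCE_NUMBER)
    return {
        "pixels": pixels.copy(),
        "acquisition_seconds": acq_s,
        "trigger_seconds": trig_s,
        "pixel_spacing": spacing,
        "patient_id": _text(TAG_PATIENT_ID) or "",
        "series_description": _text(TAG_SERIES_DESC) or "",
        "instance_number": int(inst) if inst else None,
    }
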