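"""Minimal DICOM series codec (uncompressed explicit-VR little endian).

pydicom is not part of the runtime environment this package targets, so a
small self-contained reader/writer is bundled. It covers exactly what the
pipeline needs: single-frame 16-bit signed CT slices with pixel spacing,
image position, and rescale slope/intercept, one file per axial slice.
Anything outside that profile raises :class:`FormatError`.
"""

from __future__ import annotations

import os
import struct

import numpy as np

from ctradiomics.errors import FormatError

_EXPLICIT_VR_LE = "1.2.840.10008.1.2.1"
_CT_STORAGE = "1.2.840.10008.5.1.4.1.1.2"
_UID_ROOT = "1.2.826.0.1.3680043.10.1405"

# VRs whose explicit-VR encoding uses a 4-byte length after 2 reserved bytes
_LONG_VRS = {"OB", "OW", "OF", "SQ", "UT", "UN"}

TAG_SERIES_UID = (0x0020, 0x000E)
TAG_INSTANCE_NUMBER = (0x0020, 0x0013)
TAG_IMAGE_POSITION = (0x0020, 0x0032)
TAG_IMAGE_ORIENTATION = (0x0020, 0x0037)
TAG_ROWS = (0x0028, 0x0010)
TAG_COLS = (0x0028, 0x0011)
TAG_PIXEL_SPACING = (0x0028, 0x0030)
TAG_BITS_ALLOCATED = (0x0028, 0x0100)
TAG_PIXEL_REPRESENTATION = (0x0028, 0x0103)
TAG_RESCALE_INTERCEPT = (0x0028, 0x1052)
TAG_RESCALE_SLOPE = (0x0028, 0x1053)
TAG_PIXEL_DATA = (0x7FE0, 0x0010)


def _encode_element(group: int, elem: int, vr: str, value: bytes) -> bytes:
    if len(value) % 2:
        value += b"\x00" if vr != "UI" else b"\x00"
    head = struct.pack("<HH", group, elem) + vr.encode("ascii")
    if vr in _LONG_VRS:
        return head + b"\x00\x00" + struct.pack("<I", len(value)) + value
    return head + struct.pack("<H", len(value)) + value


def _ds(*values: float) -> bytes:
    return "\\".join(f"{v:.10g}" for v in values).encode("ascii")


def write_slice(
    path: str,
    pixels: np.ndarray,
    pixel_spacing_mm: tuple[float, float],
    position_mm: tuple[float, float, float],
    series_uid: str,
    instance_number: int,
    slope: float = 1.0,
    intercept: float = 0.0,
) -> None:
    """Write one int16 axial slice (``pixels`` indexed ``[row, col]``)."""
    pixels = np.asarray(pixels, dtype="<i2")
    rows, cols = pixels.shape
    sop_uid = f"{series_uid}.{instance_number}"

    meta_body = b"".join(
        [
            _encode_element(0x0002, 0x0002, "UI", _CT_STORAGE.encode()),
            _encode_element(0x0002, 0x0003, "UI", sop_uid.encode()),
            _encode_element(0x0002, 0x0010, "UI", _EXPLICIT_VR_LE.encode()),
        ]
    )
    meta = (
        _encode_element(0x0002, 0x0000, "UL", struct.pack("<I", len(meta_body)))
        + meta_body
    )

    # dataset elements must stay in ascending tag order
    elements = [
        _encode_element(0x0008, 0x0016, "UI", _CT_STORAGE.encode()),
        _encode_element(0x0008, 0x0018, "UI", sop_uid.encode()),
        _encode_element(0x0008, 0x0060, "CS", b"CT"),
        _encode_element(*TAG_SERIES_UID, "UI", series_uid.encode()),
        _encode_element(*TAG_INSTANCE_NUMBER, "IS", str(instance_number).encode()),
        _encode_element(*TAG_IMAGE_POSITION, "DS", _ds(*position_mm)),
        _encode_element(*TAG_IMAGE_ORIENTATION, "DS", _ds(1, 0, 0, 0, 1, 0)),
        _encode_element(0x0028, 0x0002, "US", struct.pack("<H", 1)),
        _encode_element(*TAG_ROWS, "US", struct.pack("<H", rows)),
        _encode_element(*TAG_COLS, "US", struct.pack("<H", cols)),
        # PixelSpacing is (row spacing, column spacing) = (dy, dx)
        _encode_element(
            *TAG_PIXEL_SPACING, "DS", _ds(pixel_spacing_mm[1], pixel_spacing_mm[0])
        ),
        _encode_element(*TAG_BITS_ALLOCATED, "US", struct.pack("<H", 16)),
        _encode_element(0x0028, 0x0101, "US", struct.pack("<H", 16)),
        _encode_element(0x0028, 0x0102, "US", struct.pack("<H", 15)),
        _encode_element(*TAG_PIXEL_REPRESENTATION, "US", struct.pack("<H", 1)),
        _encode_element(*TAG_RESCALE_INTERCEPT, "DS", _ds(intercept)),
        _encode_element(*TAG_RESCALE_SLOPE, "DS", _ds(slope)),
        _encode_element(*TAG_PIXEL_DATA, "OW", pixels.tobytes()),
    ]
    with open(path, "wb") as fh:
        fh.write(b"\x00" * 128 + b"DICM")
        fh.write(meta)
        fh.write(b"".join(elements))


def write_series(
    directory: str,
    intensities: np.ndarray,
    spacing_mm: tuple[float, float, float],
    origin_mm: tuple[float, float, float],
    slope: float = 1.0,
    intercept: float = 0.0,
) -> None:
    """Write an ``(x, y, z)`` HU grid as one ``.dcm`` file per z slice."""
    os.makedirs(directory, exist_ok=True)
    series_uid = f"{_UID_ROOT}.{abs(hash(directory)) % 10**8}"
    inv_slope = 1.0 / slope
    for k in range(intensities.shape[2]):
        stored = np.round((intensities[:, :, k] - intercept) * inv_slope)
        write_slice(
            os.path.join(directory, f"slice_{k:04d}.dcm"),
            stored.T.astype(np.int16),  # [row=y, col=x]
            (spacing_mm[0], spacing_mm[1]),
            (origin_mm[0], origin_mm[1], origin_mm[2] + k * spacing_mm[2]),
            series_uid,
            k + 1,
            slope=slope,
            intercept=intercept,
        )


def _parse_elements(buf: bytes, path: str) -> dict:
    """Parse explicit-VR-LE data elements into a tag -> raw-bytes map."""
    out: dict[tuple[int, int], bytes] = {}
    pos = 0
    n = len(buf)
    while pos + 8 <= n:
        group, elem = struct.unpack_from("<HH", buf, pos)
        vr = buf[pos + 4 : pos + 6].decode("ascii", errors="replace")
        if not vr.isalpha() or not vr.isupper():
            raise FormatError(f"{path}: implicit-VR or corrupt element at {pos}")
        if vr in _LONG_VRS:
            (length,) = struct.unpack_from("<I", buf, pos + 8)
            body = pos + 12
        else:
            (length,) = struct.unpack_from("<H", buf, pos + 6)
            body = pos + 8
        if vr == "SQ":
            raise FormatError(f"{path}: sequences are not supported")
        if length == 0xFFFFFFFF:
            raise FormatError(f"{path}: undefined-length element (compressed data?)")
        out[(group, elem)] = buf[body : body + length]
        pos = body + length
    return out


def _get_ds(elements: dict, tag, path: str) -> list[float]:
    if tag not in elements:
        raise FormatError(f"{path}: missing required tag {tag}")
    text = elements[tag].decode("ascii").strip("\x00 ").strip()
    return [float(v) for v in text.split("\\")]


def read_slice(path: str) -> dict:
    """Read one slice file into a dict of the fields the loader needs."""
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < 132 or raw[128:132] != b"DICM":
        raise FormatError(f"{path}: not a DICOM part-10 file")
    # file meta group: group length element then meta body
    group, elem = struct.unpack_from("<HH", raw, 132)
    if (group, elem) != (0x0002, 0x0000):
        raise FormatError(f"{path}: missing file meta group length")
    (meta_len,) = struct.unpack_from("<I", raw, 140)
    meta = _parse_elements(raw[144 : 144 + meta_len], path)
    tsuid = meta.get((0x0002, 0x0010), b"").decode("ascii").strip("\x00 ").strip()
    if tsuid != _EXPLICIT_VR_LE:
        raise FormatError(f"{path}: unsupported transfer syntax {tsuid!r}")
    elements = _parse_elements(raw[144 + meta_len :], path)

    if TAG_PIXEL_SPACING not in elements:
        raise FormatError(f"{path}: missing pixel spacing")
    rows = struct.unpack("<H", elements[TAG_ROWS])[0]
    cols = struct.unpack("<H", elements[TAG_COLS])[0]
    bits = struct.unpack("<H", elements[TAG_BITS_ALLOCATED])[0]
    if bits != 16:
        raise FormatError(f"{path}: only 16-bit pixel data is supported")
    signed = struct.unpack("<H", elements.get(TAG_PIXEL_REPRESENTATION, b"\x00\x00"))[0]
    dtype = "<i2" if signed else "<u2"
    pixels = np.frombuffer(elements[TAG_PIXEL_DATA], dtype=dtype)[: rows * cols]
    pixels = pixels.reshape(rows, cols)
    row_spacing, col_spacing = _get_ds(elements, TAG_PIXEL_SPACING, path)
    slope = _get_ds(elements, TAG_RESCALE_SLOPE, path)[0] if TAG_RESCALE_SLOPE in elements else 1.0
    intercept = (
        _get_ds(elements, TAG_RESCALE_INTERCEPT, path)[0]
        if TAG_RESCALE_INTERCEPT in elements
        else 0.0
    )
    series_uid = (
        elements.get(TAG_SERIES_UID, b"").decode("ascii").strip("\x00 ").strip()
    )
    position = (
        _get_ds(elements, TAG_IMAGE_POSITION, path)
        if TAG_IMAGE_POSITION in elements
        else [0.0, 0.0, 0.0]
    )
    return {
        "pixels": pixels,
        "spacing_xy": (col_spacing, row_spacing),
        "position": position,
        "slope": slope,
        "intercept": intercept,
        "series_uid": series_uid,
        "path": path,
    }


def read_series(directory: str, gap_tol_mm: float = 1e-3):
    """Assemble a directory of slice files into ``(grid, spacing, origin)``.

    Slices are sorted by their position along z regardless of filename
    order; mixed series UIDs, inconsistent in-plane geometry and
    non-uniform slice gaps beyond ``gap_tol_mm`` are format errors.
    """
    files = sorted(
        os.path.join(directory, f)
        for f in os.listdir(directory)
        if f.endswith(".dcm")
    )
    if not files:
        raise FormatError(f"{directory}: no .dcm files found")
    slices = [read_slice(f) for f in files]

    uids = {s["series_uid"] for s in slices}
    if len(uids) > 1:
        raise FormatError(f"{directory}: mixed series UIDs {sorted(uids)}")
    shapes = {s["pixels"].shape for s in slices}
    if len(shapes) > 1:
        raise FormatError(f"{directory}: inconsistent slice shapes {sorted(shapes)}")
    spacings = {s["spacing_xy"] for s in slices}
    if len(spacings) > 1:
        raise FormatError(f"{directory}: inconsistent pixel spacing")

    slices.sort(key=lambda s: s["position"][2])
    zs = np.array([s["position"][2] for s in slices])
    if len(zs) > 1:
        gaps = np.diff(zs)
        if gaps.min() <= 0:
            raise FormatError(f"{directory}: duplicate slice positions")
        if gaps.max() - gaps.min() > gap_tol_mm:
            raise FormatError(
                f"{directory}: non-uniform slice gap "
                f"(min {gaps.min():.6g}, max {gaps.max():.6g} mm)"
            )
        dz = float(gaps.mean())
    else:
        dz = 1.0

    first = slices[0]
    ny, nx = first["pixels"].shape
    grid = np.empty((nx, ny, len(slices)), dtype=np.float64)
    for k, s in enumerate(slices):
        grid[:, :, k] = s["pixels"].T * s["slope"] + s["intercept"]
    spacing = (first["spacing_xy"][0], first["spacing_xy"][1], dz)
    origin = (first["position"][0], first["position"][1], float(zs[0]))
    return grid, spacing, origin
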