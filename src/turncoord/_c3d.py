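"""Minimal C3D point-data reader/writer.

C3D is the motion-capture ecosystem's standard binary container. This module
implements the small subset the pipeline needs: Intel (little-endian)
byte order, floating-point 3D point data, the POINT parameter group
(USED/FRAMES/RATE/SCALE/DATA_START/LABELS/UNITS), and no analog channels.
Integer-scaled point data is also read (via POINT:SCALE), but files are
always written as float. Points with a negative residual are treated as
invalid and surfaced as NaN.

The layout follows the public C3D specification: a 512-byte header block,
a parameter section of group/parameter records, and 512-byte data blocks of
``frames x points x (x, y, z, residual)``.
"""

from __future__ import annotations

import struct

import numpy as np

_BLOCK = 512
_PROC_INTEL = 84  # processor type byte: 83 + 1


class C3DError(ValueError):
    """Raised for files outside the supported C3D subset or corrupt input."""


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _parse_parameters(buf: bytes) -> dict[str, dict[str, object]]:
    """Parse the parameter section into {GROUP: {PARAM: value}}."""
    if len(buf) < 4:
        raise C3DError("truncated parameter section")
    proc = buf[3]
    if proc != _PROC_INTEL:
        raise C3DError(f"unsupported processor type {proc} (only Intel/84)")
    groups_by_id: dict[int, str] = {}
    params: list[tuple[int, str, object]] = []
    pos = 4
    while pos + 2 <= len(buf):
        nname = struct.unpack_from("<b", buf, pos)[0]
        gid = struct.unpack_from("<b", buf, pos + 1)[0]
        if nname == 0:
            break
        nchars = abs(nname)
        name = buf[pos + 2 : pos + 2 + nchars].decode("ascii", "replace").upper()
        off_pos = pos + 2 + nchars
        offset = struct.unpack_from("<h", buf, off_pos)[0]
        if gid < 0:  # group record
            groups_by_id[-gid] = name
        else:  # parameter record
            p = off_pos + 2
            dtype = struct.unpack_from("<b", buf, p)[0]
            ndims = buf[p + 1]
            dims = list(buf[p + 2 : p + 2 + ndims])
            dstart = p + 2 + ndims
            count = int(np.prod(dims)) if dims else 1
            if dtype == -1:
                raw = buf[dstart : dstart + count]
                if len(dims) <= 1:
                    value = raw.decode("ascii", "replace")
                else:
                    width = dims[0]
                    n = count // width
                    value = [
                        raw[i * width : (i + 1) * width]
                        .decode("ascii", "replace")
                        .strip()
                        for i in range(n)
                    ]
            elif dtype in (1, 2, 4):
                fmt = {1: "b", 2: "h", 4: "f"}[dtype]
                vals = struct.unpack_from(f"<{count}{fmt}", buf, dstart)
                value = vals[0] if count == 1 else np.array(vals)
            else:
                raise C3DError(f"unknown parameter type {dtype} for {name}")
            params.append((gid, name, value))
        if offset <= 0:
            break
        pos = off_pos + offset
    out: dict[str, dict[str, object]] = {}
    for gid, name, value in params:
        gname = groups_by_id.get(gid, f"GROUP{gid}")
        out.setdefault(gname, {})[name] = value
    return out


def read(path):
    """Read point data from a C3D file.

    Returns
    -------
    points : (T, n_points, 3) float ndarray (NaN where invalid)
    labels : list of str
    rate : float, point frame rate in Hz
    units : str, e.g. ``"m"`` or ``"mm"``
    """
    with open(path, "rb") as fh:
        data = fh.read()
    if len(data) < _BLOCK:
        raise C3DError("file shorter than one block")
    param_block, magic = data[0], data[1]
    if magic != 0x50:
        raise C3DError("not a C3D file (bad magic byte)")
    header = struct.unpack_from("<4H f H H f f", data, 2)
    # n_points, analog_per_frame, first_frame, last_frame packed separately:
    n_points = struct.unpack_from("<H", data, 2)[0]
    first_frame = struct.unpack_from("<H", data, 6)[0]
    last_frame = struct.unpack_from("<H", data, 8)[0]
    del header

    pstart = (param_block - 1) * _BLOCK
    n_param_blocks = data[pstart + 2]
    pbuf = data[pstart : pstart + max(n_param_blocks, 1) * _BLOCK]
    params = _parse_parameters(pbuf)
    try:
        point = params["POINT"]
        used = int(point["USED"])
        frames = int(point["FRAMES"])
        rate = float(point["RATE"])
        scale = float(point["SCALE"])
        data_block = int(point["DATA_START"])
        labels = list(point["LABELS"])
    except KeyError as exc:
        raise C3DError(f"POINT parameter missing: {exc}") from exc
    units = str(point.get("UNITS", "m")).strip()
    if used != n_points:
        n_points = used
    if frames <= 0:
        frames = last_frame - first_frame + 1

    dstart = (data_block - 1) * _BLOCK
    count = frames * n_points * 4
    if scale < 0:
        raw = np.frombuffer(data, dtype="<f4", count=count, offset=dstart)
        arr = raw.reshape(frames, n_points, 4).astype(float)
        xyz = arr[:, :, :3]
        resid = arr[:, :, 3]
    else:
        raw = np.frombuffer(data, dtype="<i2", count=count, offset=dstart)
        arr = raw.reshape(frames, n_points, 4).astype(float)
        xyz = arr[:, :, :3] * scale
        resid = arr[:, :, 3]
    xyz = xyz.copy()
    xyz[resid < 0] = np.nan
    return xyz, labels[:n_points], rate, units


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _param_record(gid: int, name: str, dtype: int, dims: list[int], payload: bytes) -> bytes:
    rec = struct.pack("<bb", len(name), gid) + name.encode("ascii")
    body = struct.pack("<bb", dtype, len(dims)) + bytes(dims) + payload + b"\x00"
    rec += struct.pack("<h", 2 + len(body)) + body
    return rec


def _group_record(gid: int, name: str) -> bytes:
    rec = struct.pack("<bb", len(name), -gid) + name.encode("ascii")
    rec += struct.pack("<h", 3) + b"\x00"
    return rec


def write(path, points: np.ndarray, labels, rate: float, units: str = "m") -> None:
    """Write float point data to a C3D file.

    Parameters
    ----------
    points : (T, n_points, 3) array in ``units``; NaN rows are written as
        invalid points (residual -1).
    labels : sequence of marker names.
    rate : point frame rate in Hz.
    """
    points = np.asarray(points, dtype=float)
    frames, n_points, _ = points.shape
    if len(labels) != n_points:
        raise C3DError("labels/points mismatch")
    if frames > 65535:
        raise C3DError("more frames than the 16-bit header supports")

    width = max(4, max(len(l) for l in labels))
    label_payload = b"".join(l.ljust(width).encode("ascii") for l in labels)

    # parameter section: header word + POINT group + 7 parameters
    precs = [
        _group_record(1, "POINT"),
        _param_record(1, "USED", 2, [], struct.pack("<h", n_points)),
        _param_record(1, "FRAMES", 2, [], struct.pack("<h", frames)),
        _param_record(1, "RATE", 4, [], struct.pack("<f", rate)),
        _param_record(1, "SCALE", 4, [], struct.pack("<f", -1.0)),
        _param_record(1, "UNITS", -1, [len(units)], units.encode("ascii")),
        _param_record(1, "LABELS", -1, [width, n_points], label_payload),
    ]
    # DATA_START is patched once the parameter section length is known.
    ds_placeholder = _param_record(1, "DATA_START", 2, [], struct.pack("<h", 0))
    body = b"".join(precs) + ds_placeholder + struct.pack("<bb", 0, 0)
    n_param_blocks = -(-(len(body) + 4) // _BLOCK)
    data_block = 2 + n_param_blocks  # header block + parameter blocks, 1-based

    precs.append(_param_record(1, "DATA_START", 2, [], struct.pack("<h", data_block)))
    body = b"".join(precs) + struct.pack("<bb", 0, 0)
    param = struct.pack("<BBBB", 1, 0x50, n_param_blocks, _PROC_INTEL) + body
    param = param.ljust(n_param_blocks * _BLOCK, b"\x00")

    header = bytearray(_BLOCK)
    struct.pack_into("<BB", header, 0, 2, 0x50)  # parameters at block 2
    struct.pack_into("<H", header, 2, n_points)
    struct.pack_into("<H", header, 4, 0)  # no analog
    struct.pack_into("<H", header, 6, 1)  # first frame
    struct.pack_into("<H", header, 8, frames)
    struct.pack_into("<H", header, 10, 0)  # max interpolation gap
    struct.pack_into("<f", header, 12, -1.0)  # scale: float data
    struct.pack_into("<H", header, 16, data_block)
    struct.pack_into("<H", header, 18, 0)  # analog samples per frame
    struct.pack_into("<f", header, 20, rate)

    arr = np.zeros((frames, n_points, 4), dtype="<f4")
    arr[:, :, :3] = points
    invalid = np.isnan(points).any(axis=2)
    arr[:, :, 3] = np.where(invalid, -1.0, 0.0)
    arr[:, :, :3][invalid] = 0.0
    payload = arr.tobytes()
    payload = payload.ljust(-(-len(payload) // _BLOCK) * _BLOCK, b"\x00")

    with open(path, "wb") as fh:
        fh.write(bytes(header) + param + payload)
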