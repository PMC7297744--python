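"""Minimal LAS 1.2 reader/writer (point format 0 + appended extra bytes).

Supports exactly what the pipeline needs: XYZ at millimetre quantization,
return number / number of returns, and — as extra bytes appended to each
point record — the derived attributes (NormZ, layer, class id, maximum
class probability). VLRs, waveforms and CRS records are out of scope;
files written by other producers are readable as long as they use point
formats 0–3 and carry the return-number bits.

Extra-byte layout appended to each record when derived attributes are
persisted (9 bytes): norm_z float32 [m], layer uint8, class_id int16
(-1 = unset), max class probability uint16 quantized by 1/65535.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .pointcloud import Layer, PointCloud

__all__ = ["read_las", "write_las"]

_HEADER_SIZE = 227
_SCALE = 0.001
# bytes of the standard part of point formats 0..3
_BASE_LEN = {0: 20, 1: 28, 2: 26, 3: 34}
_EXTRA_DTYPE = np.dtype([
    ("norm_z", "<f4"), ("layer", "u1"), ("class_id", "<i2"), ("max_prob", "<u2"),
])


def _point_dtype(fmt: int, extra: bool) -> np.dtype:
    fields = [("X", "<i4"), ("Y", "<i4"), ("Z", "<i4"),
              ("intensity", "<u2"), ("flags", "u1"), ("classification", "u1"),
              ("scan_angle", "i1"), ("user_data", "u1"), ("point_source", "<u2")]
    if fmt in (1, 3):
        fields.append(("gps_time", "<f8"))
    if fmt in (2, 3):
        fields += [("red", "<u2"), ("green", "<u2"), ("blue", "<u2")]
    if extra:
        fields += [(n, _EXTRA_DTYPE[n]) for n in _EXTRA_DTYPE.names]
    return np.dtype(fields)


def read_las(path: str | Path) -> PointCloud:
    """Read a LAS 1.x file (point formats 0–3) into a :class:`PointCloud`.

    Raises
    ------
    ValueError
        On a malformed header, an unsupported point format, or when the
        return-number attributes are absent (all-zero return bits).
    """
    raw = Path(path).read_bytes()
    if raw[:4] != b"LASF":
        raise ValueError(f"{path}: not a LAS file (bad signature)")
    fmt = raw[104]
    rec_len = struct.unpack_from("<H", raw, 105)[0]
    offset = struct.unpack_from("<I", raw, 96)[0]
    n = struct.unpack_from("<I", raw, 107)[0]
    sx, sy, sz, ox, oy, oz = struct.unpack_from("<6d", raw, 131)
    if fmt not in _BASE_LEN:
        raise ValueError(f"{path}: unsupported point data format {fmt}")
    base = _BASE_LEN[fmt]
    extra = rec_len == base + _EXTRA_DTYPE.itemsize
    if rec_len < base:
        raise ValueError(f"{path}: point record length {rec_len} below "
                         f"format-{fmt} minimum {base}")
    dtype = _point_dtype(fmt, extra)
    body = raw[offset:offset + n * rec_len]
    if len(body) < n * rec_len:
        raise ValueError(f"{path}: truncated point data")
    if rec_len == dtype.itemsize:
        rec = np.frombuffer(body, dtype=dtype, count=n)
    else:  # unknown trailing bytes: read the known prefix of each record
        rows = np.frombuffer(body, dtype=np.uint8).reshape(n, rec_len)
        rec = rows[:, :dtype.itemsize].copy().view(dtype).reshape(n)
    echo_index = (rec["flags"] & 0x07).astype(np.int32)
    num_echoes = ((rec["flags"] >> 3) & 0x07).astype(np.int32)
    if n and (np.all(echo_index == 0) or np.all(num_echoes == 0)):
        raise ValueError(
            f"{path}: return number / number of returns bits are all zero — "
            "echo attributes are required")
    kwargs = {}
    if extra:
        norm_z = rec["norm_z"].astype(np.float64)
        norm_z[~np.isfinite(norm_z)] = np.nan
        kwargs = dict(
            norm_z=norm_z,
            layer=rec["layer"].astype(np.uint8),
            class_id=rec["class_id"].astype(np.int32),
        )
    cloud = PointCloud(
        x=rec["X"] * sx + ox, y=rec["Y"] * sy + oy, z=rec["Z"] * sz + oz,
        echo_index=echo_index, num_echoes=num_echoes, **kwargs,
    )
    if extra:
        cloud.max_class_prob = rec["max_prob"].astype(np.float64) / 65535.0
    return cloud


def write_las(cloud: PointCloud, path: str | Path) -> None:
    """Write a :class:`PointCloud` as LAS 1.2 point format 0.

    Derived attributes (norm_z / layer / class_id / max class probability)
    are appended as extra bytes whenever any of them is set, so a
    classified cloud round-trips through :func:`read_las`.
    """
    if len(cloud) == 0:
        raise ValueError("refusing to write an empty point cloud")
    has_derived = (np.any(np.isfinite(cloud.norm_z))
                   or np.any(cloud.layer != Layer.UNSET)
                   or np.any(cloud.class_id >= 0)
                   or cloud.class_probs is not None)
    dtype = _point_dtype(0, has_derived)
    rec = np.zeros(len(cloud), dtype=dtype)
    ox = float(np.floor(cloud.x.min()))
    oy = float(np.floor(cloud.y.min()))
    oz = float(np.floor(cloud.z.min()))
    rec["X"] = np.round((cloud.x - ox) / _SCALE).astype(np.int64)
    rec["Y"] = np.round((cloud.y - oy) / _SCALE).astype(np.int64)
    rec["Z"] = np.round((cloud.z - oz) / _SCALE).astype(np.int64)
    rec["flags"] = ((cloud.echo_index & 0x07)
                    | ((cloud.num_echoes & 0x07) << 3)).astype(np.uint8)
    if has_derived:
        nz = cloud.norm_z.astype(np.float32)
        rec["norm_z"] = np.where(np.isfinite(nz), nz, np.float32(np.nan))
        rec["layer"] = cloud.layer
        rec["class_id"] = np.clip(cloud.class_id, -1, 32767).astype(np.int16)
        if cloud.class_probs is not None:
            mp = cloud.class_probs.max(axis=1)
        else:
            mp = np.zeros(len(cloud))
        rec["max_prob"] = np.round(mp * 65535).astype(np.uint16)

    header = bytearray(_HEADER_SIZE)
    header[0:4] = b"LASF"
    header[24] = 1  # version major
    header[25] = 2  # version minor
    struct.pack_into("<32s", header, 26, b"shrubscan")
    struct.pack_into("<H", header, 94, _HEADER_SIZE)
    struct.pack_into("<I", header, 96, _HEADER_SIZE)  # offset to point data
    header[104] = 0  # point data format
    struct.pack_into("<H", header, 105, dtype.itemsize)
    struct.pack_into("<I", header, 107, len(cloud))
    struct.pack_into("<I", header, 111, len(cloud))  # returns-by-count[0]
    struct.pack_into("<6d", header, 131, _SCALE, _SCALE, _SCALE, ox, oy, oz)
    struct.pack_into("<6d", header, 179,
                     cloud.x.max(), cloud.x.min(),
                     cloud.y.max(), cloud.y.min(),
                     cloud.z.max(), cloud.z.min())
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(rec.tobytes())
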