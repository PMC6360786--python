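"""Point-cloud and raster file I/O.

Supports LAS 1.2/1.4 (point formats 0-8, coordinates + classification),
PLY (ASCII and binary little-endian) and whitespace-delimited XYZ text.
DTM rasters are written as ESRI ASCII grids.  Only the fields the
pipeline consumes (coordinates, class labels) are preserved.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .cloud import GROUND, OUTLIER, UNLABELED, VEGETATION, PointCloud
from .errors import FileFormatError

_LAS_HEADER_12 = 227
# ours -> ASPRS class codes
_TO_LAS = {UNLABELED: 1, GROUND: 2, VEGETATION: 4, OUTLIER: 7}
_FROM_LAS = {1: UNLABELED, 2: GROUND, 3: VEGETATION, 4: VEGETATION,
             5: VEGETATION, 7: OUTLIER}

_PLY_TYPES = {
    "char": "i1", "int8": "i1", "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2", "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4", "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4", "double": "f8", "float64": "f8",
}


def read_cloud(path, fmt: str | None = None) -> PointCloud:
    """Read a point cloud, inferring the format from the extension."""
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "las":
        return _read_las(path)
    if fmt == "ply":
        return _read_ply(path)
    if fmt in ("xyz", "txt"):
        return _read_xyz(path)
    raise FileFormatError(f"unsupported point-cloud format: {fmt!r}")


def write_cloud(cloud: PointCloud, path, fmt: str | None = None,
                binary: bool = True) -> None:
    """Write a point cloud; format inferred from the extension."""
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "las":
        _write_las(cloud, path)
    elif fmt == "ply":
        _write_ply(cloud, path, binary=binary)
    elif fmt in ("xyz", "txt"):
        _write_xyz(cloud, path)
    else:
        raise FileFormatError(f"unsupported point-cloud format: {fmt!r}")


# ---------------------------------------------------------------- LAS

def _write_las(cloud: PointCloud, path: Path, scale: float = 0.001) -> None:
    xyz = cloud.xyz
    n = len(xyz)
    offset = xyz.min(axis=0) if n else np.zeros(3)
    header = bytearray(_LAS_HEADER_12)
    struct.pack_into("<4s", header, 0, b"LASF")
    struct.pack_into("<BB", header, 24, 1, 2)
    struct.pack_into("<32s", header, 26, b"lidarpheno")
    struct.pack_into("<32s", header, 58, b"lidarpheno")
    struct.pack_into("<H", header, 94, _LAS_HEADER_12)
    struct.pack_into("<I", header, 96, _LAS_HEADER_12)
    struct.pack_into("<B", header, 104, 0)
    struct.pack_into("<H", header, 105, 20)
    struct.pack_into("<I", header, 107, n)
    struct.pack_into("<3d", header, 131, scale, scale, scale)
    struct.pack_into("<3d", header, 155, *offset)
    if n:
        mx, mn = xyz.max(axis=0), xyz.min(axis=0)
    else:
        mx = mn = np.zeros(3)
    struct.pack_into("<6d", header, 179,
                     mx[0], mn[0], mx[1], mn[1], mx[2], mn[2])

    rec = np.zeros(n, dtype=[("X", "<i4"), ("Y", "<i4"), ("Z", "<i4"),
                             ("intensity", "<u2"), ("flags", "u1"),
                             ("cls", "u1"), ("angle", "i1"), ("user", "u1"),
                             ("src", "<u2")])
    quant = np.round((xyz - offset) / scale).astype(np.int64)
    if n and (np.abs(quant) > np.iinfo(np.int32).max).any():
        raise FileFormatError("coordinates overflow LAS int32 at this scale")
    rec["X"], rec["Y"], rec["Z"] = quant.T.astype(np.int32)
    rec["flags"] = 1  # single return, first of one
    rec["cls"] = np.vectorize(_TO_LAS.get)(cloud.labels) if n else 0
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(rec.tobytes())


def _read_las(path: Path) -> PointCloud:
    raw = Path(path).read_bytes()
    if len(raw) < _LAS_HEADER_12 or raw[:4] != b"LASF":
        raise FileFormatError(f"{path}: not a LAS file (bad signature)")
    minor = raw[25]
    point_offset, = struct.unpack_from("<I", raw, 96)
    point_format = raw[104] & 0x3F
    record_len, = struct.unpack_from("<H", raw, 105)
    count, = struct.unpack_from("<I", raw, 107)
    if minor >= 4 and count == 0:
        count, = struct.unpack_from("<Q", raw, 247)
    scale = np.array(struct.unpack_from("<3d", raw, 131))
    offset = np.array(struct.unpack_from("<3d", raw, 155))
    cls_off = 15 if point_format <= 5 else 16
    if record_len < cls_off + 1:
        raise FileFormatError(f"{path}: point record too short ({record_len})")
    dt = np.dtype({"names": ["X", "Y", "Z", "cls"],
                   "formats": ["<i4", "<i4", "<i4", "u1"],
                   "offsets": [0, 4, 8, cls_off],
                   "itemsize": record_len})
    end = point_offset + count * record_len
    if end > len(raw):
        raise FileFormatError(
            f"{path}: truncated at point record "
            f"{(len(raw) - point_offset) // record_len}")
    rec = np.frombuffer(raw, dtype=dt, count=count, offset=point_offset)
    xyz = np.stack([rec["X"] * scale[0] + offset[0],
                    rec["Y"] * scale[1] + offset[1],
                    rec["Z"] * scale[2] + offset[2]], axis=1)
    cls = rec["cls"] & (0x1F if point_format <= 5 else 0xFF)
    labels = np.array([_FROM_LAS.get(int(c), UNLABELED) for c in cls],
                      dtype=np.int8)
    return PointCloud(xyz, labels)


# ---------------------------------------------------------------- PLY

def _write_ply(cloud: PointCloud, path: Path, binary: bool = True) -> None:
    n = len(cloud)
    fmt = "binary_little_endian" if binary else "ascii"
    header = (
        "ply\n"
        f"format {fmt} 1.0\n"
        f"element vertex {n}\n"
        "property double x\n"
        "property double y\n"
        "property double z\n"
        "property uchar label\n"
        "end_header\n"
    )
    rec = np.zeros(n, dtype=[("x", "<f8"), ("y", "<f8"), ("z", "<f8"),
                             ("label", "u1")])
    rec["x"], rec["y"], rec["z"] = cloud.xyz.T
    rec["label"] = cloud.labels.astype(np.uint8)
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        if binary:
            fh.write(rec.tobytes())
        else:
            for r in rec:
                fh.write(f"{float(r['x'])!r} {float(r['y'])!r} "
                         f"{float(r['z'])!r} "
                         f"{int(r['label'])}\n".encode("ascii"))


def _read_ply(path: Path) -> PointCloud:
    raw = Path(path).read_bytes()
    end = raw.find(b"end_header\n")
    if not raw.startswith(b"ply") or end < 0:
        raise FileFormatError(f"{path}: not a PLY file")
    header_lines = raw[:end].decode("ascii", "replace").splitlines()
    body = raw[end + len(b"end_header\n"):]

    fmt = None
    elements: list[tuple[str, int, list[tuple[str, str]]]] = []
    for i, line in enumerate(header_lines):
        tok = line.split()
        if not tok:
            continue
        if tok[0] == "format":
            fmt = tok[1]
        elif tok[0] == "element":
            elements.append((tok[1], int(tok[2]), []))
        elif tok[0] == "property":
            if not elements:
                raise FileFormatError(f"{path}: property before element "
                                      f"(header line {i + 1})")
            if tok[1] == "list":
                elements[-1][2].append(("list", tok[-1]))
            else:
                if tok[1] not in _PLY_TYPES:
                    raise FileFormatError(
                        f"{path}: unknown property type {tok[1]!r}")
                elements[-1][2].append((tok[1], tok[-1]))
    if fmt not in ("ascii", "binary_little_endian"):
        raise FileFormatError(f"{path}: unsupported PLY format {fmt!r}")
    if not elements or elements[0][0] != "vertex":
        raise FileFormatError(f"{path}: first element must be 'vertex'")
    name, count, props = elements[0]
    if any(t == "list" for t, _ in props):
        raise FileFormatError(f"{path}: list properties on vertices")
    names = [p for _, p in props]
    formats = ["<" + _PLY_TYPES[t] for t, _ in props]
    dt = np.dtype({"names": names, "formats": formats})
    for axis in "xyz":
        if axis not in names:
            raise FileFormatError(f"{path}: vertex lacks property {axis!r}")

    if fmt == "binary_little_endian":
        need = count * dt.itemsize
        if len(body) < need:
            raise FileFormatError(
                f"{path}: truncated at vertex {len(body) // dt.itemsize}")
        rec = np.frombuffer(body, dtype=dt, count=count)
    else:
        text = body.decode("ascii", "replace").split("\n")
        rows = [ln.split() for ln in text[:count]]
        for j, r in enumerate(rows):
            if len(r) != len(props):
                raise FileFormatError(f"{path}: malformed vertex row {j + 1}")
        rec = np.zeros(count, dtype=dt)
        arr = np.array(rows, dtype=np.float64).reshape(count, len(props))
        for j, nm in enumerate(names):
            rec[nm] = arr[:, j]

    xyz = np.stack([rec["x"], rec["y"], rec["z"]], axis=1).astype(np.float64)
    labels = rec["label"].astype(np.int8) if "label" in names else None
    return PointCloud(xyz, labels)


# ---------------------------------------------------------------- XYZ

def _write_xyz(cloud: PointCloud, path: Path) -> None:
    data = np.column_stack([cloud.xyz, cloud.labels])
    np.savetxt(path, data, fmt=("%.6f", "%.6f", "%.6f", "%d"))


def _read_xyz(path: Path) -> PointCloud:
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            tok = line.split()
            if not tok or tok[0].startswith("#"):
                continue
            if len(tok) < 3:
                raise FileFormatError(f"{path}: line {i}: expected >= 3 "
                                      f"columns, got {len(tok)}")
            try:
                rows.append([float(v) for v in tok[:4]])
            except ValueError as exc:
                raise FileFormatError(f"{path}: line {i}: {exc}") from exc
    if not rows:
        return PointCloud(np.empty((0, 3)))
    width = min(len(r) for r in rows)
    arr = np.array([r[:width] for r in rows])
    labels = arr[:, 3].astype(np.int8) if width >= 4 else None
    return PointCloud(arr[:, :3], labels)


# ------------------------------------------------------------ rasters

def write_ascii_grid(grid: np.ndarray, origin: tuple[float, float],
                     resolution: float, path, nodata: float = -9999.0) -> None:
    """Write an elevation grid (row 0 = south) as an ESRI ASCII raster."""
    grid = np.asarray(grid, dtype=np.float64)
    nrows, ncols = grid.shape
    out = np.where(np.isfinite(grid), grid, nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\nnrows {nrows}\n"
                 f"xllcorner {float(origin[0])!r}\n"
                 f"yllcorner {float(origin[1])!r}\n"
                 f"cellsize {float(resolution)!r}\n"
                 f"NODATA_value {float(nodata)!r}\n")
        for row in out[::-1]:  # ESRI rasters are written north to south
            fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")


def read_ascii_grid(path) -> tuple[np.ndarray, tuple[float, float], float]:
    with open(path) as fh:
        meta = {}
        for _ in range(6):
            key, val = fh.readline().split()
            meta[key.lower()] = float(val)
        data = np.loadtxt(fh)
    grid = np.atleast_2d(data)[::-1]
    grid = np.where(grid == meta.get("nodata_value", -9999.0), np.nan, grid)
    return grid, (meta["xllcorner"], meta["yllcorner"]), meta["cellsize"]
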