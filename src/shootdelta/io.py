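"""Point-cloud file I/O: PLY (ASCII / binary little-endian), PCD, xyz text.

Only the vertex geometry plus scalar per-point properties are handled —
enough to round-trip clouds with organ/shoot/status labels between stages.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np

from .cloud import PointCloud
from .exceptions import CloudIOError, CloudParseError, EmptyCloudError

__all__ = ["read_cloud", "write_cloud"]

_PLY_DTYPES = {
    "char": "i1", "int8": "i1",
    "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2",
    "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4",
    "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4",
    "double": "f8", "float64": "f8",
}


def _sniff_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("ply", "pcd", "xyz"):
        return suffix
    with open(path, "rb") as fh:
        head = fh.read(64)
    if head.startswith(b"ply"):
        return "ply"
    if b"VERSION" in head or head.startswith(b"#"):
        return "pcd" if b"PCD" in head else "xyz"
    return "xyz"


def read_cloud(path: str | os.PathLike, format: str = "auto") -> PointCloud:
    """Read a point cloud, assigning ids 0..N-1 in file order.

    Parameters
    ----------
    path : path to a .ply, .pcd or whitespace-delimited xyz text file.
    format : "ply", "pcd", "xyz" or "auto" (sniff from suffix/content).

    xyz dialect: '#'-prefixed comment lines are skipped; columns beyond
    x y z are preserved as string label columns ``col3``, ``col4``, ...
    """
    path = Path(path)
    if not path.is_file():
        raise CloudIOError(f"no such file: {path}")
    fmt = _sniff_format(path) if format == "auto" else format
    if fmt == "ply":
        cloud = _read_ply(path)
    elif fmt == "pcd":
        cloud = _read_pcd(path)
    elif fmt == "xyz":
        cloud = _read_xyz(path)
    else:
        raise CloudIOError(f"unknown format {format!r}")
    if len(cloud) == 0:
        raise EmptyCloudError(f"{path}: file contains zero points")
    return cloud


def write_cloud(cloud: PointCloud, path: str | os.PathLike, format: str = "auto") -> None:
    """Write a cloud as ASCII PLY or xyz text; labels become extra columns."""
    path = Path(path)
    if not path.parent.is_dir():
        raise CloudIOError(f"parent directory does not exist: {path.parent}")
    fmt = path.suffix.lower().lstrip(".") if format == "auto" else format
    if fmt == "ply":
        _write_ply(cloud, path)
    elif fmt == "xyz":
        _write_xyz(cloud, path)
    else:
        raise CloudIOError(f"unsupported output format {fmt!r}")


# ---------------------------------------------------------------- PLY


def _read_ply(path: Path) -> PointCloud:
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic != b"ply":
            raise CloudParseError(f"{path}: not a PLY file", line=1)
        fmt = None
        n_vertices = None
        props: list[tuple[str, str]] = []
        categories: dict[str, list[str]] = {}
        in_vertex = False
        lineno = 1
        while True:
            raw = fh.readline()
            lineno += 1
            if not raw:
                raise CloudParseError("unexpected end of PLY header", line=lineno)
            tokens = raw.decode("ascii", "replace").split()
            if not tokens:
                continue
            if tokens[0] == "comment":
                if len(tokens) >= 3 and tokens[1] == "categories":
                    categories[tokens[2]] = tokens[3:]
            elif tokens[0] == "format":
                fmt = tokens[1]
            elif tokens[0] == "element":
                in_vertex = tokens[1] == "vertex"
                if in_vertex:
                    n_vertices = int(tokens[2])
            elif tokens[0] == "property" and in_vertex:
                if tokens[1] == "list":
                    raise CloudParseError("list properties on vertex unsupported", line=lineno)
                props.append((tokens[2], tokens[1]))
            elif tokens[0] == "end_header":
                break
        if fmt not in ("ascii", "binary_little_endian"):
            raise CloudParseError(f"unsupported PLY format {fmt!r}")
        if n_vertices is None:
            raise CloudParseError("PLY header has no vertex element")
        names = [name for name, _ in props]
        for axis in ("x", "y", "z"):
            if axis not in names:
                raise CloudParseError(f"PLY vertex element lacks property {axis!r}")
        dtype = np.dtype([(name, _PLY_DTYPES[t]) for name, t in props])
        if fmt == "ascii":
            rows = []
            for _ in range(n_vertices):
                raw = fh.readline()
                lineno += 1
                vals = raw.split()
                if len(vals) != len(props):
                    raise CloudParseError(
                        f"expected {len(props)} values, got {len(vals)}", line=lineno
                    )
                rows.append(tuple(float(v) for v in vals))
            data = np.array(rows, dtype=dtype) if rows else np.empty(0, dtype=dtype)
        else:
            data = np.fromfile(fh, dtype=dtype.newbyteorder("<"), count=n_vertices)
            if len(data) != n_vertices:
                raise CloudParseError(
                    f"binary PLY truncated: {len(data)}/{n_vertices} vertices"
                )
    points = np.column_stack([data["x"], data["y"], data["z"]]).astype(np.float64)
    labels = {}
    ids = None
    for name, _ in props:
        if name in ("x", "y", "z"):
            continue
        if name == "point_id":
            ids = data[name].astype(np.int64)
        elif name.endswith("__cat") and name[:-5] in categories:
            cats = np.asarray(categories[name[:-5]], dtype="U32")
            labels[name[:-5]] = cats[data[name].astype(np.int64)]
        else:
            labels[name] = np.asarray(data[name])
    return PointCloud(points=points, ids=ids, labels=labels)


def _write_ply(cloud: PointCloud, path: Path) -> None:
    cols: list[tuple[str, str, np.ndarray]] = [
        ("x", "double", cloud.x),
        ("y", "double", cloud.y),
        ("z", "double", cloud.z),
        ("point_id", "int", cloud.ids),
    ]
    for key, col in cloud.labels.items():
        col = np.asarray(col)
        if col.dtype.kind in "iub":
            cols.append((key, "int", col.astype(np.int64)))
        elif col.dtype.kind == "f":
            cols.append((key, "double", col.astype(np.float64)))
        else:
            # strings encoded as a categorical int column plus a header comment
            cats, codes = np.unique(col.astype(str), return_inverse=True)
            cols.append((f"{key}__cat", "int", codes))
            cols.append(("__comment__" + key, "", cats))
    try:
        with open(path, "w") as fh:
            fh.write("ply\nformat ascii 1.0\n")
            for name, typ, data in cols:
                if name.startswith("__comment__"):
                    key = name[len("__comment__"):]
                    fh.write(f"comment categories {key} " + " ".join(data) + "\n")
            fh.write(f"element vertex {len(cloud)}\n")
            for name, typ, _ in cols:
                if not name.startswith("__comment__"):
                    fh.write(f"property {typ} {name}\n")
            fh.write("end_header\n")
            writable = [(t, np.asarray(d)) for n, t, d in cols
                        if not n.startswith("__comment__")]
            for i in range(len(cloud)):
                cells = [f"{d[i]:.9g}" if t == "double" else str(int(d[i]))
                         for t, d in writable]
                fh.write(" ".join(cells) + "\n")
    except OSError as exc:
        raise CloudIOError(f"cannot write {path}: {exc}") from exc


# ---------------------------------------------------------------- PCD


def _read_pcd(path: Path) -> PointCloud:
    with open(path, "r") as fh:
        header: dict[str, list[str]] = {}
        lineno = 0
        for raw in fh:
            lineno += 1
            if raw.startswith("#"):
                continue
            tokens = raw.split()
            if not tokens:
                continue
            header[tokens[0].upper()] = tokens[1:]
            if tokens[0].upper() == "DATA":
                if tokens[1] != "ascii":
                    raise CloudParseError("only ASCII PCD supported", line=lineno)
                break
        fields = header.get("FIELDS", ["x", "y", "z"])
        n = int(header.get("POINTS", [0])[0])
        rows = []
        for raw in fh:
            lineno += 1
            if raw.strip():
                vals = raw.split()
                if len(vals) != len(fields):
                    raise CloudParseError(
                        f"expected {len(fields)} fields, got {len(vals)}", line=lineno
                    )
                rows.append([float(v) for v in vals])
        if len(rows) != n:
            raise CloudParseError(f"PCD declares {n} points but has {len(rows)}")
    data = np.asarray(rows, dtype=np.float64).reshape(len(rows), len(fields))
    idx = {f: i for i, f in enumerate(fields)}
    for axis in ("x", "y", "z"):
        if axis not in idx:
            raise CloudParseError(f"PCD lacks field {axis!r}")
    points = data[:, [idx["x"], idx["y"], idx["z"]]]
    labels = {f: data[:, i] for f, i in idx.items() if f not in ("x", "y", "z")}
    return PointCloud(points=points, labels=labels)


# ---------------------------------------------------------------- xyz


def _read_xyz(path: Path) -> PointCloud:
    pts: list[tuple[float, float, float]] = []
    extras: list[list[str]] = []
    n_extra = None
    col_names: list[str] | None = None
    with open(path, "r") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if line.startswith("# columns:"):
                col_names = line[len("# columns:"):].split()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) < 3:
                raise CloudParseError(f"need at least 3 columns, got {len(tokens)}", line=lineno)
            try:
                xyz = (float(tokens[0]), float(tokens[1]), float(tokens[2]))
            except ValueError as exc:
                raise CloudParseError(str(exc), line=lineno) from exc
            extra = tokens[3:]
            if n_extra is None:
                n_extra = len(extra)
            elif len(extra) != n_extra:
                raise CloudParseError(
                    f"inconsistent column count ({3 + len(extra)} vs {3 + n_extra})",
                    line=lineno,
                )
            pts.append(xyz)
            extras.append(extra)
    points = np.asarray(pts, dtype=np.float64).reshape(len(pts), 3)
    labels = {}
    if n_extra:
        cols = list(zip(*extras))
        for j, col in enumerate(cols):
            if col_names is not None and len(col_names) == 3 + n_extra:
                name = col_names[3 + j]
            else:
                name = f"col{3 + j}"
            arr = np.asarray(col, dtype="U32")
            try:  # numeric columns come back numeric
                arr = arr.astype(np.float64)
                if np.all(arr == np.round(arr)):
                    arr = arr.astype(np.int64)
            except ValueError:
                pass
            labels[name] = arr
    return PointCloud(points=points, labels=labels)


def _write_xyz(cloud: PointCloud, path: Path) -> None:
    try:
        with open(path, "w") as fh:
            keys = list(cloud.labels)
            if keys:
                fh.write("# columns: x y z " + " ".join(keys) + "\n")
            for i in range(len(cloud)):
                row = [f"{c:.9g}" for c in cloud.points[i]]
                row += [str(cloud.labels[k][i]) for k in keys]
                fh.write(" ".join(row) + "\n")
    except OSError as exc:
        raise CloudIOError(f"cannot write {path}: {exc}") from exc
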