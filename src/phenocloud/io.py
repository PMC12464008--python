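"""Reading and writing labeled point clouds.

Two formats are supported:

* PLY (``element vertex`` with float ``x,y,z`` and optional integer ``label``
  and ``instance`` properties), ASCII or binary little-endian;
* whitespace-separated ASCII ``x y z [label] [instance]`` with ``#`` comments,
  the dialect CloudCompare exports.
"""

from __future__ import annotations

import struct
from pathlib import Path
from typing import Optional

import numpy as np

from .cloud import LabeledCloud


class CloudParseError(ValueError):
    """Malformed point-cloud file; the message names the offending element."""


_PLY_TYPES = {
    "char": "i1", "int8": "i1",
    "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2",
    "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4",
    "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4",
    "double": "f8", "float64": "f8",
}


def _sniff_format(path: Path, format: Optional[str]) -> str:
    if format is not None:
        fmt = format.lower()
        if fmt not in ("ply", "xyz", "ascii"):
            raise ValueError(f"unknown format {format!r}")
        return "ply" if fmt == "ply" else "xyz"
    if path.suffix.lower() == ".ply":
        return "ply"
    return "xyz"


def read_cloud(path, format: Optional[str] = None) -> LabeledCloud:
    """Load a cloud from a PLY or ASCII-XYZ[L] file, preserving row order."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _sniff_format(path, format) == "ply":
        return _read_ply(path)
    return _read_xyz(path)


def write_cloud(cloud: LabeledCloud, path, format: Optional[str] = None,
                binary: bool = True) -> None:
    """Write a cloud; PLY gains ``label``/``instance`` properties when present."""
    path = Path(path)
    if _sniff_format(path, format) == "ply":
        _write_ply(cloud, path, binary=binary)
    else:
        _write_xyz(cloud, path)


def _read_xyz(path: Path) -> LabeledCloud:
    coords, labels, instances = [], [], []
    ncols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if ncols is None:
                if len(parts) not in (3, 4, 5):
                    raise CloudParseError(
                        f"{path}:{lineno}: expected 3-5 columns, got {len(parts)}"
                    )
                ncols = len(parts)
            elif len(parts) != ncols:
                raise CloudParseError(
                    f"{path}:{lineno}: inconsistent column count "
                    f"({len(parts)} vs {ncols})"
                )
            try:
                coords.append([float(v) for v in parts[:3]])
                if ncols >= 4:
                    labels.append(int(float(parts[3])))
                if ncols == 5:
                    instances.append(int(float(parts[4])))
            except ValueError as exc:
                raise CloudParseError(f"{path}:{lineno}: {exc}") from exc
    if not coords:
        raise CloudParseError(f"{path}: no points found")
    return LabeledCloud(
        coords=np.array(coords),
        semantic_labels=np.array(labels) if labels else None,
        instance_ids=np.array(instances) if instances else None,
    )


def _write_xyz(cloud: LabeledCloud, path: Path) -> None:
    cols = [cloud.coords]
    fmts = ["%.9g", "%.9g", "%.9g"]
    if cloud.semantic_labels is not None:
        cols.append(cloud.semantic_labels[:, None])
        fmts.append("%d")
    if cloud.instance_ids is not None:
        if cloud.semantic_labels is None:
            raise ValueError("cannot write instance ids without semantic labels")
        cols.append(cloud.instance_ids[:, None])
        fmts.append("%d")
    np.savetxt(path, np.hstack(cols), fmt=fmts)


def _read_ply(path: Path) -> LabeledCloud:
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic != b"ply":
            raise CloudParseError(f"{path}: missing 'ply' magic")
        fmt = None
        n_vertex = None
        props: list[tuple[str, str]] = []  # (dtype code, name)
        in_vertex = False
        while True:
            raw = fh.readline()
            if not raw:
                raise CloudParseError(f"{path}: header ended before end_header")
            line = raw.decode("ascii", "replace").strip()
            if line == "end_header":
                break
            tok = line.split()
            if not tok or tok[0] == "comment":
                continue
            if tok[0] == "format":
                fmt = tok[1]
            elif tok[0] == "element":
                in_vertex = tok[1] == "vertex"
                if in_vertex:
                    n_vertex = int(tok[2])
            elif tok[0] == "property" and in_vertex:
                if tok[1] == "list":
                    raise CloudParseError(f"{path}: list property on vertex unsupported")
                if tok[1] not in _PLY_TYPES:
                    raise CloudParseError(f"{path}: unknown property type {tok[1]}")
                props.append((_PLY_TYPES[tok[1]], tok[2]))
        if fmt is None or n_vertex is None:
            raise CloudParseError(f"{path}: header lacks format or vertex element")
        names = [p[1] for p in props]
        for ax in "xyz":
            if ax not in names:
                raise CloudParseError(f"{path}: vertex element lacks property {ax}")
        if fmt == "ascii":
            rows = []
            while len(rows) < n_vertex:
                raw = fh.readline()
                if not raw:
                    raise CloudParseError(
                        f"{path}: expected {n_vertex} vertices, got {len(rows)}"
                    )
                line = raw.decode("ascii", "replace").strip()
                if not line:
                    continue
                rows.append(line.split())
            data = {
                name: np.array([r[i] for r in rows], dtype=np.dtype(code))
                for i, (code, name) in enumerate(props)
            }
        elif fmt in ("binary_little_endian", "binary_big_endian"):
            endian = "<" if fmt == "binary_little_endian" else ">"
            dtype = np.dtype([(name, endian + code) for code, name in props])
            buf = fh.read(dtype.itemsize * n_vertex)
            if len(buf) != dtype.itemsize * n_vertex:
                raise CloudParseError(f"{path}: truncated vertex data")
            rec = np.frombuffer(buf, dtype=dtype)
            data = {name: rec[name] for _, name in props}
        else:
            raise CloudParseError(f"{path}: unsupported format {fmt}")
    coords = np.column_stack([data["x"], data["y"], data["z"]]).astype(np.float64)
    return LabeledCloud(
        coords=coords,
        semantic_labels=data["label"].astype(np.int64) if "label" in data else None,
        instance_ids=data["instance"].astype(np.int64) if "instance" in data else None,
    )


def _write_ply(cloud: LabeledCloud, path: Path, binary: bool = True) -> None:
    n = len(cloud)
    has_label = cloud.semantic_labels is not None
    has_inst = cloud.instance_ids is not None
    header = ["ply"]
    header.append(
        "format binary_little_endian 1.0" if binary else "format ascii 1.0"
    )
    header.append(f"element vertex {n}")
    header += ["property float x", "property float y", "property float z"]
    if has_label:
        header.append("property int label")
    if has_inst:
        header.append("property int instance")
    header.append("end_header")
    coords32 = cloud.coords.astype(np.float32)
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            fields = [("x", "<f4"), ("y", "<f4"), ("z", "<f4")]
            if has_label:
                fields.append(("label", "<i4"))
            if has_inst:
                fields.append(("instance", "<i4"))
            rec = np.empty(n, dtype=np.dtype(fields))
            rec["x"], rec["y"], rec["z"] = coords32[:, 0], coords32[:, 1], coords32[:, 2]
            if has_label:
                rec["label"] = cloud.semantic_labels
            if has_inst:
                rec["instance"] = cloud.instance_ids
            fh.write(rec.tobytes())
        else:
            for i in range(n):
                row = [repr(float(v)) for v in coords32[i]]
                if has_label:
                    row.append(str(int(cloud.semantic_labels[i])))
                if has_inst:
                    row.append(str(int(cloud.instance_ids[i])))
                fh.write((" ".join(row) + "\n").encode("ascii"))
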