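"""Minimal NRRD volume I/O (raw and ascii encodings).

Covers the subset of NRRD this package emits: 3D float32 grids with axis-
aligned ``space directions`` and a ``space origin``.  Data are stored with
the first axis fastest (NRRD convention), i.e. Fortran order for our
``(nx, ny, nz)`` arrays.
"""

from __future__ import annotations

import os

import numpy as np

from .errors import FormatError, MetadataError
from .grids import DoseGrid, Grid3D

__all__ = ["read_volume", "write_volume", "write_fluence_csv", "read_fluence_csv"]

_TYPES = {
    "float": np.float32,
    "float32": np.float32,
    "double": np.float64,
    "float64": np.float64,
    "short": np.int16,
    "unsigned short": np.uint16,
    "int": np.int32,
    "uint": np.uint32,
}


def write_volume(path: str, grid: Grid3D, encoding: str = "raw") -> None:
    """Write a 3D grid as NRRD (float32)."""
    if encoding not in ("raw", "ascii"):
        raise FormatError(f"unsupported encoding {encoding!r}")
    nx, ny, nz = grid.values.shape
    sx, sy, sz = grid.spacing_cm
    ox, oy, oz = grid.origin_cm
    header = [
        "NRRD0004",
        "# epidose volume",
        "type: float",
        "dimension: 3",
        "space dimension: 3",
        f"sizes: {nx} {ny} {nz}",
        f"space directions: ({sx},0,0) (0,{sy},0) (0,0,{sz})",
        f"space origin: ({ox},{oy},{oz})",
        f"encoding: {encoding}",
    ]
    if encoding == "raw":
        header.append("endian: little")
    data = np.asarray(grid.values, dtype="<f4").ravel(order="F")
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n\n").encode())
        if encoding == "raw":
            fh.write(data.tobytes())
        else:
            np.savetxt(fh, data[None, :], fmt="%.9g")


def _parse_vector(text: str) -> tuple:
    return tuple(float(v) for v in text.strip().lstrip("(").rstrip(")").split(","))


def read_volume(path: str, grid_cls=DoseGrid) -> Grid3D:
    """Read an NRRD volume into ``grid_cls`` (values float32 -> float64).

    Raises :class:`FormatError` for non-NRRD input and
    :class:`MetadataError` when spacing or origin is missing.
    """
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    with open(path, "rb") as fh:
        magic = fh.readline().decode("ascii", "replace").strip()
        if not magic.startswith("NRRD"):
            raise FormatError(f"{path}: not an NRRD file")
        fields = {}
        while True:
            line = fh.readline()
            if line in (b"\n", b"\r\n", b""):
                break
            text = line.decode("ascii", "replace").strip()
            if text.startswith("#") or ":" not in text:
                continue
            key, val = text.split(":", 1)
            fields[key.strip().lower()] = val.strip()
        payload = fh.read()

    if "sizes" not in fields or "dimension" not in fields:
        raise MetadataError(f"{path}: missing sizes/dimension")
    if int(fields["dimension"]) != 3:
        raise FormatError(f"{path}: only 3D volumes supported")
    sizes = tuple(int(v) for v in fields["sizes"].split())
    dtype = _TYPES.get(fields.get("type", ""), None)
    if dtype is None:
        raise FormatError(f"{path}: unsupported type {fields.get('type')!r}")

    if "space directions" not in fields:
        raise MetadataError(f"{path}: missing 'space directions' (voxel spacing)")
    dirs = [
        _parse_vector(v) for v in fields["space directions"].replace(") (", ")|(").split("|")
    ]
    spacing = []
    for a, d in enumerate(dirs):
        off_axis = [d[i] for i in range(3) if i != a]
        if any(abs(v) > 1e-12 for v in off_axis):
            raise FormatError(f"{path}: oblique space directions unsupported")
        spacing.append(d[a])
    if "space origin" not in fields:
        raise MetadataError(f"{path}: missing 'space origin'")
    origin = _parse_vector(fields["space origin"])

    encoding = fields.get("encoding", "raw")
    if encoding == "raw":
        endian = fields.get("endian", "little")
        dt = np.dtype(dtype).newbyteorder("<" if endian == "little" else ">")
        data = np.frombuffer(payload, dtype=dt, count=int(np.prod(sizes)))
    elif encoding in ("ascii", "text", "txt"):
        data = np.array(payload.split(), dtype=float)
    else:
        raise FormatError(f"{path}: unsupported encoding {encoding!r}")
    values = np.asarray(data, dtype=float).reshape(sizes, order="F")
    return grid_cls(values, np.asarray(spacing, float), np.asarray(origin, float))


def write_fluence_csv(path: str, fluence) -> None:
    """CSV dump of a fluence map with a spacing/origin comment header."""
    with open(path, "w") as fh:
        fh.write(
            f"# spacing_cm={fluence.spacing_cm}, origin_cm={fluence.origin_cm}, "
            f"plane_distance_cm={fluence.plane_distance_cm}\n"
        )
        np.savetxt(fh, fluence.values, delimiter=",", fmt="%.9g")


def read_fluence_csv(path: str):
    """Read a fluence map written by :func:`write_fluence_csv`."""
    from .grids import FluenceMap

    with open(path) as fh:
        head = fh.readline()
        if not head.startswith("#"):
            raise MetadataError(f"{path}: missing fluence metadata header")
    import re

    m_sp = re.search(r"spacing_cm=([0-9.eE+-]+)", head)
    m_or = re.search(r"origin_cm=\(([^)]*)\)", head)
    m_pd = re.search(r"plane_distance_cm=([0-9.eE+-]+)", head)
    if not (m_sp and m_or and m_pd):
        raise MetadataError(f"{path}: malformed fluence metadata header")
    values = np.loadtxt(path, delimiter=",", comments="#")
    origin = tuple(float(v) for v in m_or.group(1).split(","))
    return FluenceMap(
        values=values,
        spacing_cm=float(m_sp.group(1)),
        origin_cm=origin,
        plane_distance_cm=float(m_pd.group(1)),
    )
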