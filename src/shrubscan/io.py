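"""Reading and writing point clouds and the tabular field inputs.

Two point-cloud formats are supported:

``xyz``
    Delimited text (comma or tab, ``.`` decimal separator) with a mandatory
    header row naming at least ``x,y,z,echo_index,num_echoes``. Derived
    attributes round-trip through the optional columns ``norm_z``, ``layer``,
    ``class_id`` and ``max_prob``.
``las``
    LAS 1.2 point format 0 with derived attributes as appended extra bytes
    (see :mod:`shrubscan.las`).

The tabular inputs emulate the field protocol: a reference table of
RTK-GNSS-surveyed objects (position, class label, size-specific gathering
radius) and a harvest table of oven-dried shrubs, each with a small manual
delineation point cloud (nominally 25 GNSS fixes) stored one file per shrub
in a companion directory as ``shrub_<id>.txt`` with columns ``x,y,z``.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from . import las as _las
from .pointcloud import (HarvestRecord, Layer, PointCloud, ReferenceRecord)

__all__ = [
    "read_point_cloud",
    "write_point_cloud",
    "read_reference_table",
    "read_harvest_table",
]

_REQUIRED = ("x", "y", "z", "echo_index", "num_echoes")
_OPTIONAL = ("norm_z", "layer", "class_id", "max_prob")


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def _read_xyz(path: Path) -> PointCloud:
    with open(path, "r", newline="") as fh:
        first = fh.readline()
        if not first.strip():
            raise ValueError(f"{path}: empty file")
        delim = _sniff_delimiter(first)
        header = [c.strip().lower() for c in first.strip().split(delim)]
        missing = [c for c in _REQUIRED if c not in header]
        if missing:
            raise ValueError(
                f"{path}: header is missing required column(s) "
                f"{', '.join(missing)} (found: {', '.join(header)})")
        try:
            df = pd.read_csv(fh, sep=delim, names=header, header=None,
                             dtype=np.float64)
        except ValueError as exc:
            raise ValueError(f"{path}: non-numeric value in data rows "
                             f"({exc})") from exc
    bad = df[list(_REQUIRED)].isna().any(axis=1)
    if bad.any():
        # +2: header line plus 1-based numbering
        line = int(bad.idxmax()) + 2
        raise ValueError(f"{path}: line {line}: missing or non-numeric "
                         "coordinate/echo value")
    kwargs = {}
    if "norm_z" in df:
        kwargs["norm_z"] = df["norm_z"].to_numpy()
    if "layer" in df:
        kwargs["layer"] = df["layer"].to_numpy().astype(np.uint8)
    if "class_id" in df:
        kwargs["class_id"] = df["class_id"].fillna(-1).to_numpy().astype(np.int32)
    try:
        cloud = PointCloud(
            df["x"].to_numpy(), df["y"].to_numpy(), df["z"].to_numpy(),
            df["echo_index"].to_numpy().astype(np.int32),
            df["num_echoes"].to_numpy().astype(np.int32),
            **kwargs)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc
    if "max_prob" in df:
        cloud.max_class_prob = df["max_prob"].to_numpy()
    return cloud


def read_point_cloud(path: str | Path, fmt: str | None = None) -> PointCloud:
    """Read a point cloud, inferring the format from the suffix if ``fmt``
    is not given (``.las`` → LAS, anything else → delimited text)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "las" if path.suffix.lower() == ".las" else "xyz"
    if fmt == "las":
        return _las.read_las(path)
    if fmt == "xyz":
        return _read_xyz(path)
    raise ValueError(f"unknown point cloud format {fmt!r}")


def write_point_cloud(cloud: PointCloud, path: str | Path,
                      fmt: str | None = None) -> None:
    """Write a cloud; derived attributes are persisted (extra columns for
    ``xyz``, extra bytes for ``las``) so classified clouds round-trip."""
    if len(cloud) == 0:
        raise ValueError("refusing to write an empty point cloud")
    path = Path(path)
    if fmt is None:
        fmt = "las" if path.suffix.lower() == ".las" else "xyz"
    if fmt == "las":
        _las.write_las(cloud, path)
        return
    if fmt != "xyz":
        raise ValueError(f"unknown point cloud format {fmt!r}")
    cols = {
        "x": cloud.x, "y": cloud.y, "z": cloud.z,
        "echo_index": cloud.echo_index, "num_echoes": cloud.num_echoes,
    }
    has_derived = (np.any(np.isfinite(cloud.norm_z))
                   or np.any(cloud.layer != Layer.UNSET)
                   or np.any(cloud.class_id >= 0)
                   or cloud.class_probs is not None)
    if has_derived:
        cols["norm_z"] = cloud.norm_z
        cols["layer"] = cloud.layer
        cols["class_id"] = cloud.class_id
        if cloud.class_probs is not None:
            cols["max_prob"] = np.round(cloud.class_probs.max(axis=1), 6)
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.6f")


def read_reference_table(
    path: str | Path,
    schema: tuple[str, ...] | None = None,
) -> tuple[list[ReferenceRecord], tuple[str, ...]]:
    """Read the reference table (``ref_id,x,y,z,class,object_radius``).

    When ``schema`` is None the class vocabulary is frozen from the table in
    order of first appearance; otherwise labels are validated against the
    given schema and an unknown label is a hard error listing the allowed
    classes. Returns ``(records, schema)``.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        first = fh.readline()
        delim = _sniff_delimiter(first)
        fh.seek(0)
        reader = csv.DictReader(fh, delimiter=delim)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file")
        fields = {f.strip().lower() for f in reader.fieldnames}
        needed = {"ref_id", "x", "y", "z", "class", "object_radius"}
        if not needed <= fields:
            raise ValueError(f"{path}: header must contain "
                             f"{sorted(needed)}, found {sorted(fields)}")
        rows = [{k.strip().lower(): v for k, v in row.items()}
                for row in reader]
    if schema is None:
        seen: list[str] = []
        for row in rows:
            lab = row["class"].strip()
            if lab not in seen:
                seen.append(lab)
        schema = tuple(seen)
    index = {name: i for i, name in enumerate(schema)}
    records = []
    for row in rows:
        lab = row["class"].strip()
        if lab not in index:
            raise ValueError(
                f"{path}: unknown class label {lab!r}; allowed classes: "
                f"{', '.join(schema)}")
        records.append(ReferenceRecord(
            ref_id=int(row["ref_id"]),
            x=float(row["x"]), y=float(row["y"]), z=float(row["z"]),
            class_id=index[lab],
            object_radius=float(row["object_radius"]),
        ))
    return records, schema


def read_harvest_table(path: str | Path,
                       delineation_dir: str | Path) -> list[HarvestRecord]:
    """Read the harvest table (``shrub_id,dry_mass``) plus per-shrub
    delineation clouds ``<delineation_dir>/shrub_<id>.txt`` (columns x,y,z)."""
    path = Path(path)
    ddir = Path(delineation_dir)
    with open(path, newline="") as fh:
        first = fh.readline()
        delim = _sniff_delimiter(first)
        fh.seek(0)
        reader = csv.DictReader(fh, delimiter=delim)
        rows = [{k.strip().lower(): v for k, v in row.items()}
                for row in reader]
    if not rows:
        raise ValueError(f"{path}: no harvest records")
    records = []
    for row in rows:
        sid = int(row["shrub_id"])
        dfile = ddir / f"shrub_{sid}.txt"
        if not dfile.exists():
            raise FileNotFoundError(
                f"delineation cloud {dfile} for shrub {sid} not found")
        tbl = pd.read_csv(dfile, sep=None, engine="python")
        tbl.columns = [c.strip().lower() for c in tbl.columns]
        pts = tbl[["x", "y", "z"]].to_numpy(dtype=np.float64)
        records.append(HarvestRecord(
            shrub_id=sid, dry_mass=float(row["dry_mass"]),
            delineation_points=pts))
    return records


def write_reference_table(records: list[ReferenceRecord],
                          schema: tuple[str, ...], path: str | Path) -> None:
    rows = [
        {"ref_id": r.ref_id, "x": r.x, "y": r.y, "z": r.z,
         "class": schema[r.class_id], "object_radius": r.object_radius}
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_harvest_tables(records: list[HarvestRecord], path: str | Path,
                         delineation_dir: str | Path) -> None:
    ddir = Path(delineation_dir)
    ddir.mkdir(parents=True, exist_ok=True)
    rows = [{"shrub_id": r.shrub_id, "dry_mass": r.dry_mass} for r in records]
    pd.DataFrame(rows).to_csv(path, index=False)
    for r in records:
        pd.DataFrame(r.delineation_points, columns=["x", "y", "z"]).to_csv(
            ddir / f"shrub_{r.shrub_id}.txt", index=False)
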