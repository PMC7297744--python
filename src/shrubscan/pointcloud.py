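"""Core data model for multi-echo LiDAR point clouds.

A :class:`PointCloud` is a column-oriented container (numpy arrays) for the
returns of a dual-return scanner: planar-projected coordinates in metres,
the echo index of each return within its pulse, the total number of echoes
of the pulse, and the attributes derived downstream — height above terrain
(``norm_z``), the coarse height layer, and the fuzzy class assignment.

Coordinates are assumed planar metric (a projected grid); the CRS is carried
as an opaque tag only. All neighbourhood radii in this package are metric.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

__all__ = [
    "Layer",
    "PointRecord",
    "PointCloud",
    "ReferenceRecord",
    "HarvestRecord",
    "DEFAULT_SCHEMA",
]

#: The default 13-class reference schema: 11 shrub/tree taxa that reach the
#: shrub layer, fenceposts (vertical-accuracy control objects that survive
#: height thresholding), and shrub-absence points.
DEFAULT_SCHEMA: tuple[str, ...] = (
    "Cytisus",
    "Juniperus",
    "Rubus",
    "Rosa",
    "Quercus",
    "Betula",
    "Pinus",
    "Sambucus",
    "Crataegus",
    "Prunus",
    "Malus",
    "fencepost",
    "absence",
)


class Layer(enum.IntEnum):
    """Coarse height strata of the normalized point cloud.

    ``GROUND``/``LOW_VEG``/``HIGH_VEG`` are set aside; ``SHRUB_LAYER``
    (0.3 m ≤ NormZ ≤ 3.5 m by default) is the stratum classified into taxa.
    ``NOISE`` marks returns further than 5 cm below the terrain model.
    """

    UNSET = 0
    GROUND = 1
    LOW_VEG = 2
    SHRUB_LAYER = 3
    HIGH_VEG = 4
    NOISE = 5


class PointRecord(NamedTuple):
    """One LiDAR return (a row view of a :class:`PointCloud`)."""

    x: float
    y: float
    z: float
    echo_index: int
    num_echoes: int
    norm_z: float  # nan when unset
    layer: Layer
    class_id: int  # -1 when unset
    class_probs: np.ndarray | None


@dataclass
class PointCloud:
    """Column store of LiDAR returns.

    Parameters
    ----------
    x, y, z
        Coordinates in metres (planar projected CRS).
    echo_index
        1-based return number of each echo within its pulse.
    num_echoes
        Total returns of the pulse the echo belongs to.
    norm_z
        Height above the terrain model; ``nan`` until computed.
    layer
        :class:`Layer` codes, ``Layer.UNSET`` until assigned.
    class_id
        Index into ``schema``; ``-1`` until classified.
    class_probs
        Optional ``(n, k)`` fuzzy class-membership matrix (rows sum to 1).
    schema
        Ordered class names matching the columns of ``class_probs``.
    crs_tag
        Free-text CRS identifier (opaque; no transformations).
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    echo_index: np.ndarray
    num_echoes: np.ndarray
    norm_z: np.ndarray = None  # type: ignore[assignment]
    layer: np.ndarray = None  # type: ignore[assignment]
    class_id: np.ndarray = None  # type: ignore[assignment]
    class_probs: np.ndarray | None = None
    schema: tuple[str, ...] | None = None
    crs_tag: str = ""

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        self.z = np.asarray(self.z, dtype=np.float64)
        self.echo_index = np.asarray(self.echo_index, dtype=np.int32)
        self.num_echoes = np.asarray(self.num_echoes, dtype=np.int32)
        n = self.x.size
        for name in ("y", "z", "echo_index", "num_echoes"):
            if getattr(self, name).size != n:
                raise ValueError(f"column {name!r} has length "
                                 f"{getattr(self, name).size}, expected {n}")
        if self.norm_z is None:
            self.norm_z = np.full(n, np.nan)
        else:
            self.norm_z = np.asarray(self.norm_z, dtype=np.float64)
        if self.layer is None:
            self.layer = np.full(n, Layer.UNSET, dtype=np.uint8)
        else:
            self.layer = np.asarray(self.layer, dtype=np.uint8)
        if self.class_id is None:
            self.class_id = np.full(n, -1, dtype=np.int32)
        else:
            self.class_id = np.asarray(self.class_id, dtype=np.int32)
        self._validate_echoes()
        if self.class_probs is not None:
            self._validate_probs()

    def _validate_echoes(self) -> None:
        if np.any(self.echo_index < 1) or np.any(self.num_echoes < 1):
            bad = int(np.flatnonzero((self.echo_index < 1)
                                     | (self.num_echoes < 1))[0])
            raise ValueError(
                f"record {bad}: echo_index and num_echoes must be >= 1")
        viol = self.echo_index > self.num_echoes
        if np.any(viol):
            bad = int(np.flatnonzero(viol)[0])
            raise ValueError(
                f"record {bad}: echo_index "
                f"({int(self.echo_index[bad])}) exceeds num_echoes "
                f"({int(self.num_echoes[bad])})")

    def _validate_probs(self) -> None:
        p = np.asarray(self.class_probs, dtype=np.float64)
        if p.ndim != 2 or p.shape[0] != len(self):
            raise ValueError("class_probs must be an (n_points, n_classes) matrix")
        if self.schema is not None and p.shape[1] != len(self.schema):
            raise ValueError("class_probs column count does not match schema")
        if np.any(p < -1e-9) or np.any(p > 1 + 1e-9):
            raise ValueError("class probabilities must lie in [0, 1]")
        sums = p.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError("class probability rows must sum to 1")
        self.class_probs = p

    def __len__(self) -> int:
        return int(self.x.size)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) enclosing all points."""
        if len(self) == 0:
            raise ValueError("empty cloud has no bounds")
        return (float(self.x.min()), float(self.y.min()),
                float(self.x.max()), float(self.y.max()))

    @property
    def xyz(self) -> np.ndarray:
        return np.column_stack([self.x, self.y, self.z])

    def record(self, i: int) -> PointRecord:
        """Materialize row ``i`` as a :class:`PointRecord`."""
        probs = None if self.class_probs is None else self.class_probs[i]
        return PointRecord(
            float(self.x[i]), float(self.y[i]), float(self.z[i]),
            int(self.echo_index[i]), int(self.num_echoes[i]),
            float(self.norm_z[i]), Layer(int(self.layer[i])),
            int(self.class_id[i]), probs,
        )

    def select(self, mask_or_idx) -> "PointCloud":
        """Row subset preserving all columns and metadata."""
        idx = np.asarray(mask_or_idx)
        probs = None if self.class_probs is None else self.class_probs[idx]
        return PointCloud(
            self.x[idx], self.y[idx], self.z[idx],
            self.echo_index[idx], self.num_echoes[idx],
            norm_z=self.norm_z[idx], layer=self.layer[idx],
            class_id=self.class_id[idx], class_probs=probs,
            schema=self.schema, crs_tag=self.crs_tag,
        )

    def copy(self) -> "PointCloud":
        return self.select(np.arange(len(self)))


@dataclass(frozen=True)
class ReferenceRecord:
    """One field-surveyed reference object (RTK-GNSS position + label).

    ``object_radius`` is the size-specific gathering radius within which
    shrub-layer returns are attributed to this object's class.
    """

    ref_id: int
    x: float
    y: float
    z: float
    class_id: int
    object_radius: float

    def __post_init__(self) -> None:
        if self.object_radius <= 0:
            raise ValueError(f"reference {self.ref_id}: object_radius must be > 0")


@dataclass(frozen=True)
class HarvestRecord:
    """One harvested shrub: oven-dry mass plus its manual delineation cloud.

    The delineation points (nominally 25 GNSS fixes around the canopy) delimit
    the shrub's footprint for volume extraction; at least 3 are required for a
    planar footprint.
    """

    shrub_id: int
    dry_mass: float  # grams
    delineation_points: np.ndarray = field(repr=False)  # (m, 3)

    def __post_init__(self) -> None:
        pts = np.asarray(self.delineation_points, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError(
                f"shrub {self.shrub_id}: delineation points must be (m, 3)")
        if pts.shape[0] < 3:
            raise ValueError(
                f"shrub {self.shrub_id}: at least 3 delineation points are "
                f"required for a planar footprint (got {pts.shape[0]})")
        if self.dry_mass < 0:
            raise ValueError(f"shrub {self.shrub_id}: dry_mass must be >= 0")
        object.__setattr__(self, "delineation_points", pts)


def concat(clouds: Sequence[PointCloud]) -> PointCloud:
    """Concatenate clouds that share a schema (class_probs dropped if mixed)."""
    if not clouds:
        raise ValueError("nothing to concatenate")
    schema = clouds[0].schema
    probs = None
    if all(c.class_probs is not None for c in clouds):
        probs = np.vstack([c.class_probs for c in clouds])
    return PointCloud(
        np.concatenate([c.x for c in clouds]),
        np.concatenate([c.y for c in clouds]),
        np.concatenate([c.z for c in clouds]),
        np.concatenate([c.echo_index for c in clouds]),
        np.concatenate([c.num_echoes for c in clouds]),
        norm_z=np.concatenate([c.norm_z for c in clouds]),
        layer=np.concatenate([c.layer for c in clouds]),
        class_id=np.concatenate([c.class_id for c in clouds]),
        class_probs=probs,
        schema=schema,
        crs_tag=clouds[0].crs_tag,
    )
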