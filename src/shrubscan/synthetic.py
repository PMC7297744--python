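"""Synthetic grassland scenes with known structure, volume and biomass.

The generator emulates — at desk scale — the acquisition that the pipeline
is built for: a gently undulating terrain, a grass layer, and parametric
shrub/tree archetypes that differ in the properties the structural
features respond to (point density, surface roughness, canopy shape and
light penetration). A dual-return scan is simulated geometrically:
vertical pulses on a jittered grid return the first surface hit, and a
pulse through a canopy yields a second, ground echo with the archetype's
penetration probability (both echoes of such a pulse carry
``num_echoes = 2``). Canopy interiors are additionally filled with
volumetric returns at the archetype's point density, emulating the
multi-angle sampling of a real flight.

Every return carries its true class, and each placed shrub's analytic
canopy volume feeds a linear allometry (``mass = a + b * volume`` plus
Gaussian noise, truncated at zero), so classification accuracy, biomass
model recovery and change detection can all be scored against ground
truth. All randomness flows from the scene seed through counter-based
per-shrub streams: adding a shrub never perturbs another shrub's points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .pointcloud import HarvestRecord, PointCloud, ReferenceRecord

__all__ = [
    "ShrubArchetype", "Placement", "SceneSpec", "Scene", "generate_scene",
    "make_reference_table", "make_harvest_table", "default_archetypes",
    "scatter_placements", "remove_shrub", "remove_last_shrubs",
]

CANOPY_SHAPES = ("ellipsoid", "hemisphere", "cone", "overhang")


@dataclass(frozen=True)
class ShrubArchetype:
    """A parametric shrub/tree growth form.

    ``penetration_prob`` is the chance a canopy pulse also records a ground
    echo (light penetration); ``echo2_prob`` the chance a canopy return is
    part of a dual-echo pulse for other reasons (internal structure).
    Radii and heights are in metres; density in returns per m^3 of canopy.
    """

    name: str
    canopy: str
    radius_range: tuple[float, float]
    height_range: tuple[float, float]
    point_density: float
    roughness_sigma: float
    penetration_prob: float
    echo2_prob: float

    def __post_init__(self) -> None:
        if self.canopy not in CANOPY_SHAPES:
            raise ValueError(f"unknown canopy shape {self.canopy!r}")
        for p in (self.penetration_prob, self.echo2_prob):
            if not (0 <= p <= 1):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.point_density <= 0:
            raise ValueError("point_density must be positive")


def default_archetypes() -> dict[str, ShrubArchetype]:
    """Three contrasting growth forms spanning the feature space.

    ``broom``: dense erect ellipsoid with moderate penetration (a
    broom-like shrub); ``conifer``: compact smooth hemisphere with almost
    no penetration (juniper-like); ``tree_overhang``: sparser elevated
    canopy with clear trunk space and high penetration (low tree with an
    overhanging crown).
    """
    return {
        "broom": ShrubArchetype(
            "broom", "ellipsoid", (0.5, 0.9), (1.0, 2.0),
            point_density=350.0, roughness_sigma=0.08,
            penetration_prob=0.3, echo2_prob=0.6),
        "conifer": ShrubArchetype(
            "conifer", "hemisphere", (0.6, 1.0), (0.8, 1.4),
            point_density=900.0, roughness_sigma=0.02,
            penetration_prob=0.05, echo2_prob=0.05),
        "tree_overhang": ShrubArchetype(
            "tree_overhang", "overhang", (0.8, 1.2), (2.4, 3.3),
            point_density=80.0, roughness_sigma=0.18,
            penetration_prob=0.5, echo2_prob=0.0),
    }


@dataclass(frozen=True)
class Placement:
    archetype: ShrubArchetype
    center: tuple[float, float]
    scale: float = 1.0


@dataclass(frozen=True)
class SceneSpec:
    """Parametric description of a synthetic scene (fully reproducible:
    the same spec always generates bit-identical output)."""

    extent: tuple[float, float] = (20.0, 20.0)
    terrain_amplitude: float = 0.4
    terrain_corr_length: float = 10.0
    grass_height: tuple[float, float] = (0.02, 0.25)
    placements: tuple[Placement, ...] = ()
    allometry: tuple[float, float, float] = (80.0, 4700.0, 50.0)  # a, b, sigma
    pulse_spacing: float = 0.07
    bare_ground_prob: float = 0.4
    seed: int = 0


@dataclass
class _Shrub:
    """A realized shrub: archetype with concrete dimensions."""

    shrub_id: int
    archetype: ShrubArchetype
    cx: float
    cy: float
    radius: float
    height: float

    @property
    def volume(self) -> float:
        r, h = self.radius, self.height
        if self.archetype.canopy == "ellipsoid":
            return 4.0 / 3.0 * math.pi * r * r * (h / 2.0)
        if self.archetype.canopy == "hemisphere":
            return 2.0 / 3.0 * math.pi * r * r * h
        if self.archetype.canopy == "cone":
            return math.pi * r * r * h / 3.0
        # overhang: ellipsoidal crown occupying the upper 60% of the height
        return 4.0 / 3.0 * math.pi * r * r * (0.3 * h)

    def crown_band(self) -> tuple[float, float]:
        """Vertical span of the canopy above local ground."""
        if self.archetype.canopy == "overhang":
            return 0.4 * self.height, self.height
        return 0.0, self.height

    def top_at(self, dx: np.ndarray, dy: np.ndarray) -> np.ndarray:
        """Canopy top height above local ground at planar offsets; nan
        outside the footprint."""
        d2 = (dx ** 2 + dy ** 2) / self.radius ** 2
        inside = d2 < 1.0
        out = np.full(np.shape(d2), np.nan)
        lo, hi = self.crown_band()
        mid = (lo + hi) / 2.0
        half = (hi - lo) / 2.0
        shape = self.archetype.canopy
        if shape == "cone":
            out = np.where(inside, hi * (1.0 - np.sqrt(np.maximum(d2, 0))),
                           np.nan)
        elif shape == "hemisphere":
            out = np.where(inside, hi * np.sqrt(np.maximum(1.0 - d2, 0)),
                           np.nan)
        else:  # ellipsoid / overhang
            out = np.where(inside,
                           mid + half * np.sqrt(np.maximum(1.0 - d2, 0)),
                           np.nan)
        return out

    def contains(self, px: np.ndarray, py: np.ndarray, pz_rel: np.ndarray,
                 ) -> np.ndarray:
        """Membership of points (heights relative to local ground) in the
        canopy solid."""
        dx = (px - self.cx) / self.radius
        dy = (py - self.cy) / self.radius
        lo, hi = self.crown_band()
        mid = (lo + hi) / 2.0
        half = (hi - lo) / 2.0
        shape = self.archetype.canopy
        if shape == "cone":
            frac = np.clip(pz_rel / hi, 0, 1)
            return (pz_rel >= 0) & (pz_rel <= hi) & (
                dx ** 2 + dy ** 2 <= (1 - frac) ** 2)
        return dx ** 2 + dy ** 2 + ((pz_rel - mid) / half) ** 2 <= 1.0


@dataclass
class Scene:
    """A generated scene: labelled cloud, per-point truth, shrub table."""

    cloud: PointCloud
    true_class: np.ndarray  # index into truth_schema per point
    truth_schema: tuple[str, ...]
    shrubs: pd.DataFrame  # shrub_id, archetype, cx, cy, radius, height,
    #                       volume_m3, biomass_g
    spec: SceneSpec

    def terrain_z(self, x, y) -> np.ndarray:
        return _terrain(self.spec, np.asarray(x, dtype=float),
                        np.asarray(y, dtype=float))


def _terrain(spec: SceneSpec, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Smooth deterministic terrain: two crossed sinusoids whose phases are
    derived from the scene seed."""
    rng = np.random.default_rng([spec.seed, 7])
    p1, p2, p3 = rng.uniform(0, 2 * math.pi, 3)
    L = spec.terrain_corr_length
    return 40.0 + spec.terrain_amplitude * (
        np.sin(2 * math.pi * x / L + p1) * 0.6
        + np.sin(2 * math.pi * y / L + p2) * 0.6
        + np.sin(2 * math.pi * (x + y) / (1.7 * L) + p3) * 0.3)


def _realize_shrubs(spec: SceneSpec) -> list[_Shrub]:
    shrubs = []
    W, H = spec.extent
    for i, pl in enumerate(spec.placements):
        rng = np.random.default_rng([spec.seed, 1000 + i])
        a = pl.archetype
        radius = rng.uniform(*a.radius_range) * pl.scale
        height = rng.uniform(*a.height_range) * pl.scale
        cx, cy = pl.center
        if not (radius <= cx <= W - radius and radius <= cy <= H - radius):
            raise ValueError(
                f"shrub {i} ({a.name}) at ({cx}, {cy}) with radius "
                f"{radius:.2f} m extends outside the {W} x {H} m extent")
        shrubs.append(_Shrub(i, a, cx, cy, radius, height))
    return shrubs


def generate_scene(spec: SceneSpec) -> Scene:
    """Simulate the scene described by ``spec``.

    Returns the labelled point cloud (echo attributes set; derived fields
    unset, exactly as a raw scan) plus the per-shrub truth table with
    analytic canopy volumes and allometric biomass.
    """
    shrubs = _realize_shrubs(spec)
    W, H = spec.extent
    s = spec.pulse_spacing

    # pulse grid with jitter; the stream is independent of the shrub list
    rng_pulse = np.random.default_rng([spec.seed, 0])
    ix = np.arange(int(W / s))
    iy = np.arange(int(H / s))
    gx, gy = np.meshgrid(ix, iy, indexing="ij")
    px = (gx.ravel() + rng_pulse.uniform(0, 1, gx.size)) * s
    py = (gy.ravel() + rng_pulse.uniform(0, 1, gy.size)) * s
    ground_z = _terrain(spec, px, py)

    # first canopy hit per pulse: shrubs are disjoint in practice; the
    # highest canopy top wins where footprints do overlap
    top = np.full(px.size, -np.inf)
    owner = np.full(px.size, -1, dtype=np.int64)
    for sh in shrubs:
        t = sh.top_at(px - sh.cx, py - sh.cy)
        better = np.isfinite(t) & (t > top)
        top[better] = t[better]
        owner[better] = sh.shrub_id

    xs, ys, zs, e_idx, n_ech, labels = [], [], [], [], [], []
    truth_schema = tuple(dict.fromkeys(sh.archetype.name for sh in shrubs))
    schema_full = truth_schema + ("grass", "ground")
    lab_index = {n: i for i, n in enumerate(schema_full)}

    # open-land pulses: bare ground or grass, single return. Draws are made
    # for EVERY pulse and subset afterwards so that a pulse's grass fate is
    # independent of which pulses the shrub canopies absorb — adding or
    # removing a shrub never re-keys the remaining grass.
    rng_grass = np.random.default_rng([spec.seed, 1])
    open_mask = owner < 0
    bare_all = rng_grass.uniform(0, 1, px.size) < spec.bare_ground_prob
    gh_all = rng_grass.uniform(*spec.grass_height, px.size)
    gz_all = rng_grass.normal(0, 0.005, px.size)
    n_open = int(open_mask.sum())
    bare = bare_all[open_mask]
    oz = np.where(bare, ground_z[open_mask] + gz_all[open_mask],
                  ground_z[open_mask] + gh_all[open_mask])
    xs.append(px[open_mask])
    ys.append(py[open_mask])
    zs.append(oz)
    e_idx.append(np.ones(n_open, dtype=np.int64))
    n_ech.append(np.ones(n_open, dtype=np.int64))
    lab = np.where(bare, lab_index["ground"], lab_index["grass"])
    labels.append(lab)

    rows = []
    for sh in shrubs:
        rng = np.random.default_rng([spec.seed, 2000 + sh.shrub_id])
        a = sh.archetype
        sel = owner == sh.shrub_id
        n_hit = int(sel.sum())
        # canopy surface returns from the pulse pass
        cz = (ground_z[sel] + top[sel]
              + rng.normal(0, a.roughness_sigma, n_hit))
        u = rng.uniform(0, 1, n_hit)
        penetrated = u < a.penetration_prob
        dual = penetrated | (u < a.penetration_prob + (
            1 - a.penetration_prob) * a.echo2_prob)
        xs.append(px[sel])
        ys.append(py[sel])
        zs.append(cz)
        e_idx.append(np.ones(n_hit, dtype=np.int64))
        n_ech.append(np.where(dual, 2, 1))
        labels.append(np.full(n_hit, lab_index[a.name]))
        # second echoes of penetrating pulses reach the ground
        n_pen = int(penetrated.sum())
        if n_pen:
            xs.append(px[sel][penetrated])
            ys.append(py[sel][penetrated])
            zs.append(ground_z[sel][penetrated]
                      + rng.normal(0, 0.01, n_pen))
            e_idx.append(np.full(n_pen, 2, dtype=np.int64))
            n_ech.append(np.full(n_pen, 2, dtype=np.int64))
            labels.append(np.full(n_pen, lab_index["ground"]))
        # volumetric canopy returns at the archetype density
        n_vol = int(round(a.point_density * sh.volume))
        if n_vol:
            pts = np.empty((0, 3))
            lo, hi = sh.crown_band()
            while pts.shape[0] < n_vol:
                cand = rng.uniform(
                    [-sh.radius, -sh.radius, lo], [sh.radius, sh.radius, hi],
                    (max(64, 2 * n_vol), 3))
                ok = sh.contains(cand[:, 0] + sh.cx, cand[:, 1] + sh.cy,
                                 cand[:, 2])
                pts = np.vstack([pts, cand[ok]])
            pts = pts[:n_vol]
            vx = pts[:, 0] + sh.cx
            vy = pts[:, 1] + sh.cy
            vz = (_terrain(spec, vx, vy) + pts[:, 2]
                  + rng.normal(0, a.roughness_sigma / 2, n_vol))
            xs.append(vx)
            ys.append(vy)
            zs.append(vz)
            e_idx.append(np.ones(n_vol, dtype=np.int64))
            dual_v = rng.uniform(0, 1, n_vol) < (
                a.penetration_prob + (1 - a.penetration_prob) * a.echo2_prob)
            n_ech.append(np.where(dual_v, 2, 1))
            labels.append(np.full(n_vol, lab_index[a.name]))
        biomass = spec.allometry[0] + spec.allometry[1] * sh.volume \
            + rng.normal(0, spec.allometry[2])
        rows.append({
            "shrub_id": sh.shrub_id, "archetype": a.name,
            "cx": sh.cx, "cy": sh.cy, "radius": sh.radius,
            "height": sh.height, "volume_m3": sh.volume,
            "biomass_g": max(0.0, float(biomass)),
        })

    cloud = PointCloud(
        np.concatenate(xs), np.concatenate(ys), np.concatenate(zs),
        np.concatenate(e_idx), np.concatenate(n_ech))
    shrub_table = pd.DataFrame(
        rows, columns=["shrub_id", "archetype", "cx", "cy", "radius",
                       "height", "volume_m3", "biomass_g"])
    return Scene(cloud=cloud, true_class=np.concatenate(labels),
                 truth_schema=schema_full, shrubs=shrub_table, spec=spec)


def remove_last_shrubs(spec: SceneSpec, k: int = 1) -> SceneSpec:
    """Spec with the last ``k`` placements removed.

    Per-shrub random streams are keyed by position in the placement list,
    so dropping placements from the tail leaves every remaining shrub's
    points bit-identical — the property change detection relies on.
    Removing an interior placement would re-key later shrubs and is
    therefore not offered."""
    if not (0 < k <= len(spec.placements)):
        raise ValueError(f"cannot remove {k} of {len(spec.placements)} "
                         "placements")
    return replace(spec, placements=spec.placements[:-k])


def remove_shrub(spec: SceneSpec, shrub_id: int) -> SceneSpec:
    """Spec with the last placement removed; ``shrub_id`` must name it
    (interior removal would re-key later shrubs' random streams)."""
    if shrub_id != len(spec.placements) - 1:
        raise ValueError("only the last placement can be removed without "
                         "re-keying the remaining shrub streams")
    return remove_last_shrubs(spec, 1)


def make_reference_table(scene: Scene, n_absence: int = 8,
                         absence_radius: float = 1.5,
                         ) -> tuple[list[ReferenceRecord], tuple[str, ...]]:
    """Survey emulation: one reference record per placed shrub, plus
    shrub-absence records over open ground.

    Each shrub record sits at the shrub centre with the canopy radius as
    the size-specific gathering radius. Absence records are placed on
    shrub-free ground (terrain undulation pushes some grass returns above
    the 0.3 m layer threshold; the absence class is what teaches the
    classifier that such points are not shrubs — absence records that
    gather no shrub-layer points are skipped downstream with a warning).
    The reference schema is the archetype names plus the trailing
    shrub-absence class."""
    schema = tuple(n for n in scene.truth_schema
                   if n not in ("grass", "ground")) + ("absence",)
    index = {n: i for i, n in enumerate(schema)}
    records = []
    for row in scene.shrubs.itertuples():
        z = float(scene.terrain_z(row.cx, row.cy)) + row.height
        records.append(ReferenceRecord(
            ref_id=int(row.shrub_id), x=float(row.cx), y=float(row.cy), z=z,
            class_id=index[row.archetype],
            object_radius=float(row.radius)))
    rng = np.random.default_rng([scene.spec.seed, 5])
    W, H = scene.spec.extent
    centers = scene.shrubs[["cx", "cy"]].to_numpy() \
        if len(scene.shrubs) else np.zeros((0, 2))
    radii = scene.shrubs["radius"].to_numpy() if len(scene.shrubs) else \
        np.zeros(0)
    placed = 0
    next_id = len(scene.shrubs)
    for _attempt in range(200 * max(1, n_absence)):
        if placed >= n_absence:
            break
        cx = rng.uniform(0.5, W - 0.5)
        cy = rng.uniform(0.5, H - 0.5)
        d = np.hypot(centers[:, 0] - cx, centers[:, 1] - cy) if len(centers) \
            else np.array([np.inf])
        if np.all(d > radii + absence_radius + 0.2):
            records.append(ReferenceRecord(
                ref_id=next_id, x=float(cx), y=float(cy),
                z=float(scene.terrain_z(cx, cy)),
                class_id=index["absence"], object_radius=absence_radius))
            next_id += 1
            placed += 1
    return records, schema


def make_harvest_table(scene: Scene, k: int, seed: int | None = None,
                       archetype: str | None = None) -> list[HarvestRecord]:
    """Harvest records for ``k`` shrubs: the truth biomass as the dry
    mass, delimited by a 25-point GNSS-style ring sampled on the canopy
    footprint boundary (its convex hull closely matches the true circular
    footprint). ``archetype`` restricts harvesting to one growth form —
    a destructive field campaign targets the species whose allometry is
    being built."""
    table = scene.shrubs
    if archetype is not None:
        table = table[table["archetype"] == archetype]
    if k > len(table):
        raise ValueError(f"scene has only {len(table)} shrubs"
                         + (f" of archetype {archetype!r}" if archetype
                            else ""))
    records = []
    for row in table.head(k).itertuples():
        rng = np.random.default_rng(
            [scene.spec.seed if seed is None else seed, 3000 + row.shrub_id])
        theta = np.sort(rng.uniform(0, 2 * math.pi, 25))
        rr = row.radius * rng.uniform(0.97, 1.0, 25)
        x = row.cx + rr * np.cos(theta)
        y = row.cy + rr * np.sin(theta)
        z = scene.terrain_z(x, y) + 0.5 * row.height
        records.append(HarvestRecord(
            shrub_id=int(row.shrub_id), dry_mass=float(row.biomass_g),
            delineation_points=np.column_stack([x, y, z])))
    return records


def scatter_placements(archetypes: list[ShrubArchetype], per_class: int,
                       extent: tuple[float, float], seed: int,
                       margin: float = 1.5, min_sep: float = 3.0,
                       ) -> tuple[Placement, ...]:
    """Randomly place ``per_class`` shrubs of each archetype, keeping
    centres ``min_sep`` apart and ``margin`` off the scene edge."""
    rng = np.random.default_rng([seed, 42])
    W, H = extent
    centers: list[tuple[float, float]] = []
    placements = []
    for a in archetypes:
        for _ in range(per_class):
            for _attempt in range(1000):
                cx = rng.uniform(margin, W - margin)
                cy = rng.uniform(margin, H - margin)
                if all((cx - ox) ** 2 + (cy - oy) ** 2 >= min_sep ** 2
                       for ox, oy in centers):
                    break
            else:
                raise RuntimeError("could not place shrubs with the "
                                   "requested separation")
            centers.append((cx, cy))
            placements.append(Placement(a, (cx, cy)))
    return tuple(placements)
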