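"""Zonation systems: irregular Voronoi-derived units and ASR-matched grids.

A zonation system is a partition of the study region into polygon
sampling units (PSUs).  The irregular (IRR) family starts from one
Voronoi cell per village point — the standard stand-in where village
boundary files do not exist — and is merged into coarser contiguous
units emulating sub-districts and districts.  The regular (REG) family
tiles the region with square cells whose side equals the average
spatial resolution (ASR) of the matching IRR system, so the two
families compare shape at an equal effective scale.
"""

from __future__ import annotations

import heapq
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import MultiPoint, Point, Polygon, box, mapping, shape as shp_shape
from shapely.ops import unary_union

from .landscape import VillageSite

LEVELS = ("village", "subdistrict", "district")
SHAPES = ("IRR", "REG")


@dataclass
class PSU:
    """One polygon sampling unit of a zonation system."""

    id: str
    polygon: Polygon
    level: str
    shape: str
    parent_id: str | None = None
    members: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.polygon.is_empty or not self.polygon.is_valid:
            raise ValueError(f"PSU {self.id!r} has an empty or invalid polygon")
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}")
        if self.shape not in SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}")

    @property
    def area(self) -> float:
        return self.polygon.area


@dataclass
class ZonationSystem:
    """A set of PSUs partitioning the study region at one level/shape."""

    psus: list[PSU]
    region: Polygon
    level: str
    shape: str
    asr: float | None = None
    membership: dict[str, str] = field(default_factory=dict)
    """Maps a finer unit's id to the id of the PSU here that contains it."""

    def __post_init__(self) -> None:
        ids = [p.id for p in self.psus]
        if len(ids) != len(set(ids)):
            raise ValueError("PSU ids must be unique")

    def __len__(self) -> int:
        return len(self.psus)

    def ids(self) -> list[str]:
        return [p.id for p in self.psus]

    def by_id(self) -> dict[str, PSU]:
        return {p.id: p for p in self.psus}

    def total_area(self) -> float:
        return sum(p.area for p in self.psus)


def compute_asr(land_area: float, n_units: int) -> float:
    """Average spatial resolution: sqrt(land area / number of units), in km.

    The effective linear resolution of a set of areal units; used to
    size the regular-grid comparator of an irregular zonation.
    """
    if land_area <= 0:
        raise ValueError(f"land_area must be positive, got {land_area}")
    if n_units < 1:
        raise ValueError(f"n_units must be >= 1, got {n_units}")
    return math.sqrt(land_area / n_units)


def voronoi_zonation(villages: list[VillageSite], region: Polygon,
                     land_area: float | None = None) -> ZonationSystem:
    """One clipped Voronoi cell per village; cell id equals village id.

    Requires at least three non-collinear villages, all inside the
    region, with no duplicated coordinates (run census filtering first).
    """
    if len(villages) < 3:
        raise ValueError("Voronoi tessellation needs at least 3 generator points")
    coords = [(v.x, v.y) for v in villages]
    if len(set(coords)) != len(coords):
        dupes = {c for c in coords if coords.count(c) > 1}
        raise ValueError(
            f"duplicate village coordinates {sorted(dupes)[:3]}; "
            "filter the census before building the tessellation"
        )
    pts = [Point(c) for c in coords]
    for v, p in zip(villages, pts):
        if not region.covers(p):
            raise ValueError(f"village {v.id!r} lies outside the region")

    raw = shapely.voronoi_polygons(
        MultiPoint(pts), extend_to=region.buffer(region.length)
    )
    cells = list(raw.geoms)
    # voronoi_polygons gives no ordering guarantee: match each generator
    # to the (unique) raw cell containing it via an STR-tree.
    tree = shapely.STRtree(cells)
    psus: list[PSU] = []
    for v, p in zip(villages, pts):
        hits = tree.query(p, predicate="within")
        if len(hits) != 1:  # pragma: no cover - defensive
            raise RuntimeError(f"village {v.id!r} matched {len(hits)} Voronoi cells")
        cell = cells[int(hits[0])].intersection(region)
        if cell.geom_type == "MultiPolygon":
            cell = max(cell.geoms, key=lambda g: g.area)
        psus.append(PSU(id=v.id, polygon=cell, level="village", shape="IRR"))

    if land_area is None:
        land_area = region.area
    return ZonationSystem(
        psus=psus,
        region=region,
        level="village",
        shape="IRR",
        asr=compute_asr(land_area, len(psus)),
    )


def _adjacency(psus: list[PSU]) -> dict[int, set[int]]:
    """Indices of PSUs sharing a boundary segment (not just a corner)."""
    geoms = [p.polygon for p in psus]
    tree = shapely.STRtree(geoms)
    adj: dict[int, set[int]] = {i: set() for i in range(len(geoms))}
    left, right = tree.query(geoms, predicate="intersects")
    for a, b in zip(left.tolist(), right.tolist()):
        if a >= b:
            continue
        inter = geoms[a].intersection(geoms[b])
        if inter.length > 0:
            adj[a].add(b)
            adj[b].add(a)
    return adj


def merge_to_coarser(system: ZonationSystem, n_target: int, level: str,
                     seed: int, land_area: float | None = None) -> ZonationSystem:
    """Merge a fine IRR system into ``n_target`` contiguous coarser units.

    Seeded k-way region growing over the PSU adjacency graph: ``n_target``
    seed cells are sampled, then frontier cells are attached one at a
    time to the adjacent partition with the fewest members (ties broken
    by partition then cell id), which keeps units compact and the
    partition strictly nested.  Each input PSU belongs to exactly one
    output unit; the membership map is retained on the result.
    """
    n = len(system.psus)
    if n_target < 1:
        raise ValueError(f"n_target must be >= 1, got {n_target}")
    if n_target > n:
        raise ValueError(f"n_target {n_target} exceeds the {n} PSUs available")
    if system.shape != "IRR":
        raise ValueError("can only merge IRR systems")

    order = sorted(range(n), key=lambda i: system.psus[i].id)
    rng = np.random.default_rng(seed)

    if n_target == n:
        assign = {i: k for k, i in enumerate(order)}
    else:
        adj = _adjacency(system.psus)
        seeds = [order[i] for i in rng.choice(n, size=n_target, replace=False)]
        assign = {s: k for k, s in enumerate(seeds)}
        sizes = [1] * n_target
        # lazy heap of candidate attachments: (partition size at push, k, cell id, cell)
        heap: list[tuple[int, int, str, int]] = []
        for s in seeds:
            k = assign[s]
            for nb in adj[s]:
                if nb not in assign:
                    heapq.heappush(heap, (sizes[k], k, system.psus[nb].id, nb))
        n_assigned = n_target
        while n_assigned < n:
            while heap:
                size_k, k, _, cell = heapq.heappop(heap)
                if cell in assign:
                    continue
                if size_k != sizes[k]:  # stale priority, re-push with current size
                    heapq.heappush(heap, (sizes[k], k, system.psus[cell].id, cell))
                    continue
                break
            else:
                # disconnected component: attach the lexicographically first
                # unassigned cell to the smallest partition
                cell = min(
                    (i for i in range(n) if i not in assign),
                    key=lambda i: system.psus[i].id,
                )
                k = int(np.argmin(sizes))
            assign[cell] = k
            sizes[k] += 1
            n_assigned += 1
            for nb in adj[cell]:
                if nb not in assign:
                    heapq.heappush(heap, (sizes[k], k, system.psus[nb].id, nb))

    prefix = {"subdistrict": "s", "district": "d"}.get(level, level[0])
    width = len(str(max(n_target - 1, 1)))
    groups: dict[int, list[int]] = {}
    for i, k in assign.items():
        groups.setdefault(k, []).append(i)

    psus: list[PSU] = []
    membership: dict[str, str] = {}
    for k in sorted(groups):
        members = sorted(groups[k], key=lambda i: system.psus[i].id)
        geom = unary_union([system.psus[i].polygon for i in members])
        if geom.geom_type == "MultiPolygon":
            geom = geom.buffer(0)
        member_ids = tuple(system.psus[i].id for i in members)
        pid = f"{prefix}{k:0{width}d}"
        psus.append(
            PSU(id=pid, polygon=geom, level=level, shape="IRR", members=member_ids)
        )
        for mid in member_ids:
            membership[mid] = pid

    if land_area is None:
        land_area = system.region.area
    return ZonationSystem(
        psus=psus,
        region=system.region,
        level=level,
        shape="IRR",
        asr=compute_asr(land_area, n_target),
        membership=membership,
    )


def regular_grid_zonation(region: Polygon, asr: float, level: str,
                          min_area_frac: float = 0.05) -> ZonationSystem:
    """Square-cell zonation with cell side ``asr``, clipped to the region.

    The grid is anchored at the lower-left corner of the region's
    bounding box.  Clipped cells smaller than ``min_area_frac * asr**2``
    are dropped to avoid sliver units with unstable densities.
    """
    if asr <= 0:
        raise ValueError(f"asr must be positive, got {asr}")
    xmin, ymin, xmax, ymax = region.bounds
    nx = max(1, math.ceil((xmax - xmin) / asr - 1e-9))
    ny = max(1, math.ceil((ymax - ymin) / asr - 1e-9))
    min_area = min_area_frac * asr * asr
    candidates: list[tuple[str, Polygon]] = []
    wy, wx = len(str(ny - 1)) if ny > 1 else 1, len(str(nx - 1)) if nx > 1 else 1
    for iy in range(ny):
        for ix in range(nx):
            cell = box(
                xmin + ix * asr, ymin + iy * asr,
                xmin + (ix + 1) * asr, ymin + (iy + 1) * asr,
            )
            clipped = cell.intersection(region)
            if clipped.is_empty or clipped.area == 0:
                continue
            if clipped.geom_type == "MultiPolygon":
                clipped = max(clipped.geoms, key=lambda g: g.area)
            candidates.append((f"g{iy:0{wy}d}_{ix:0{wx}d}", clipped))
    kept = [(cid, g) for cid, g in candidates if g.area >= min_area]
    if not kept:  # asr larger than the region: one clipped cell, not an error
        kept = [max(candidates, key=lambda cg: cg[1].area)]
    psus = [
        PSU(id=cid, polygon=g, level=level, shape="REG") for cid, g in kept
    ]
    return ZonationSystem(
        psus=psus, region=region, level=level, shape="REG", asr=asr
    )


def system_to_geojson(system: ZonationSystem, path: str | Path) -> None:
    """Write the system as a GeoJSON FeatureCollection
    (id, level, shape, area_km2, parent_id properties)."""
    feats = []
    for p in system.psus:
        feats.append(
            {
                "type": "Feature",
                "geometry": mapping(p.polygon),
                "properties": {
                    "id": p.id,
                    "level": p.level,
                    "shape": p.shape,
                    "area_km2": p.area,
                    "parent_id": p.parent_id,
                },
            }
        )
    obj = {
        "type": "FeatureCollection",
        "features": feats,
        "properties": {
            "level": system.level,
            "shape": system.shape,
            "asr": system.asr,
            "region": mapping(system.region),
            "membership": system.membership,
        },
    }
    Path(path).write_text(json.dumps(obj))


def system_from_geojson(path: str | Path) -> ZonationSystem:
    obj = json.loads(Path(path).read_text())
    meta = obj.get("properties", {})
    psus = [
        PSU(
            id=f["properties"]["id"],
            polygon=shp_shape(f["geometry"]),
            level=f["properties"]["level"],
            shape=f["properties"]["shape"],
            parent_id=f["properties"].get("parent_id"),
        )
        for f in obj["features"]
    ]
    return ZonationSystem(
        psus=psus,
        region=shp_shape(meta["region"]) if "region" in meta else unary_union(
            [p.polygon for p in psus]
        ),
        level=meta.get("level", psus[0].level),
        shape=meta.get("shape", psus[0].shape),
        asr=meta.get("asr"),
        membership=meta.get("membership", {}),
    )
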