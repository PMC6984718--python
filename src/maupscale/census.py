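"""Census filtering and additive aggregation into zonation systems.

The response variable of the downscaling model is the log10 of the
per-PSU density of birds per suitable km²: raw point records are
filtered (bad coordinates, duplicated ids or coordinates), counts are
summed additively into each polygon sampling unit, divided by the
unit's suitable land area, and log-transformed with a configurable
offset so zero-count units remain usable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from .grid import PredictorStack
from .landscape import VillageSite
from .zonation import PSU, ZonationSystem

logger = logging.getLogger(__name__)

DENSITY_OFFSET = 1.0
"""Default offset (birds per suitable km²) added inside the log10."""


@dataclass(frozen=True)
class PSURecord:
    """Aggregated census state of one PSU."""

    psu_id: str
    count: int
    suitable_area: float
    density: float
    log_density: float

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError(f"negative count for PSU {self.psu_id!r}")


@dataclass(frozen=True)
class FilterReport:
    """Tallies of the census filtering rules applied, one count per rule."""

    n_input: int
    n_bad_coords: int
    n_dup_id: int
    n_dup_coords: int
    n_retained: int

    def __post_init__(self) -> None:
        if self.n_retained != (
            self.n_input - self.n_bad_coords - self.n_dup_id - self.n_dup_coords
        ):
            raise ValueError("filter report tallies are inconsistent")


def filter_records(raw: pd.DataFrame, region: Polygon,
                   seed: int) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the census cleaning rules and report per-rule removal counts.

    Records with a zero coordinate field or falling outside the study
    region are removed.  Among records sharing an id, and then among
    records sharing exact coordinates, one is kept uniformly at random
    under ``seed``; the others count as removals.
    """
    for col in ("id", "x", "y"):
        if col not in raw.columns:
            raise KeyError(f"census table is missing required column {col!r}")
    n_input = len(raw)
    rng = np.random.default_rng(seed)

    zero = (raw["x"] == 0) | (raw["y"] == 0)
    pts = shapely.points(raw["x"].to_numpy(float), raw["y"].to_numpy(float))
    inside = shapely.covers(region, pts)
    good = raw[~zero & inside]
    n_bad = n_input - len(good)

    def keep_one(df: pd.DataFrame, key) -> pd.DataFrame:
        picked = []
        for _, grp in df.groupby(key, sort=True):
            if len(grp) == 1:
                picked.append(grp.index[0])
            else:
                picked.append(grp.index[int(rng.integers(len(grp)))])
        return df.loc[sorted(picked)]

    dedup_id = keep_one(good, "id")
    n_dup_id = len(good) - len(dedup_id)
    dedup_xy = keep_one(dedup_id, ["x", "y"])
    n_dup_xy = len(dedup_id) - len(dedup_xy)

    report = FilterReport(
        n_input=n_input,
        n_bad_coords=n_bad,
        n_dup_id=n_dup_id,
        n_dup_coords=n_dup_xy,
        n_retained=len(dedup_xy),
    )
    return dedup_xy.reset_index(drop=True), report


def assign_villages(villages: list[VillageSite],
                    system: ZonationSystem) -> dict[str, str]:
    """Map each village id to the id of the PSU containing it.

    Villages on a shared PSU boundary are assigned to the PSU with the
    smallest id, so the assignment is a deterministic partition.  A
    village outside every PSU raises an error naming it.
    """
    geoms = [p.polygon for p in system.psus]
    tree = shapely.STRtree(geoms)
    pts = shapely.points([v.x for v in villages], [v.y for v in villages])
    vi, pi = tree.query(pts, predicate="intersects")
    best: dict[int, str] = {}
    for v_idx, p_idx in zip(vi.tolist(), pi.tolist()):
        pid = system.psus[p_idx].id
        if v_idx not in best or pid < best[v_idx]:
            best[v_idx] = pid
    missing = [villages[k].id for k in range(len(villages)) if k not in best]
    if missing:
        raise ValueError(
            f"villages outside every PSU: {missing[:5]}"
            + ("..." if len(missing) > 5 else "")
        )
    return {villages[k].id: pid for k, pid in best.items()}


def aggregate_counts(villages: list[VillageSite], system: ZonationSystem,
                     species: str,
                     assignment: dict[str, str] | None = None) -> dict[str, int]:
    """Additive aggregation: PSU count = sum of member village counts.

    PSUs containing no villages get count 0, so the totals are conserved
    exactly under any partition of the region.
    """
    if assignment is None:
        assignment = assign_villages(villages, system)
    counts = {p.id: 0 for p in system.psus}
    for v in villages:
        counts[assignment[v.id]] += v.count(species)
    return counts


def suitable_pixel_indices(polygon, stack: PredictorStack
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Row/col indices of suitable pixels whose centers fall strictly
    inside the polygon (pixel-center containment rule, half-open cells).

    The search is restricted to the polygon's bounding-box window, so
    it is exact but cheap even on large grids.
    """
    spec = stack.spec
    xmin, ymin, xmax, ymax = polygon.bounds
    j0 = max(0, int(math.floor((xmin - spec.x0) / spec.cell)))
    j1 = min(spec.ncols, int(math.ceil((xmax - spec.x0) / spec.cell)))
    i0 = max(0, int(math.floor((ymin - spec.y0) / spec.cell)))
    i1 = min(spec.nrows, int(math.ceil((ymax - spec.y0) / spec.cell)))
    empty = np.array([], dtype=int)
    if j1 <= j0 or i1 <= i0:
        return empty, empty
    sub = stack.mask[i0:i1, j0:j1]
    ii, jj = np.nonzero(sub)
    if ii.size == 0:
        return empty, empty
    cx = spec.x0 + (jj + j0 + 0.5) * spec.cell
    cy = spec.y0 + (ii + i0 + 0.5) * spec.cell
    inside = shapely.contains_xy(polygon, cx, cy)
    return ii[inside] + i0, jj[inside] + j0


def suitable_area(psu: PSU, stack: PredictorStack) -> float:
    """Suitable land area (km²) of a PSU by the pixel-center rule.

    Counts the suitable pixels whose centers fall strictly inside the
    polygon and multiplies by the cell area.  Returns 0 for fully
    unsuitable PSUs.
    """
    ii, _ = suitable_pixel_indices(psu.polygon, stack)
    return float(ii.size) * stack.spec.cell_area()


def label_raster(system: ZonationSystem, stack: PredictorStack) -> np.ndarray:
    """Integer raster assigning each suitable pixel center to a PSU index.

    Uses the same strict pixel-center containment rule as
    :func:`suitable_area`; unassigned or unsuitable pixels get -1.
    PSU indices follow ``system.psus`` order.
    """
    spec = stack.spec
    lab = np.full(spec.shape, -1, dtype=np.int32)
    ii, jj = np.nonzero(stack.mask)
    if ii.size == 0:
        return lab
    cx = spec.x0 + (jj + 0.5) * spec.cell
    cy = spec.y0 + (ii + 0.5) * spec.cell
    pts = shapely.points(cx, cy)
    tree = shapely.STRtree([p.polygon for p in system.psus])
    pt_idx, p_idx = tree.query(pts, predicate="within")
    # resolve boundary double-hits to the smallest PSU id (none expected
    # under strict containment, but keep the partition deterministic)
    psu_ids = np.array([system.psus[k].id for k in p_idx.tolist()])
    order = np.lexsort((psu_ids, pt_idx))
    for q, p in zip(pt_idx[order].tolist(), p_idx[order].tolist()):
        r, c = int(ii[q]), int(jj[q])
        if lab[r, c] == -1:
            lab[r, c] = p
    return lab


def suitable_areas_all(system: ZonationSystem, stack: PredictorStack,
                       labels: np.ndarray | None = None) -> dict[str, float]:
    """Suitable area of every PSU in one vectorised pass."""
    if labels is None:
        labels = label_raster(system, stack)
    flat = labels[labels >= 0]
    counts = np.bincount(flat, minlength=len(system.psus))
    ca = stack.spec.cell_area()
    return {p.id: float(counts[k]) * ca for k, p in enumerate(system.psus)}


def make_response(counts: dict[str, int], areas: dict[str, float],
                  offset: float = DENSITY_OFFSET
                  ) -> tuple[list[PSURecord], list[str]]:
    """Per-PSU log10 density response records.

    density = count / suitable_area; log_density = log10(density + offset).
    PSUs with zero suitable area — and, when ``offset`` is 0, PSUs with
    zero count — are excluded and their ids returned separately.
    """
    if set(counts) != set(areas):
        orphans = set(counts) ^ set(areas)
        raise KeyError(f"counts and areas keyed differently: {sorted(orphans)[:5]}")
    records: list[PSURecord] = []
    excluded: list[str] = []
    for pid in sorted(counts):
        c = counts[pid]
        if c < 0:
            raise ValueError(f"negative count for PSU {pid!r}")
        a = areas[pid]
        if a <= 0:
            excluded.append(pid)
            continue
        density = c / a
        if density + offset <= 0:
            excluded.append(pid)
            continue
        records.append(
            PSURecord(
                psu_id=pid,
                count=int(c),
                suitable_area=float(a),
                density=float(density),
                log_density=float(np.log10(density + offset)),
            )
        )
    if excluded:
        logger.info("make_response: excluded %d PSUs (zero suitable area "
                    "or non-positive density+offset)", len(excluded))
    return records, excluded


def response_to_frame(records: list[PSURecord], level: str = "",
                      shape: str = "") -> pd.DataFrame:
    """Long-format response table (psu_id, level, shape, count,
    suitable_km2, density, log_density)."""
    return pd.DataFrame(
        {
            "psu_id": [r.psu_id for r in records],
            "level": level,
            "shape": shape,
            "count": [r.count for r in records],
            "suitable_km2": [r.suitable_area for r in records],
            "density": [r.density for r in records],
            "log_density": [r.log_density for r in records],
        }
    )
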