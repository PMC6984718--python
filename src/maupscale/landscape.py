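"""Synthetic landscape generator.

Produces seeded stand-ins for the inputs of a national livestock census
downscaling study: spatially autocorrelated environmental predictors, a
suitability mask with contiguous unsuitable patches (water, protected or
unpopulated land), village point locations, and per-village head counts
for species with contrasting spatial regimes — one distributed
homogeneously across the landscape, one clustered on patches of a focal
covariate (the synthetic analogue of ducks concentrating in wetland
rice-paddy areas while chickens are raised everywhere).

Every generator is deterministic under its seed: identical inputs and
seed give bit-identical output.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .grid import GridSpec, PredictorStack


@dataclass(frozen=True)
class VillageSite:
    """One village point: unique id, planar coordinates (km), per-species counts."""

    id: str
    x: float
    y: float
    counts: dict[str, int] = field(default_factory=dict, compare=False)

    def count(self, species: str) -> int:
        return self.counts.get(species, 0)


@dataclass(frozen=True)
class SpeciesProfile:
    """Statistical profile of one species' spatial abundance regime.

    Parameters
    ----------
    name : str
        Species label (e.g. ``"chicken"``).
    regime : {"homogeneous", "clustered"}
        Homogeneous species respond (weakly) to predictors everywhere;
        clustered species are additionally gated onto high values of a
        focal covariate, concentrating abundance in patches.
    focal_layer : str or None
        Layer name driving the clustering gate (clustered regime only).
    effect_sizes : dict
        Coefficients linking predictor layers to log-abundance.
    intercept : float
        Baseline log-abundance; sets the expected head count of an
        average village before rescaling, hence the zero-count rate.
    site_noise_sd : float
        Standard deviation (natural-log scale) of an unstructured
        log-normal village effect added to the linear predictor.  It
        models the between-village heterogeneity a census shows but the
        predictors cannot explain (husbandry practices, reporting
        error); because it is spatially unstructured it averages out
        under aggregation, which is what makes coarse-scale responses
        smoother than village-scale ones.
    dispersion : float
        Negative-binomial dispersion (size) parameter; smaller values
        mean more overdispersed counts. Must be positive.
    total : int
        Target national head count; generated counts are rescaled to
        sum to this exactly.
    gate_quantile : float
        Quantile of the focal layer above which the clustered gate
        opens (soft threshold).
    gate_sharpness : float
        Steepness of the logistic gate, in units of focal-layer sd.
    gate_floor : float
        Minimum relative abundance off-patch.  A small positive floor
        keeps the clustered species present (at low density) outside
        its core habitat, as real censuses show.
    """

    name: str
    regime: str
    effect_sizes: dict[str, float] = field(default_factory=dict)
    intercept: float = 3.0
    site_noise_sd: float = 1.5
    focal_layer: str | None = None
    dispersion: float = 1.0
    total: int = 1_000_000
    gate_quantile: float = 0.75
    gate_sharpness: float = 8.0
    gate_floor: float = 0.0

    def __post_init__(self) -> None:
        if self.regime not in ("homogeneous", "clustered"):
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.regime == "clustered" and not self.focal_layer:
            raise ValueError("clustered regime requires a focal_layer")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.total < 0:
            raise ValueError("total must be non-negative")


def generate_predictors(spec: GridSpec, n_layers: int, range_km: float,
                        seed: int) -> PredictorStack:
    """Generate ``n_layers`` spatially autocorrelated predictor rasters.

    Each layer is Gaussian-smoothed white noise with kernel scale
    ``range_km`` (the correlation length), standardized to zero mean and
    unit standard deviation over the grid.  Layers are named
    ``pred_00 .. pred_NN``; the suitability mask starts out all-True.
    """
    if n_layers < 1:
        raise ValueError(f"n_layers must be >= 1, got {n_layers}")
    if range_km <= 0:
        raise ValueError(f"range_km must be positive, got {range_km}")

    rng = np.random.default_rng(seed)
    sigma_px = range_km / spec.cell
    layers: dict[str, np.ndarray] = {}
    for k in range(n_layers):
        noise = rng.standard_normal(spec.shape)
        fld = ndimage.gaussian_filter(noise, sigma=sigma_px, mode="reflect")
        fld = (fld - fld.mean()) / fld.std()
        layers[f"pred_{k:02d}"] = fld
    return PredictorStack(spec=spec, layers=layers)


def generate_suitability_mask(stack: PredictorStack, unsuitable_fraction: float,
                              seed: int, range_km: float | None = None
                              ) -> PredictorStack:
    """Fill the stack's mask with contiguous-ish unsuitable patches.

    An auxiliary autocorrelated field is thresholded at the
    ``unsuitable_fraction`` quantile: pixels below the threshold are
    unsuitable, so patches inherit the field's spatial coherence.  The
    realised unsuitable share matches the request up to quantile ties.
    """
    if not 0 <= unsuitable_fraction < 1:
        raise ValueError(
            f"unsuitable_fraction must be in [0, 1), got {unsuitable_fraction}"
        )
    if unsuitable_fraction == 0:
        return stack.with_mask(np.ones(stack.spec.shape, dtype=bool))

    spec = stack.spec
    if range_km is None:
        range_km = 0.05 * min(spec.width, spec.height)
    rng = np.random.default_rng(seed)
    fld = ndimage.gaussian_filter(
        rng.standard_normal(spec.shape), sigma=range_km / spec.cell, mode="reflect"
    )
    thresh = np.quantile(fld, unsuitable_fraction)
    return stack.with_mask(fld >= thresh)


def generate_villages(stack: PredictorStack, n: int, clustering: str = "uniform",
                      seed: int = 0, parent_rate: float = 0.05,
                      cluster_sd_km: float | None = None) -> list[VillageSite]:
    """Place ``n`` village points on suitable pixels.

    ``uniform`` draws suitable pixels without replacement and jitters
    the point uniformly within the pixel.  ``clustered`` uses a
    parent-offspring (Neyman-Scott style) process: parents uniform on
    suitable land, offspring displaced by isotropic Gaussian noise and
    rejected off suitable land.
    """
    if n < 3:
        raise ValueError(f"need at least 3 villages (Voronoi generators), got {n}")
    if clustering not in ("uniform", "clustered"):
        raise ValueError(f"unknown clustering mode {clustering!r}")

    spec = stack.spec
    suit_i, suit_j = np.nonzero(stack.mask)
    if suit_i.size == 0:
        raise ValueError("stack has no suitable pixels")
    if n > suit_i.size:
        raise ValueError(
            f"cannot place {n} villages on {suit_i.size} suitable pixels"
        )

    rng = np.random.default_rng(seed)

    if clustering == "uniform":
        pick = rng.choice(suit_i.size, size=n, replace=False)
        ii, jj = suit_i[pick], suit_j[pick]
        xs = spec.x0 + (jj + rng.uniform(0.05, 0.95, n)) * spec.cell
        ys = spec.y0 + (ii + rng.uniform(0.05, 0.95, n)) * spec.cell
    else:
        if cluster_sd_km is None:
            cluster_sd_km = 0.03 * min(spec.width, spec.height)
        n_parents = max(1, int(round(parent_rate * n)))
        pick = rng.choice(suit_i.size, size=min(n_parents, suit_i.size), replace=False)
        px = spec.x0 + (suit_j[pick] + 0.5) * spec.cell
        py = spec.y0 + (suit_i[pick] + 0.5) * spec.cell
        xs_list: list[float] = []
        ys_list: list[float] = []
        seen: set[tuple[float, float]] = set()
        while len(xs_list) < n:
            k = int(rng.integers(len(px)))
            x = px[k] + rng.normal(0, cluster_sd_km)
            y = py[k] + rng.normal(0, cluster_sd_km)
            if not spec.contains(x, y):
                continue
            i, j = spec.index_of(x, y)
            if not stack.mask[i, j] or (x, y) in seen:
                continue
            seen.add((x, y))
            xs_list.append(float(x))
            ys_list.append(float(y))
        xs = np.array(xs_list)
        ys = np.array(ys_list)

    width = len(str(n - 1))
    return [
        VillageSite(id=f"v{k:0{width}d}", x=float(xs[k]), y=float(ys[k]))
        for k in range(n)
    ]


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``weights``, exact sum."""
    w = np.asarray(weights, dtype=np.float64)
    if w.sum() <= 0:
        w = np.ones_like(w)
    quota = w * (total / w.sum())
    base = np.floor(quota).astype(np.int64)
    short = total - int(base.sum())
    if short > 0:
        frac = quota - base
        # deterministic tie-break: larger fraction first, then lower index
        order = np.lexsort((np.arange(len(w)), -frac))
        base[order[:short]] += 1
    return base


def generate_population(villages: list[VillageSite], stack: PredictorStack,
                        profile: SpeciesProfile, seed: int) -> list[VillageSite]:
    """Draw per-village counts for one species and rescale to the exact total.

    Counts follow a negative-binomial model: the log-mean is the
    profile's linear predictor evaluated at each village's pixel, plus
    an unstructured log-normal village effect (``site_noise_sd``); the
    clustered regime multiplies the mean by a soft logistic gate on the
    focal layer so abundance concentrates in high-focal patches.  The
    draw is then rescaled by largest-remainder rounding so the national
    total equals ``profile.total`` exactly.
    """
    if not villages:
        raise ValueError("villages must be non-empty")
    for lyr in profile.effect_sizes:
        if lyr not in stack.layers:
            raise KeyError(f"profile references missing layer {lyr!r}")
    if profile.regime == "clustered" and profile.focal_layer not in stack.layers:
        raise KeyError(f"focal layer {profile.focal_layer!r} not in stack")

    spec = stack.spec
    xs = np.array([v.x for v in villages])
    ys = np.array([v.y for v in villages])
    ii, jj = spec.index_of(xs, ys)

    eta = np.full(len(villages), profile.intercept)
    for lyr, beta in profile.effect_sizes.items():
        eta += beta * stack.layers[lyr][ii, jj]
    mu = np.exp(eta)

    if profile.regime == "clustered":
        focal = stack.layers[profile.focal_layer]
        fvals = focal[ii, jj]
        q = np.quantile(focal[stack.mask], profile.gate_quantile)
        sd = focal[stack.mask].std()
        gate = 1.0 / (1.0 + np.exp(-profile.gate_sharpness * (fvals - q) / sd))
        gate = profile.gate_floor + (1.0 - profile.gate_floor) * gate
        mu = mu * gate

    rng = np.random.default_rng(seed)
    if profile.site_noise_sd > 0:
        mu = mu * np.exp(rng.normal(0.0, profile.site_noise_sd, len(villages)))
    k = profile.dispersion
    # NB with mean mu and size k: p = k / (k + mu)
    p = k / (k + np.maximum(mu, 1e-12))
    raw = rng.negative_binomial(k, p)
    counts = _largest_remainder(raw.astype(np.float64), profile.total)

    out = []
    for v, c in zip(villages, counts):
        merged = dict(v.counts)
        merged[profile.name] = int(c)
        out.append(VillageSite(id=v.id, x=v.x, y=v.y, counts=merged))
    return out


def default_species_profiles(focal_layer: str = "pred_00",
                             total: int = 1_000_000) -> list[SpeciesProfile]:
    """Two contrasting regimes mirroring a backyard species raised
    everywhere and a species tied to a focal habitat covariate."""
    return [
        SpeciesProfile(
            name="homogeneous",
            regime="homogeneous",
            effect_sizes={"pred_01": 0.4, "pred_02": 0.3},
            dispersion=1.0,
            total=total,
        ),
        SpeciesProfile(
            name="clustered",
            regime="clustered",
            focal_layer=focal_layer,
            effect_sizes={focal_layer: 1.2, "pred_01": 0.4},
            dispersion=1.0,
            total=total,
            gate_sharpness=3.0,
            gate_quantile=0.6,
            gate_floor=0.03,
        ),
    ]


def villages_to_csv(villages: list[VillageSite], path: str | Path) -> None:
    """Write villages as long-format CSV: id,x,y,species,count."""
    species = sorted({s for v in villages for s in v.counts})
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "x", "y", "species", "count"])
        for v in villages:
            if species:
                for s in species:
                    w.writerow([v.id, repr(v.x), repr(v.y), s, v.count(s)])
            else:
                w.writerow([v.id, repr(v.x), repr(v.y), "", 0])


def villages_to_geojson(villages: list[VillageSite], path: str | Path) -> None:
    feats = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [v.x, v.y]},
            "properties": {"id": v.id, **{s: c for s, c in v.counts.items()}},
        }
        for v in villages
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": feats})
    )
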