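"""Model evaluation: goodness of fit and downscaling precision.

Three surfaces are computed, mirroring the sensitivity design:

* **Internal fit** — RMSE and Pearson's r (COR) between observed
  log10 densities of the held-out PSUs and the pixel predictions
  aggregated back to those PSUs.
* **Area-stratified fit** — the same metrics within PSU-area classes
  (0-10/10-20/>20 km² for villages, 0-100/100-200/>200 for
  sub-district-scale units, 0-500/500-1000/>1000 for district-scale).
* **Downscaling precision (COR_down)** — Pearson's r between the
  predictions aggregated to the finest (village) units and the
  observed village log-densities, whatever scale trained the model.

Back-aggregation happens in linear density space (predictions are
exponentiated, averaged over the PSU's suitable pixels, then
re-logged), so predicted PSU values are constructed the same way as the
observed ones (count / area, then log) and the two are commensurable.
Degenerate correlations (either vector constant) are returned as NaN,
never as 0, so they cannot silently bias replicate averages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .census import PSURecord, label_raster, suitable_pixel_indices
from .grid import PredictorStack
from .zonation import PSU, ZonationSystem

logger = logging.getLogger(__name__)

AREA_CLASS_LABELS = ("c1", "c2", "c3")


@dataclass(frozen=True)
class AreaClassScheme:
    """Two strictly increasing breakpoints (km²) defining three PSU-area
    classes: [0, b1), [b1, b2), [b2, inf)."""

    breakpoints: tuple[float, float]

    def __post_init__(self) -> None:
        b1, b2 = self.breakpoints
        if not 0 < b1 < b2:
            raise ValueError("breakpoints must be strictly increasing and positive")

    def classify(self, area: float) -> str:
        b1, b2 = self.breakpoints
        if area < b1:
            return "c1"
        if area < b2:
            return "c2"
        return "c3"

    def label(self, cls: str) -> str:
        b1, b2 = self.breakpoints
        return {"c1": f"0-{b1:g} km2", "c2": f"{b1:g}-{b2:g} km2",
                "c3": f">{b2:g} km2"}[cls]


DEFAULT_SCHEMES = {
    "village": AreaClassScheme((10.0, 20.0)),
    "subdistrict": AreaClassScheme((100.0, 200.0)),
    "district": AreaClassScheme((500.0, 1000.0)),
}


def rmse(obs, pred) -> float:
    """Root mean square error between paired vectors."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError(f"length mismatch: {obs.shape} vs {pred.shape}")
    if obs.size == 0:
        raise ValueError("need at least one pair")
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def pearson(obs, pred) -> float:
    """Sample Pearson correlation; NaN (with a warning) if either vector
    has zero variance."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError(f"length mismatch: {obs.shape} vs {pred.shape}")
    if obs.size < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    # degenerate to rounding noise counts as zero variance: a constant
    # raster back-aggregated per PSU can differ across PSUs in the last ulp
    def _degenerate(v: np.ndarray) -> bool:
        return np.ptp(v) <= 1e-12 * max(1.0, float(np.abs(v).max()))

    if _degenerate(obs) or _degenerate(pred):
        logger.warning("pearson: zero-variance input, returning NaN")
        return float("nan")
    o = obs - obs.mean()
    p = pred - pred.mean()
    return float((o @ p) / np.sqrt((o @ o) * (p @ p)))


def aggregate_prediction(raster: np.ndarray, psu: PSU, stack: PredictorStack,
                         offset: float) -> float:
    """Predicted PSU log10 density from a pixel prediction raster.

    Back-transforms each suitable pixel to linear density
    (``10**v - offset``, floored at 0), averages over the PSU, and
    re-applies ``log10(mean + offset)`` — the same construction as the
    observed response.
    """
    ii, jj = suitable_pixel_indices(psu.polygon, stack)
    if ii.size == 0:
        logger.warning("aggregate_prediction: PSU %s has no suitable pixel",
                       psu.id)
        return float("nan")
    vals = raster[ii, jj]
    lin = np.maximum(10.0 ** vals - offset, 0.0)
    return float(np.log10(np.mean(lin) + offset))


def aggregate_prediction_all(raster: np.ndarray, labels: np.ndarray,
                             n_psus: int, offset: float) -> np.ndarray:
    """Vectorised :func:`aggregate_prediction` for every PSU at once.

    ``labels`` assigns each pixel to a PSU index (-1 = none); returns an
    array of length ``n_psus`` with NaN for PSUs without pixels.
    """
    sel = labels >= 0
    flat = labels[sel]
    lin = np.maximum(10.0 ** raster[sel] - offset, 0.0)
    counts = np.bincount(flat, minlength=n_psus).astype(float)
    sums = np.bincount(flat, weights=lin, minlength=n_psus)
    out = np.full(n_psus, np.nan)
    ok = counts > 0
    out[ok] = np.log10(sums[ok] / counts[ok] + offset)
    return out


def paired_obs_pred(raster: np.ndarray, system: ZonationSystem,
                    response: list[PSURecord], stack: PredictorStack,
                    offset: float, psu_ids=None,
                    labels: np.ndarray | None = None) -> pd.DataFrame:
    """Observed vs back-aggregated predicted log-densities per PSU.

    Returns a frame indexed by psu_id with columns obs, pred, area
    (polygon area, km²), restricted to ``psu_ids`` when given and to
    PSUs with a response record and at least one suitable pixel.
    """
    if labels is None:
        labels = label_raster(system, stack)
    pred = aggregate_prediction_all(raster, labels, len(system.psus), offset)
    obs = {r.psu_id: r.log_density for r in response}
    wanted = set(psu_ids) if psu_ids is not None else set(obs)
    rows, index = [], []
    for k, p in enumerate(system.psus):
        if p.id not in obs or p.id not in wanted or not np.isfinite(pred[k]):
            continue
        index.append(p.id)
        rows.append((obs[p.id], float(pred[k]), p.area))
    return pd.DataFrame(rows, index=index, columns=["obs", "pred", "area"])


def area_stratified_metrics(pairs: pd.DataFrame,
                            scheme: AreaClassScheme) -> pd.DataFrame:
    """RMSE and COR overall and within each PSU-area class.

    Classes with fewer than 3 PSUs emit NaN rows rather than being
    dropped, so the output schema is stable across replicates.
    """
    rows = []

    def emit(cls: str, sub: pd.DataFrame) -> None:
        if len(sub) >= 3:
            rows.append(("RMSE", cls, rmse(sub["obs"], sub["pred"]), len(sub)))
            rows.append(("COR", cls, pearson(sub["obs"], sub["pred"]), len(sub)))
        else:
            rows.append(("RMSE", cls, float("nan"), len(sub)))
            rows.append(("COR", cls, float("nan"), len(sub)))

    emit("all", pairs)
    classes = pairs["area"].map(scheme.classify)
    for cls in AREA_CLASS_LABELS:
        emit(cls, pairs[classes == cls])
    return pd.DataFrame(rows, columns=["metric", "area_class", "value", "n_psus"])


def downscaling_precision(raster: np.ndarray, village_system: ZonationSystem,
                          village_response: list[PSURecord],
                          stack: PredictorStack, offset: float,
                          village_ids=None,
                          labels: np.ndarray | None = None) -> float:
    """COR_down: Pearson's r between predictions aggregated to the
    finest (village) units and the observed village log-densities.

    Computed over every village with suitable area by default; pass
    ``village_ids`` to restrict to a validation fold.
    """
    pairs = paired_obs_pred(
        raster, village_system, village_response, stack, offset,
        psu_ids=village_ids, labels=labels,
    )
    if len(pairs) < 3:
        raise ValueError("fewer than 3 villages with predictions")
    return pearson(pairs["obs"], pairs["pred"])
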