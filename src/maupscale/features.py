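"""Per-PSU predictor vectors by the two sampling methods under comparison.

``random_point`` draws one uniform point inside the polygon (restricted
to suitable land, so masked pixels never feed the model) and reads the
matching pixel of every layer.  ``average`` takes the unweighted mean of
each layer over the suitable pixels whose centers fall in the polygon.
For a spatially constant layer the two methods agree exactly.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import shapely

from .census import suitable_pixel_indices
from .grid import PredictorStack
from .zonation import PSU, ZonationSystem

logger = logging.getLogger(__name__)

SAMPLING_METHODS = ("random_point", "average")
MAX_REJECTION_TRIES = 1000


def extract_zonal_average(psu: PSU, stack: PredictorStack) -> dict[str, float]:
    """Unweighted per-layer mean over suitable pixels inside the PSU.

    Pixels are enumerated in row-major order and averaged with pairwise
    float64 summation, so the result is bit-reproducible regardless of
    how the polygon was constructed.
    """
    ii, jj = suitable_pixel_indices(psu.polygon, stack)
    if ii.size == 0:
        raise ValueError(
            f"PSU {psu.id!r} contains no suitable pixel; exclude it upstream"
        )
    return {
        name: float(np.mean(stack.layers[name][ii, jj].astype(np.float64)))
        for name in stack.layer_names
    }


def extract_random_point(psu: PSU, stack: PredictorStack,
                         seed: int) -> dict[str, float]:
    """Predictor values at one uniformly sampled suitable point in the PSU.

    Rejection-samples uniform points in the polygon's bounding box until
    one falls inside the polygon on a suitable pixel (at most
    ``MAX_REJECTION_TRIES`` draws, after which the zonal average is
    returned with a warning — this only happens for near-degenerate
    polygons whose suitable area is a sliver).
    """
    ii, jj = suitable_pixel_indices(psu.polygon, stack)
    if ii.size == 0:
        raise ValueError(
            f"PSU {psu.id!r} contains no suitable pixel; exclude it upstream"
        )
    member = set(zip(ii.tolist(), jj.tolist()))
    spec = stack.spec
    xmin, ymin, xmax, ymax = psu.polygon.bounds
    rng = np.random.default_rng(seed)
    for _ in range(MAX_REJECTION_TRIES):
        x = rng.uniform(xmin, xmax)
        y = rng.uniform(ymin, ymax)
        if not shapely.contains_xy(psu.polygon, x, y):
            continue
        if not spec.contains(x, y):
            continue
        i, j = (int(v) for v in spec.index_of(x, y))
        # the pixel must belong to the PSU's own enumeration (its center
        # inside the polygon), so the vector is one of the PSU's pixels
        if (i, j) in member:
            return {name: float(stack.layers[name][i, j])
                    for name in stack.layer_names}
    logger.warning(
        "random-point sampling exhausted %d tries in PSU %s; "
        "falling back to the zonal average", MAX_REJECTION_TRIES, psu.id,
    )
    return extract_zonal_average(psu, stack)


def build_feature_table(system: ZonationSystem, stack: PredictorStack,
                        sampling: str, seed: int = 0,
                        labels: np.ndarray | None = None) -> pd.DataFrame:
    """Feature matrix for every PSU with at least one suitable pixel.

    Returns a DataFrame indexed by psu_id with one column per layer and
    a ``sampling`` tag in ``attrs``.  PSUs without suitable pixels are
    omitted (they carry no usable response either).  For ``average``
    sampling a precomputed label raster makes this a single vectorised
    group-by; ``random_point`` derives one child seed per PSU from
    ``seed`` so rows are independent but reproducible.
    """
    if sampling not in SAMPLING_METHODS:
        raise ValueError(f"sampling must be one of {SAMPLING_METHODS}")

    names = stack.layer_names
    if sampling == "average" and labels is not None:
        flat = labels[labels >= 0]
        counts = np.bincount(flat, minlength=len(system.psus))
        rows, index = [], []
        sums = {
            n: np.bincount(flat, weights=stack.layers[n][labels >= 0],
                           minlength=len(system.psus))
            for n in names
        }
        for k, p in enumerate(system.psus):
            if counts[k] == 0:
                continue
            index.append(p.id)
            rows.append([sums[n][k] / counts[k] for n in names])
        df = pd.DataFrame(rows, index=index, columns=names)
    else:
        rng = np.random.default_rng(seed)
        rows, index = [], []
        for p in system.psus:
            child = int(rng.integers(0, 2**31 - 1))
            try:
                if sampling == "average":
                    vec = extract_zonal_average(p, stack)
                else:
                    vec = extract_random_point(p, stack, seed=child)
            except ValueError:
                continue
            index.append(p.id)
            rows.append([vec[n] for n in names])
        df = pd.DataFrame(rows, index=index, columns=names)

    df.index.name = "psu_id"
    df.attrs["sampling"] = sampling
    return df
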