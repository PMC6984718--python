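"""Random-forest downscaling model and the replicate bootstrap.

The disaggregation step follows the Gridded Livestock of the World
recipe: a random-forest regression of per-PSU log10 densities on
per-PSU predictor vectors, predicted back onto every suitable pixel of
the analysis grid.  Defaults follow the standard parameterisation:
500 trees and mtry = floor(sqrt(p)) variables per split.  Model
stability is assessed with repeated 70/30 train/evaluation splits
(20 replicates by default); mean and standard-deviation maps summarise
the replicate predictions pixel-wise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import RandomForestRegressor
from sklearn.utils.validation import check_is_fitted, validate_data

from .census import PSURecord
from .grid import GridSpec, PredictorStack


@dataclass(frozen=True)
class ModelConfig:
    """Knobs of the downscaling model and its replicate design."""

    n_trees: int = 500
    mtry_rule: str = "sqrt"
    train_fraction: float = 0.70
    n_replicates: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.mtry_rule != "sqrt":
            raise ValueError("only the sqrt mtry rule is supported")


class DownscaleForest(RegressorMixin, BaseEstimator):
    """Random-forest regressor for census downscaling.

    A thin scikit-learn estimator around :class:`RandomForestRegressor`
    with the downscaling defaults baked in (500 trees, mtry =
    floor(sqrt(p))) and an optional categorical stratum: when
    ``stratum`` labels are passed to :meth:`fit`, one forest is fitted
    per stratum and predictions are mosaicked by stratum, mirroring the
    stratified variant of the global livestock models.  The default is
    a single stratum covering the whole region.

    Parameters
    ----------
    n_trees : int
        Number of trees in each forest.
    random_state : int or None
        Seed for the forest's internal randomness.

    Attributes
    ----------
    forests_ : dict
        Fitted forest per stratum label (``None`` key = single stratum).
    feature_names_ : list of str
        Layer names seen during fit, in training column order.
    y_min_, y_max_ : float
        Training response range; pixel predictions (means of training
        leaves) always fall inside it.
    """

    def __init__(self, n_trees: int = 500, random_state: int | None = None):
        self.n_trees = n_trees
        self.random_state = random_state

    def fit(self, X, y, stratum=None):
        if isinstance(X, pd.DataFrame):
            self.feature_names_ = list(X.columns)
            X = X.to_numpy()
        X, y = validate_data(self, X, y, ensure_min_samples=2)
        if not hasattr(self, "feature_names_"):
            self.feature_names_ = [f"x{k}" for k in range(X.shape[1])]
        strata = np.asarray(stratum) if stratum is not None else np.zeros(len(y))
        self.forests_ = {}
        for lab in np.unique(strata):
            sel = strata == lab
            rf = RandomForestRegressor(
                n_estimators=self.n_trees,
                max_features="sqrt",
                random_state=self.random_state,
                n_jobs=1,
            )
            rf.fit(X[sel], y[sel])
            self.forests_[lab] = rf
        self.y_min_ = float(np.min(y))
        self.y_max_ = float(np.max(y))
        return self

    def predict(self, X, stratum=None):
        check_is_fitted(self)
        if isinstance(X, pd.DataFrame):
            X = X.to_numpy()
        X = validate_data(self, X, reset=False)
        if stratum is None:
            if len(self.forests_) != 1:
                raise ValueError("fitted with strata; pass stratum to predict")
            return next(iter(self.forests_.values())).predict(X)
        strata = np.asarray(stratum)
        out = np.empty(len(X))
        for lab, rf in self.forests_.items():
            sel = strata == lab
            if sel.any():
                out[sel] = rf.predict(X[sel])
        return out


@dataclass
class ReplicateResult:
    """One train/evaluation replicate: the split, the fitted model and
    its prediction raster; metric rows are attached by the evaluation."""

    replicate_id: int
    train_ids: tuple[str, ...]
    eval_ids: tuple[str, ...]
    model: DownscaleForest
    prediction: np.ndarray
    metrics: pd.DataFrame | None = None


@dataclass
class SummaryMaps:
    """Pixel-wise mean and standard deviation over replicate predictions."""

    mean_map: np.ndarray
    sd_map: np.ndarray
    spec: GridSpec


def split_train_eval(psu_ids, train_fraction: float,
                     seed: int) -> tuple[list[str], list[str]]:
    """Simple random train/eval split of PSU ids, seeded.

    Train size is ``round(train_fraction * n)``; both sides must be
    non-empty.  Input order does not matter: ids are sorted before the
    seeded permutation, so the split depends only on the id set.
    """
    ids = sorted(psu_ids)
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 PSUs to split")
    n_train = int(round(train_fraction * n))
    if n_train < 1 or n_train >= n:
        raise ValueError(
            f"train_fraction {train_fraction} leaves an empty side for n={n}"
        )
    perm = np.random.default_rng(seed).permutation(n)
    train = sorted(ids[k] for k in perm[:n_train])
    evaln = sorted(ids[k] for k in perm[n_train:])
    return train, evaln


def fit_model(features: pd.DataFrame, response: list[PSURecord],
              config: ModelConfig, seed: int) -> DownscaleForest:
    """Fit the forest on aligned feature/response tables.

    ``features`` is indexed by psu_id; ``response`` must cover exactly
    the same ids (orphans on either side are an error).  At least five
    training rows are required for the fit to be meaningful.
    """
    resp = {r.psu_id: r.log_density for r in response}
    f_ids, r_ids = set(features.index), set(resp)
    if f_ids != r_ids:
        orphans = sorted(f_ids ^ r_ids)
        raise KeyError(f"feature/response key mismatch: {orphans[:10]}")
    if len(resp) < 5:
        raise ValueError(f"need >= 5 training rows, got {len(resp)}")
    X = features.sort_index()
    y = np.array([resp[i] for i in X.index])
    return DownscaleForest(n_trees=config.n_trees, random_state=seed).fit(X, y)


def predict_raster(model: DownscaleForest, stack: PredictorStack) -> np.ndarray:
    """Predicted log10 density at every suitable pixel; NaN elsewhere."""
    check_is_fitted(model)
    if list(model.feature_names_) != stack.layer_names:
        raise ValueError(
            f"model was trained on layers {model.feature_names_}, "
            f"stack provides {stack.layer_names}"
        )
    X = stack.suitable_matrix()
    out = np.full(stack.spec.shape, np.nan)
    if len(X):
        out[stack.mask] = model.predict(X)
    return out


def run_replicates(features: pd.DataFrame, response: list[PSURecord],
                   stack: PredictorStack, config: ModelConfig
                   ) -> tuple[list[ReplicateResult], SummaryMaps]:
    """Run ``config.n_replicates`` split→fit→predict cycles.

    Replicate ``r`` derives its seed as ``config.seed + r``, making the
    whole set reproducible while keeping splits independent.  The
    summary maps are the pixel-wise mean and population standard
    deviation across the replicate prediction rasters.
    """
    records = {r.psu_id: r for r in response}
    results: list[ReplicateResult] = []
    stackmat = stack.suitable_matrix()
    for r in range(config.n_replicates):
        rep_seed = config.seed + r
        train, evaln = split_train_eval(records, config.train_fraction, rep_seed)
        model = fit_model(
            features.loc[sorted(train)],
            [records[i] for i in train],
            config,
            seed=rep_seed,
        )
        pred = np.full(stack.spec.shape, np.nan)
        if len(stackmat):
            pred[stack.mask] = model.predict(stackmat)
        results.append(
            ReplicateResult(
                replicate_id=r,
                train_ids=tuple(train),
                eval_ids=tuple(evaln),
                model=model,
                prediction=pred,
            )
        )
    cube = np.stack([res.prediction for res in results])
    maps = SummaryMaps(
        mean_map=np.mean(cube, axis=0),
        sd_map=np.std(cube, axis=0),
        spec=stack.spec,
    )
    return results, maps


def rescale_to_totals(prediction: np.ndarray, stack: PredictorStack,
                      labels: np.ndarray, psu_counts: dict[str, int],
                      psu_order: list[str], offset: float) -> np.ndarray:
    """Optional dasymetric rebalancing of pixel predictions to PSU totals.

    Converts the log-density raster to linear head counts per pixel,
    rescales within each PSU so pixel sums match the observed PSU count,
    and returns the adjusted log raster.  Off by default in the
    pipeline: the sensitivity analysis evaluates raw predicted
    densities.
    """
    lin = np.where(np.isfinite(prediction),
                   np.maximum(10.0 ** prediction - offset, 0.0), 0.0)
    heads = lin * stack.spec.cell_area()
    out = prediction.copy()
    for k, pid in enumerate(psu_order):
        sel = labels == k
        s = heads[sel].sum()
        if s > 0:
            factor = psu_counts.get(pid, 0) / s
            out[sel] = np.log10(lin[sel] * factor + offset)
    return out


def mtry(n_features: int) -> int:
    """Variables tried per split: floor of the square root of p."""
    return max(1, int(math.floor(math.sqrt(n_features))))
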