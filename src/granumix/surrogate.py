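"""Surrogate models mapping the 9 descriptors to the forecast mixing time.

Four regressor families — random forest (rf), RBF support-vector regression
(svr), partial least squares (plsr) and elastic net (elastic_net) — are
evaluated by leave-one-out cross-validation with hyperparameter grid search
nested inside each training fold, and R^2 is computed on the pooled
out-of-fold predictions (1 - SSE/SST; may be negative).  Descriptor
importance for the random forest is the percent increase in out-of-fold
mean-squared error after permuting one descriptor column.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import ElasticNet
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .forecast import EndpointEstimate
from .params import DESCRIPTOR_NAMES, MaterialProcessParams

logger = logging.getLogger(__name__)

__all__ = ["FeatureTable", "MethodResult", "SurrogateReport",
           "assemble_table", "fit_and_crossvalidate",
           "permutation_importance", "default_method_spec"]

RESPONSE_COL = "t_end_s"
ALL_METHODS = ("rf", "svr", "plsr", "elastic_net")


@dataclass
class FeatureTable:
    """Rows of 9 descriptors + mixing-time response + provenance tag."""

    frame: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in (*DESCRIPTOR_NAMES, RESPONSE_COL)
                   if c not in self.frame.columns]
        if missing:
            raise ValueError(f"feature table missing columns: {missing}")
        if self.frame[RESPONSE_COL].isna().any():
            raise ValueError("feature table has missing responses")
        if "provenance" not in self.frame.columns:
            self.frame["provenance"] = "unknown"

    @classmethod
    def from_frame(cls, df: pd.DataFrame, metadata: dict | None = None,
                   ) -> "FeatureTable":
        return cls(df.reset_index(drop=True), metadata or {})

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    @property
    def X(self) -> np.ndarray:
        return self.frame[list(DESCRIPTOR_NAMES)].to_numpy(float)

    @property
    def y(self) -> np.ndarray:
        return self.frame[RESPONSE_COL].to_numpy(float)

    def design_summary(self) -> pd.DataFrame:
        """Per-descriptor min/mean/max, the violin-diagnostic numbers."""
        d = self.frame[list(DESCRIPTOR_NAMES)]
        return pd.DataFrame({"min": d.min(), "mean": d.mean(), "max": d.max()})

    def zero_variance_columns(self) -> list[str]:
        return [c for c in DESCRIPTOR_NAMES
                if float(self.frame[c].std()) == 0.0]

    def write(self, path: str | Path) -> None:
        path = Path(path)
        self.frame.to_csv(path, index=False)
        path.with_suffix(".meta.json").write_text(
            json.dumps(self.metadata, indent=2, default=str))

    @classmethod
    def read(cls, path: str | Path) -> "FeatureTable":
        path = Path(path)
        meta_path = path.with_suffix(".meta.json")
        meta = (json.loads(meta_path.read_text()) if meta_path.exists() else {})
        return cls(pd.read_csv(path), meta)


def assemble_table(run_results: Sequence[tuple[MaterialProcessParams,
                                               EndpointEstimate]],
                   ) -> FeatureTable:
    """One row per resolved run; no-crossing runs are excluded and counted.

    Duplicate descriptor sets with differing t_end are kept and flagged as
    replicate noise; all-constant descriptor columns trigger a warning
    naming the column.
    """
    rows, excluded = [], 0
    for params, est in run_results:
        if est.t_end is None or est.no_crossing:
            excluded += 1
            continue
        row = params.as_dict()
        row[RESPONSE_COL] = float(est.t_end)
        row["provenance"] = "dem+arima"
        rows.append(row)
    if excluded:
        logger.info("assemble_table: excluded %d no-crossing runs", excluded)
    df = pd.DataFrame(rows)
    table = FeatureTable.from_frame(df, metadata={
        "n_input_runs": len(run_results), "n_excluded_no_crossing": excluded})
    dup = df.duplicated(subset=list(DESCRIPTOR_NAMES), keep=False)
    if dup.any():
        table.metadata["replicate_rows"] = df.index[dup].tolist()
        logger.warning("duplicate descriptor sets kept as replicate noise "
                       "(rows %s)", df.index[dup].tolist())
    for col in table.zero_variance_columns():
        warnings.warn(f"descriptor column {col!r} has zero variance",
                      UserWarning, stacklevel=2)
    table.metadata["design_summary"] = table.design_summary().to_dict()
    return table


def default_method_spec(seed: int = 0, n_estimators: int = 500,
                        ) -> dict[str, tuple[object, dict]]:
    """(estimator, hyperparameter grid) per method.

    rf sees raw descriptors (trees are scale-free); svr/plsr/elastic_net are
    standardized inside a Pipeline so the grid search never leaks test-fold
    statistics.  Grids are conventional small-data choices.
    """
    return {
        "rf": (RandomForestRegressor(n_estimators=n_estimators, bootstrap=True,
                                     random_state=seed),
               {"max_features": [2, 3, 5, 9], "max_depth": [3, 5, 10, None]}),
        "svr": (Pipeline([("scale", StandardScaler()),
                          ("est", SVR(kernel="rbf"))]),
                {"est__C": [0.1, 1.0, 10.0, 100.0],
                 "est__gamma": ["scale", 0.01, 0.1]}),
        "plsr": (Pipeline([("scale", StandardScaler()),
                           ("est", PLSRegression())]),
                 {"est__n_components": [1, 2, 3, 4, 5]}),
        "elastic_net": (Pipeline([("scale", StandardScaler()),
                                  ("est", ElasticNet(max_iter=50000))]),
                        {"est__l1_ratio": [0.1, 0.5, 0.9],
                         "est__alpha": list(np.logspace(-4, 1, 6))}),
    }


@dataclass
class MethodResult:
    method: str
    loocv_predictions: np.ndarray
    r_squared: float
    chosen_hyperparams: list[dict]
    loocv_verified: bool  # every row predicted by a fold excluding it


@dataclass
class SurrogateReport:
    methods: dict[str, MethodResult]
    n_rows: int
    seed: int
    skipped: dict[str, str] = field(default_factory=dict)
    importances: pd.DataFrame | None = None

    def best_method(self) -> str:
        return max(self.methods, key=lambda m: self.methods[m].r_squared)

    def as_dict(self) -> dict:
        out = {"n_rows": self.n_rows, "seed": self.seed,
               "skipped": self.skipped, "methods": {}}
        for name, res in self.methods.items():
            out["methods"][name] = {
                "r_squared": res.r_squared,
                "loocv_predictions": res.loocv_predictions.tolist(),
                "chosen_hyperparams": res.chosen_hyperparams,
                "loocv_verified": res.loocv_verified}
        if self.importances is not None:
            out["importances"] = self.importances.to_dict()
        return out


def _pooled_r2(y: np.ndarray, pred: np.ndarray) -> float:
    sst = float(np.sum((y - y.mean()) ** 2))
    sse = float(np.sum((y - pred) ** 2))
    return 1.0 - sse / sst if sst > 0 else np.nan


def fit_and_crossvalidate(table: FeatureTable,
                          methods: Sequence[str] = ALL_METHODS,
                          seed: int = 0, inner_cv: int = 3,
                          method_spec: dict | None = None,
                          n_estimators: int = 500) -> SurrogateReport:
    """LOOCV evaluation of each method with fold-nested grid search.

    For every left-out row the hyperparameters are re-tuned by
    ``inner_cv``-fold grid search on the remaining rows only; R^2 is pooled
    over the out-of-fold predictions.  Single-point grids skip the inner
    search.  Methods facing a degenerate (constant-response) training fold
    are skipped with a reason.
    """
    if table.n_rows < 10:
        raise ValueError("need at least 10 rows for LOOCV surrogate fitting")
    X, y = table.X, table.y
    spec = method_spec or default_method_spec(seed, n_estimators)
    unknown = [m for m in methods if m not in spec]
    if unknown:
        raise ValueError(f"unknown methods: {unknown}")
    n = table.n_rows
    report = SurrogateReport(methods={}, n_rows=n, seed=seed)
    for name in methods:
        est, grid = spec[name]
        if float(np.std(y)) == 0.0:
            report.skipped[name] = "constant response"
            continue
        preds = np.empty(n)
        chosen: list[dict] = []
        verified = True
        n_combos = int(np.prod([len(v) for v in grid.values()])) if grid else 1
        for i in range(n):
            train = np.delete(np.arange(n), i)
            verified &= i not in train
            Xtr, ytr = X[train], y[train]
            if n_combos > 1:
                search = GridSearchCV(
                    clone(est), grid, cv=inner_cv,
                    scoring="neg_mean_squared_error", n_jobs=1)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    search.fit(Xtr, ytr)
                model = search.best_estimator_
                chosen.append(dict(search.best_params_))
            else:
                model = clone(est)
                params = {k: v[0] for k, v in grid.items()}
                model.set_params(**params)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model.fit(Xtr, ytr)
                chosen.append(params)
            preds[i] = float(np.ravel(model.predict(X[i:i + 1]))[0])
        report.methods[name] = MethodResult(
            method=name, loocv_predictions=preds,
            r_squared=_pooled_r2(y, preds),
            chosen_hyperparams=chosen, loocv_verified=verified)
        logger.info("surrogate %s: pooled LOOCV R^2 = %.3f", name,
                    report.methods[name].r_squared)
    return report


def permutation_importance(table: FeatureTable,
                           fitted_rf: RandomForestRegressor | None = None,
                           n_permutations: int = 20, seed: int = 0,
                           n_folds: int = 5) -> pd.DataFrame:
    """Percent increase in out-of-fold MSE from permuting each descriptor.

    The table is split into ``n_folds`` folds; per fold a forest (cloning
    ``fitted_rf``'s hyperparameters when given) is fit on the training part
    and each descriptor column of the held-out part is permuted
    ``n_permutations`` times.  Returns a frame indexed by descriptor with
    ``importance_pct`` (mean percent MSE increase), ``sd_pct`` (spread over
    permutation replicates) and ``rank`` (1 = most important).  Zero-variance
    descriptors get importance 0 by definition, flagged in ``zero_variance``.
    """
    if n_permutations < 10:
        raise ValueError("n_permutations must be >= 10")
    rng = np.random.default_rng(seed)
    X, y = table.X, table.y
    n, p = X.shape
    base = (fitted_rf if fitted_rf is not None
            else RandomForestRegressor(n_estimators=300, random_state=seed))
    zero_var = [DESCRIPTOR_NAMES.index(c)
                for c in table.zero_variance_columns()]
    kf = KFold(n_splits=min(n_folds, n), shuffle=True,
               random_state=int(rng.integers(2**31 - 1)))
    base_sq = np.empty(n)
    perm_sq = np.zeros((n_permutations, p, n))
    for train, test in kf.split(X):
        model = clone(base)
        model.set_params(random_state=int(rng.integers(2**31 - 1)))
        model.fit(X[train], y[train])
        base_sq[test] = (y[test] - model.predict(X[test])) ** 2
        # stack every (permutation, descriptor) variant of the held-out
        # block into one predict call
        m = len(test)
        blocks = []
        for r in range(n_permutations):
            for j in range(p):
                Xp = X[test].copy()
                if j not in zero_var:
                    Xp[:, j] = Xp[rng.permutation(m), j]
                blocks.append(Xp)
        preds = model.predict(np.vstack(blocks)).reshape(
            n_permutations, p, m)
        perm_sq[:, :, test] = (y[test][None, None, :] - preds) ** 2
        for j in zero_var:
            perm_sq[:, j, test] = base_sq[test]
    mse0 = float(np.mean(base_sq))
    pct = 100.0 * (perm_sq.mean(axis=2) - mse0) / mse0  # (n_perm, p)
    out = pd.DataFrame({
        "importance_pct": pct.mean(axis=0),
        "sd_pct": pct.std(axis=0, ddof=1),
        "zero_variance": [j in zero_var for j in range(p)],
    }, index=list(DESCRIPTOR_NAMES))
    out.loc[out["zero_variance"], "importance_pct"] = 0.0
    out["rank"] = out["importance_pct"].rank(ascending=False).astype(int)
    return out.sort_values("importance_pct", ascending=False)
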