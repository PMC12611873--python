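"""Conditional abundance model with retransformation bias correction.

A random-forest regression of log abundance on habitat covariates across
presence sites, selected by repeated k-fold cross-validation RMSE, then
post-processed with (i) a regression of observed on estimated log values to
undo the forest's compression of extremes, and (ii) Duan's smearing factor
so the back-transform to ind m^-2 is unbiased without assuming normal
errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import RepeatedKFold

from .occurrence import _check_covariates


@dataclass
class AbundanceModel:
    forest: RandomForestRegressor = field(repr=False)
    feature_names: list[str]
    grid: list[int]
    chosen_max_features: int
    cv_rmse: float                 # log scale, at the chosen grid point
    cv_rmse_by_grid: dict[int, float]
    bias_intercept: float          # a_bc of observed = a_bc + b_bc * predicted
    bias_slope: float              # b_bc
    smearing: float                # Duan smearing factor S
    training_ranges: pd.DataFrame = field(repr=False, default=None)

    def predict_log(self, X: pd.DataFrame) -> np.ndarray:
        """Bias-corrected log-scale prediction (no smearing, no exponent)."""
        X = _check_covariates(self.feature_names, self.training_ranges, X)
        return self.bias_intercept + self.bias_slope * self.forest.predict(X)


def bias_correct(observed_log, predicted_log) -> tuple[float, float]:
    """Least-squares line of observed on predicted log values.

    Machine-learning regressors overpredict low and underpredict high
    values; regressing observed on estimated and applying the fitted line to
    new predictions stretches them back.  Constant predictions return the
    identity line with a warning.
    """
    obs = np.asarray(observed_log, dtype=float)
    pred = np.asarray(predicted_log, dtype=float)
    if obs.shape != pred.shape or obs.size < 3:
        raise ValueError("need >= 3 paired observed/predicted values")
    if np.ptp(pred) == 0:
        warnings.warn("constant predictions; bias line set to identity", stacklevel=2)
        return 0.0, 1.0
    slope, intercept = np.polyfit(pred, obs, 1)
    return float(intercept), float(slope)


def smearing_factor(residuals) -> float:
    """Duan's smearing estimate: mean of exponentiated log-scale residuals.

    With mean-zero residuals S >= 1 by Jensen's inequality; multiplying the
    naive exp back-transform by S removes its downward bias.
    """
    r = np.asarray(residuals, dtype=float)
    if r.size == 0:
        raise ValueError("need at least one residual")
    if not np.all(np.isfinite(r)):
        raise ValueError("non-finite residual")
    return float(np.mean(np.exp(r)))


def fit_abundance(
    data: pd.DataFrame,
    feature_names: list[str],
    abundance_col: str = "abundance",
    folds: int = 6,
    repeats: int = 10,
    n_trees: int = 500,
    max_features_grid: list[int] | None = None,
    seed: int = 0,
) -> AbundanceModel:
    """Fit the CV-selected random forest on log abundance at presence sites.

    The grid is over the number of candidate variables per split; the tree
    count is fixed high enough that the error curve has stabilized.  The
    point with the smallest mean validation RMSE (ties to the smaller grid
    value) wins and is refitted on all data with bootstrap resampling, so
    out-of-bag predictions are available for the bias line and the smearing
    residuals -- the correction is estimated on predictions the forest did
    not memorize.
    """
    X = data[list(feature_names)]
    y_raw = data[abundance_col].to_numpy(dtype=float)
    n = len(y_raw)
    if n < folds:
        raise ValueError(f"{n} presence sites is fewer than {folds} folds; reduce folds")
    if np.any(y_raw <= 0):
        raise ValueError("abundances must be > 0 on presence sites (log transform)")
    y = np.log(y_raw)
    grid = max_features_grid or list(range(1, len(feature_names) + 1))

    cv = RepeatedKFold(n_splits=folds, n_repeats=repeats, random_state=seed)
    splits = list(cv.split(X))
    rmse_by_grid: dict[int, float] = {}
    for mf in grid:
        errs = []
        for k, (tr, va) in enumerate(splits):
            rf = RandomForestRegressor(
                n_estimators=n_trees, max_features=mf,
                random_state=seed + 1000 * k, bootstrap=True,
            )
            rf.fit(X.iloc[tr], y[tr])
            pred = rf.predict(X.iloc[va])
            errs.append(np.sqrt(np.mean((pred - y[va]) ** 2)))
        rmse_by_grid[mf] = float(np.mean(errs))
    chosen = min(grid, key=lambda mf: (rmse_by_grid[mf], mf))

    forest = RandomForestRegressor(
        n_estimators=n_trees, max_features=chosen,
        random_state=seed, bootstrap=True, oob_score=True,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tiny n can leave a few rows without OOB trees
        forest.fit(X, y)
    oob = forest.oob_prediction_
    ok = np.isfinite(oob)  # rows never left out of any bootstrap have no OOB value
    a_bc, b_bc = bias_correct(y[ok], oob[ok])
    resid = y[ok] - (a_bc + b_bc * oob[ok])
    s = smearing_factor(resid)

    return AbundanceModel(
        forest=forest, feature_names=list(feature_names), grid=grid,
        chosen_max_features=chosen, cv_rmse=rmse_by_grid[chosen],
        cv_rmse_by_grid=rmse_by_grid, bias_intercept=a_bc, bias_slope=b_bc,
        smearing=s, training_ranges=pd.DataFrame({"min": X.min(), "max": X.max()}),
    )


def predict_abundance(model: AbundanceModel, covariates: pd.DataFrame) -> np.ndarray:
    """Predicted abundance in ind m^-2: exp(bias-corrected log) x smearing.

    Strictly positive by construction.
    """
    return np.exp(model.predict_log(covariates)) * model.smearing
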