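"""Environmental predictor preparation.

Depth attenuation of wave exposure, the sheltered-marina exposure
substitution rule, and an advisory collinearity screen (pairwise Pearson r
and variance inflation factors).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.outliers_influence import variance_inflation_factor
from statsmodels.tools import add_constant


@dataclass
class CovariateConfig:
    #: Exposures above this (same dimensionless index as the input layer) are
    #: treated as breakwater-misestimated and replaced by the sheltered mean.
    exposure_substitution_threshold: float = 10_000.0
    #: Exponential attenuation rate per metre of depth.  The published
    #: attenuation formula is an external choice; the default here is a
    #: plain e-folding over 1 m, overridable.
    attenuation_k: float = 1.0
    pearson_threshold: float = 0.70
    vif_threshold: float = 5.0

    def validate(self) -> None:
        for name in ("exposure_substitution_threshold", "attenuation_k",
                     "pearson_threshold", "vif_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class ScreenReport:
    """Advisory collinearity report: nothing is dropped automatically."""

    pearson: pd.DataFrame
    vif: pd.Series
    flagged_pairs: list[tuple[str, str, float]]
    flagged_variables: list[str]
    kept: list[str]
    recommended_drop: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({
            "pearson": self.pearson.round(6).to_dict(),
            "vif": {k: (None if not np.isfinite(v) else round(float(v), 6))
                    for k, v in self.vif.items()},
            "flagged_pairs": [[a, b, round(float(r), 6)] for a, b, r in self.flagged_pairs],
            "flagged_variables": self.flagged_variables,
            "kept": self.kept,
            "recommended_drop": self.recommended_drop,
        }, indent=2)


def attenuate_exposure(surface_exposure, depth, k: float = 1.0):
    """Attenuate surface wave exposure to depth: E(d) = E0 * exp(-k d).

    Monotonically non-increasing in depth and equal to the surface value at
    depth 0.  Accepts scalars or arrays.
    """
    surface_exposure = np.asarray(surface_exposure, dtype=float)
    depth = np.asarray(depth, dtype=float)
    if np.any(depth < 0):
        raise ValueError("depth must be >= 0")
    if np.any(surface_exposure < 0):
        raise ValueError("surface exposure must be >= 0")
    if k < 0:
        raise ValueError("attenuation coefficient k must be >= 0")
    out = surface_exposure * np.exp(-k * depth)
    return float(out) if out.ndim == 0 else out


def substitute_marina_exposure(marina_exposures, threshold: float = 10_000.0):
    """Replace exposures above the threshold by the mean of those at/below it.

    Marinas enclosed by breakwaters can be assigned unrealistically high
    exposure by a fetch model that ignores the breakwater; those values are
    replaced with the average of the credible (sheltered) marinas.  The
    operation is idempotent and never increases the maximum of the vector.
    """
    values = np.asarray(marina_exposures, dtype=float)
    below = values <= threshold
    if not below.any():
        raise ValueError("no sheltered reference marinas at or below the threshold")
    reference = values[below].mean()
    return np.where(below, values, reference)


def _vif_one(X: np.ndarray, names: list[str], i: int) -> float:
    col = X[:, i]
    if np.ptp(col) == 0:
        return np.inf  # constant column: R^2 of the others on it is undefined
    exog = add_constant(X, has_constant="add")
    return float(variance_inflation_factor(exog, i + 1))


def collinearity_screen(covariates: pd.DataFrame,
                        config: CovariateConfig | None = None) -> ScreenReport:
    """Screen a numeric covariate table for collinearity.

    Flags any pair with |Pearson r| >= pearson_threshold and any variable
    with VIF >= vif_threshold (VIF = 1/(1 - R^2) of that variable regressed
    on all others).  A constant column gets an infinite-VIF sentinel.  The
    report is advisory; ``recommended_drop`` lists variables removed by a
    greedy highest-VIF-first pass until all remaining VIFs pass.
    """
    config = config or CovariateConfig()
    config.validate()
    if len(covariates) < 3:
        raise ValueError("need at least 3 rows to screen covariates")
    num = covariates.select_dtypes(include=[np.number])
    if num.shape[1] < 2:
        raise ValueError("need at least 2 numeric columns to screen")
    names = list(num.columns)
    X = num.to_numpy(dtype=float)

    pearson = num.corr().fillna(0.0)
    np.fill_diagonal(pearson.values, 1.0)
    flagged_pairs = [
        (names[i], names[j], float(pearson.iloc[i, j]))
        for i in range(len(names)) for j in range(i + 1, len(names))
        if abs(pearson.iloc[i, j]) >= config.pearson_threshold
    ]

    vif = pd.Series({names[i]: _vif_one(X, names, i) for i in range(len(names))})
    flagged_vars = [n for n in names if vif[n] >= config.vif_threshold]

    # Greedy advisory drop: worst VIF first, recomputed after each removal.
    keep = list(names)
    dropped: list[str] = []
    while len(keep) > 1:
        sub = num[keep].to_numpy(dtype=float)
        v = pd.Series({keep[i]: _vif_one(sub, keep, i) for i in range(len(keep))})
        worst = v.idxmax()
        if v[worst] < config.vif_threshold:
            break
        keep.remove(worst)
        dropped.append(worst)

    return ScreenReport(
        pearson=pearson, vif=vif, flagged_pairs=flagged_pairs,
        flagged_variables=flagged_vars, kept=keep, recommended_drop=dropped,
    )
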