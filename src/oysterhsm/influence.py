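"""Predictor-influence analysis, identical for occurrence and abundance.

Permutation importance (mean 1 - Pearson r between original and
column-permuted predictions over a few runs), evaluation-strip response
curves (one variable varied over its observed range, the others fixed at
their medians), and two-variable partial dependence (data-averaged
clamping).  All operations take a plain ``predict_fn(DataFrame) -> array``
so both models share one code path.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats


def occurrence_predictor(ensemble):
    """Probability-scale prediction function for an occurrence ensemble."""
    from .occurrence import predict_occurrence

    return lambda X: predict_occurrence(ensemble, X)["probability"].to_numpy()


def abundance_log_predictor(model):
    """Log-scale (bias-corrected) prediction function for an abundance model."""
    return lambda X: model.predict_log(X)


def permutation_importance(
    predict_fn,
    data: pd.DataFrame,
    variables: list[str],
    n_runs: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation importance: mean over runs of 1 - r(original, permuted).

    Each variable is permuted independently with its own seeded draw (runs
    outermost, variables in the given order), the model re-predicted, and
    the Pearson correlation with the original predictions taken.  A variable
    the model ignores leaves predictions unchanged (r = 1, importance 0);
    values range up to 2 when permutation flips the prediction ordering.
    Constant predictions make r undefined; importance is reported as 0 with
    a warning.
    """
    if len(data) < 3:
        raise ValueError("need at least 3 rows")
    rng = np.random.default_rng(seed)
    original = np.asarray(predict_fn(data), dtype=float)
    rows = {v: [] for v in variables}
    for _ in range(n_runs):
        for v in variables:
            permuted = data.copy()
            permuted[v] = rng.permutation(permuted[v].to_numpy())
            pred = np.asarray(predict_fn(permuted), dtype=float)
            if np.ptp(original) == 0 or np.ptp(pred) == 0:
                warnings.warn(
                    f"constant predictions while permuting {v!r}; importance 0",
                    stacklevel=2,
                )
                rows[v].append(0.0)
            else:
                r = stats.pearsonr(original, pred).statistic
                rows[v].append(1.0 - float(r))
    return pd.DataFrame({
        "variable": variables,
        "importance": [float(np.mean(rows[v])) for v in variables],
        "n_runs": n_runs,
    })


def evaluation_strip(
    data: pd.DataFrame,
    variable: str,
    variables: list[str],
    n_points: int = 100,
    value_range: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """The synthetic covariate grid behind a response curve.

    ``variable`` runs over ``n_points`` evenly spaced values spanning its
    observed interval (or an explicit ``value_range``); every other variable
    is held at its observed median.
    """
    lo, hi = value_range if value_range is not None else (
        float(data[variable].min()), float(data[variable].max())
    )
    if not hi > lo:
        raise ValueError(f"variable {variable!r} has a degenerate range")
    grid = np.linspace(lo, hi, n_points)
    strip = pd.DataFrame({v: np.full(n_points, float(data[v].median()))
                          for v in variables})
    strip[variable] = grid
    return strip


def response_curve(
    predict_fn,
    data: pd.DataFrame,
    variable: str,
    variables: list[str],
    n_points: int = 100,
    value_range: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Evaluation-strip response curve: predictions along the strip.

    Occurrence curves are on the probability scale and abundance curves on
    the log scale, set by the ``predict_fn`` passed in.
    """
    strip = evaluation_strip(data, variable, variables, n_points, value_range)
    return pd.DataFrame({
        "variable": variable,
        "value": strip[variable].to_numpy(),
        "response": np.asarray(predict_fn(strip), dtype=float),
    })


def partial_dependence_2d(
    predict_fn,
    data: pd.DataFrame,
    var1: str,
    var2: str,
    variables: list[str],
    grid_n: int = 20,
) -> pd.DataFrame:
    """Two-variable partial dependence surface.

    Both variables are clamped to a grid_n x grid_n lattice over their
    observed ranges; at each lattice point the prediction is averaged over
    the full data with only those two columns replaced.  Unlike the
    evaluation strip, the remaining covariates keep their joint empirical
    distribution.  Returns a long table (var1, var2, effect); pivot for a
    matrix.
    """
    for v in (var1, var2):
        if np.ptp(data[v].to_numpy(dtype=float)) == 0:
            raise ValueError(f"variable {v!r} has a degenerate range")
    g1 = np.linspace(float(data[var1].min()), float(data[var1].max()), grid_n)
    g2 = np.linspace(float(data[var2].min()), float(data[var2].max()), grid_n)
    base = data[list(variables)]
    rows = []
    for a in g1:
        block = base.copy()
        block[var1] = a
        for b in g2:
            block[var2] = b
            rows.append((a, b, float(np.mean(predict_fn(block)))))
    return pd.DataFrame(rows, columns=[var1, var2, "effect"])
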