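"""Gated presence-absence ensemble.

A committee of four learner families (linear logistic, spline logistic,
boosted trees, random forest) is fitted on repeated 80/20 split-samples.
Members passing the AUC >= 0.70 and TSS >= 0.50 validation gates enter the
ensemble, which predicts by unweighted mean probability and classifies with
the sensitivity+specificity-maximizing cutoff found on the calibration set.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import SplineTransformer, StandardScaler

log = logging.getLogger(__name__)

FAMILIES = ("linear-logistic", "spline-logistic", "boosted-trees", "random-forest")


@dataclass
class CommitteeConfig:
    """Documented per-family hyperparameters (sensible defaults, not tuning)."""

    spline_knots: int = 4
    spline_degree: int = 3
    logistic_c: float = 1.0
    gbm_trees: int = 100
    gbm_learning_rate: float = 0.05
    gbm_depth: int = 2
    rf_trees: int = 100
    rf_min_leaf: int = 2


def _make_learner(family: str, cfg: CommitteeConfig, random_state: int):
    if family == "linear-logistic":
        return Pipeline([
            ("scale", StandardScaler()),
            ("glm", LogisticRegression(C=cfg.logistic_c, max_iter=2000)),
        ])
    if family == "spline-logistic":
        return Pipeline([
            ("scale", StandardScaler()),
            ("spline", SplineTransformer(n_knots=cfg.spline_knots, degree=cfg.spline_degree)),
            ("glm", LogisticRegression(C=cfg.logistic_c, max_iter=2000)),
        ])
    if family == "boosted-trees":
        return GradientBoostingClassifier(
            n_estimators=cfg.gbm_trees, learning_rate=cfg.gbm_learning_rate,
            max_depth=cfg.gbm_depth, random_state=random_state,
        )
    if family == "random-forest":
        return RandomForestClassifier(
            n_estimators=cfg.rf_trees, min_samples_leaf=cfg.rf_min_leaf,
            random_state=random_state,
        )
    raise ValueError(f"unknown committee family {family!r}")


def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("both presence and absence labels are required")


def auc(scores, labels) -> float:
    """Area under the ROC curve: the probability that a random presence
    outscores a random absence, counting ties as one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    _check_two_classes(labels)
    return float(roc_auc_score(labels, scores))


def tss(scores, labels, return_threshold: bool = False):
    """Maximized true skill statistic: max over thresholds of sens + spec - 1.

    Candidate thresholds are the midpoints of consecutive sorted unique
    scores, plus the two trivial boundaries (below the minimum: everything
    presence; at the maximum: everything absence), so the optimum is never
    below 0.  A score above the threshold is classified presence.  Ties in
    the maximum are broken toward the threshold nearest 0.5 (larger
    threshold if still tied).  Constant scores give TSS 0 at threshold equal
    to the score.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    _check_two_classes(labels)
    uniq = np.unique(scores)
    if len(uniq) == 1:
        return (0.0, float(uniq[0])) if return_threshold else 0.0
    span = uniq[-1] - uniq[0]
    thresholds = np.concatenate([
        [uniq[0] - 0.5 * span], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1]]])
    pos, neg = labels.sum(), (~labels).sum()
    best_t, best_v = None, -np.inf
    for t in thresholds:
        pred = scores > t
        sens = (pred & labels).sum() / pos
        spec = (~pred & ~labels).sum() / neg
        v = sens + spec - 1.0
        better = v > best_v + 1e-12
        tie = abs(v - best_v) <= 1e-12 and (
            abs(t - 0.5) < abs(best_t - 0.5) - 1e-12
            or (abs(abs(t - 0.5) - abs(best_t - 0.5)) <= 1e-12 and t > best_t)
        )
        if better or tie:
            best_v, best_t = v, float(t)
    return (float(best_v), best_t) if return_threshold else float(best_v)


@dataclass
class CommitteeMember:
    family: str
    split_id: int
    model: object
    validation_auc: float
    validation_tss: float


@dataclass
class Committee:
    members: list[CommitteeMember]
    feature_names: list[str]
    n_attempted: int
    n_skipped: int


@dataclass
class EnsembleModel:
    members: list[CommitteeMember]
    feature_names: list[str]
    auc_min: float
    tss_min: float
    inclusion_fraction: float
    cutoff: float
    calibration_auc: float
    training_ranges: pd.DataFrame = field(repr=False, default=None)


def _proba(model, X: pd.DataFrame) -> np.ndarray:
    return model.predict_proba(X)[:, 1]


def fit_committee(
    data: pd.DataFrame,
    feature_names: list[str],
    label_col: str = "observed_presence",
    families: tuple[str, ...] = FAMILIES,
    n_splits: int = 100,
    train_frac: float = 0.8,
    seed: int = 0,
    committee_config: CommitteeConfig | None = None,
) -> Committee:
    """Fit families x n_splits candidate members on repeated 80/20 splits.

    Each member is calibrated on its training split and scored (AUC, TSS) on
    its holdout.  Splits whose training part contains a single class skip
    that split's members with a logged warning.  Fully deterministic given
    the seed.
    """
    cfg = committee_config or CommitteeConfig()
    X = data[list(feature_names)]
    y = data[label_col].to_numpy().astype(int)
    _check_two_classes(y)
    n_pres = int(y.sum())
    if n_pres < 10 * len(feature_names):
        warnings.warn(
            f"{n_pres} presences for {len(feature_names)} predictors is below "
            "the 1:10 presences-per-predictor rule of thumb", stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    n = len(y)
    n_train = max(1, int(round(train_frac * n)))
    members, skipped = [], 0
    for split_id in range(n_splits):
        perm = rng.permutation(n)
        tr, va = perm[:n_train], perm[n_train:]
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[va])) < 2:
            log.warning("split %d has a single class in train or holdout; skipped", split_id)
            skipped += len(families)
            continue
        member_seed = int(rng.integers(2**31 - 1))
        for family in families:
            model = _make_learner(family, cfg, member_seed)
            model.fit(X.iloc[tr], y[tr])
            p = _proba(model, X.iloc[va])
            members.append(CommitteeMember(
                family=family, split_id=split_id, model=model,
                validation_auc=auc(p, y[va]), validation_tss=tss(p, y[va]),
            ))
    return Committee(members=members, feature_names=list(feature_names),
                     n_attempted=n_splits * len(families), n_skipped=skipped)


def build_ensemble(
    committee: Committee,
    data: pd.DataFrame,
    label_col: str = "observed_presence",
    auc_min: float = 0.70,
    tss_min: float = 0.50,
) -> EnsembleModel:
    """Gate the committee and assemble the unweighted-mean ensemble.

    Members with validation AUC >= auc_min and TSS >= tss_min are included.
    The calibration AUC and the classification cutoff (sens+spec maximizer)
    are computed from ensemble predictions on the full calibration table.
    """
    included = [m for m in committee.members
                if m.validation_auc >= auc_min and m.validation_tss >= tss_min]
    if not included:
        best_auc = max((m.validation_auc for m in committee.members), default=float("nan"))
        best_tss = max((m.validation_tss for m in committee.members), default=float("nan"))
        raise ValueError(
            "empty ensemble: no member passed the gates "
            f"(best AUC={best_auc:.3f}, best TSS={best_tss:.3f})"
        )
    X = data[committee.feature_names]
    y = data[label_col].to_numpy().astype(int)
    probs = np.mean([_proba(m.model, X) for m in included], axis=0)
    _, cutoff = tss(probs, y, return_threshold=True)
    ranges = pd.DataFrame({"min": X.min(), "max": X.max()})
    return EnsembleModel(
        members=included,
        feature_names=committee.feature_names,
        auc_min=auc_min, tss_min=tss_min,
        inclusion_fraction=len(included) / max(committee.n_attempted, 1),
        cutoff=float(cutoff),
        calibration_auc=auc(probs, y),
        training_ranges=ranges,
    )


def _check_covariates(feature_names, ranges, X: pd.DataFrame) -> pd.DataFrame:
    missing = [f for f in feature_names if f not in X.columns]
    if missing:
        raise ValueError(f"missing covariate column(s): {', '.join(missing)}")
    X = X[list(feature_names)]
    if ranges is not None:
        outside = [
            f for f in feature_names
            if (X[f].min() < ranges.loc[f, "min"]) or (X[f].max() > ranges.loc[f, "max"])
        ]
        if outside:
            warnings.warn(
                "covariates outside training range (extrapolation): "
                + ", ".join(outside), stacklevel=3,
            )
    return X


def predict_occurrence(ensemble: EnsembleModel, covariates: pd.DataFrame) -> pd.DataFrame:
    """Ensemble occurrence probability and binary presence at the cutoff.

    A probability exactly equal to the cutoff is classified absent (strict
    inequality).  Warns when covariates extrapolate beyond training ranges.
    """
    X = _check_covariates(ensemble.feature_names, ensemble.training_ranges, covariates)
    probs = np.mean([_proba(m.model, X) for m in ensemble.members], axis=0)
    return pd.DataFrame({
        "probability": probs,
        "presence": probs > ensemble.cutoff,
    }, index=covariates.index)
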