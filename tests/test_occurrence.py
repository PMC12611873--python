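"""AUC/TSS metrics, the split-sample committee, gating and prediction."""

import numpy as np
import pandas as pd
import pytest

from oysterhsm import (auc, build_ensemble, fit_committee, predict_occurrence,
                       tss)
from oysterhsm.occurrence import Committee, CommitteeMember


def _auc_oracle(scores, labels):
    """Brute-force pairwise concordance with half credit for ties."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos, neg = scores[labels], scores[~labels]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def _tss_oracle(scores, labels):
    """Exhaustive search over all real thresholds (unique scores +- eps)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    best = -np.inf
    for t in np.unique(scores):
        for cand in (t - 1e-9, t + 1e-9):
            pred = scores > cand
            sens = (pred & labels).sum() / labels.sum()
            spec = (~pred & ~labels).sum() / (~labels).sum()
            best = max(best, sens + spec - 1)
    return best


class TestAUC:
    def test_hand_example(self):
        assert auc([0.9, 0.4, 0.6, 0.1], [1, 1, 0, 0]) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_constant_scores(self):
        assert auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.2], [1, 1])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_concordance(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 50))
        labels = np.zeros(n, dtype=int)
        labels[: max(1, n // 3)] = 1
        rng.shuffle(labels)
        scores = rng.choice(np.linspace(0, 1, 7), size=n)  # force ties
        assert auc(scores, labels) == pytest.approx(
            _auc_oracle(scores, labels), abs=1e-12)


class TestTSS:
    def test_perfect_separation(self):
        assert tss([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_constant_scores(self):
        assert tss([0.3] * 5, [1, 1, 0, 0, 0]) == 0.0

    def test_hand_example(self):
        value, threshold = tss([0.9, 0.4, 0.6, 0.1], [1, 1, 0, 0],
                               return_threshold=True)
        assert value == pytest.approx(0.5)
        assert threshold in (0.25, 0.75)  # both attain the max

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_threshold_search(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(4, 40))
        labels = np.zeros(n, dtype=int)
        labels[: max(1, n // 2)] = 1
        rng.shuffle(labels)
        scores = rng.random(n).round(1)
        assert tss(scores, labels) == pytest.approx(
            _tss_oracle(scores, labels), abs=1e-9)


def _separable_table(n=40, seed=0):
    rng = np.random.default_rng(seed)
    x = np.concatenate([rng.uniform(0, 0.3, n // 2), rng.uniform(0.7, 1, n // 2)])
    return pd.DataFrame({
        "x": x,
        "noise": rng.normal(size=n),
        "observed_presence": (x > 0.5).astype(int),
    })


class TestCommittee:
    def test_separable_data_all_members_perfect(self):
        data = _separable_table()
        committee = fit_committee(data, ["x", "noise"], n_splits=5, seed=1,
                                  families=("linear-logistic", "random-forest"))
        assert all(m.validation_auc == 1.0 for m in committee.members)

    def test_shuffled_labels_auc_near_half(self):
        """Labels independent of covariates: mean holdout AUC ~ 0.5.

        Averaged over independent label shuffles (a single shuffled dataset
        carries its own noise pattern, so the mean over splits alone is not
        centred on 0.5); the SE is taken across shuffle means.
        """
        rng = np.random.default_rng(2)
        shuffle_means = []
        for i in range(12):
            data = _separable_table(n=60, seed=2)
            data["observed_presence"] = rng.permutation(
                data["observed_presence"].to_numpy())
            committee = fit_committee(data, ["x", "noise"], n_splits=10,
                                      seed=3 + i, families=("linear-logistic",))
            shuffle_means.append(
                np.mean([m.validation_auc for m in committee.members]))
        se = np.std(shuffle_means) / np.sqrt(len(shuffle_means))
        assert abs(np.mean(shuffle_means) - 0.5) < 3 * max(se, 0.02)

    def test_deterministic_given_seed(self):
        data = _separable_table()
        a = fit_committee(data, ["x"], n_splits=4, seed=5,
                          families=("linear-logistic",))
        b = fit_committee(data, ["x"], n_splits=4, seed=5,
                          families=("linear-logistic",))
        assert [(m.validation_auc, m.validation_tss) for m in a.members] == \
               [(m.validation_auc, m.validation_tss) for m in b.members]

    def test_few_presences_warns(self):
        data = _separable_table(n=30)
        with pytest.warns(UserWarning, match="rule of thumb"):
            fit_committee(data, ["x", "noise"], n_splits=2, seed=1,
                          families=("linear-logistic",))


class _StubModel:
    def __init__(self, probs):
        self.probs = np.asarray(probs, float)

    def predict_proba(self, X):
        p = self.probs[: len(X)]
        return np.column_stack([1 - p, p])


def _stub_committee(prob_sets, aucs=None, tsss=None, features=("x",)):
    members = [
        CommitteeMember("linear-logistic", i, _StubModel(p),
                        1.0 if aucs is None else aucs[i],
                        1.0 if tsss is None else tsss[i])
        for i, p in enumerate(prob_sets)
    ]
    return Committee(members=members, feature_names=list(features),
                     n_attempted=len(members), n_skipped=0)


def _calib(n=6):
    return pd.DataFrame({"x": np.linspace(0, 1, n),
                         "observed_presence": [0, 0, 0, 1, 1, 1][:n]})


class TestEnsemble:
    def test_single_member_ensemble_is_that_member(self):
        p = [0.1, 0.2, 0.3, 0.7, 0.8, 0.9]
        ens = build_ensemble(_stub_committee([p]), _calib())
        out = predict_occurrence(ens, _calib())
        assert np.allclose(out["probability"], p)

    def test_two_members_average_pointwise(self):
        p = np.array([0.1, 0.2, 0.3, 0.7, 0.8, 0.9])
        q = np.array([0.3, 0.1, 0.5, 0.9, 0.6, 0.7])
        ens = build_ensemble(_stub_committee([p, q]), _calib())
        out = predict_occurrence(ens, _calib())
        assert np.allclose(out["probability"], (p + q) / 2)

    def test_ensemble_bounded_by_members(self):
        p = np.array([0.1, 0.2, 0.3, 0.7, 0.8, 0.9])
        q = np.array([0.3, 0.1, 0.5, 0.9, 0.6, 0.7])
        ens = build_ensemble(_stub_committee([p, q]), _calib())
        probs = predict_occurrence(ens, _calib())["probability"].to_numpy()
        assert (probs >= np.minimum(p, q) - 1e-12).all()
        assert (probs <= np.maximum(p, q) + 1e-12).all()

    def test_gates_monotone_in_strictness(self):
        aucs = [0.6, 0.75, 0.9]
        tsss = [0.3, 0.55, 0.8]
        p = [0.1, 0.2, 0.3, 0.7, 0.8, 0.9]
        committee = _stub_committee([p, p, p], aucs=aucs, tsss=tsss)
        loose = build_ensemble(committee, _calib(), auc_min=0.0, tss_min=-1.0)
        strict = build_ensemble(committee, _calib(), auc_min=0.7, tss_min=0.5)
        assert len(strict.members) <= len(loose.members)
        assert len(strict.members) == 2

    def test_empty_ensemble_reports_best_metrics(self):
        committee = _stub_committee([[0.5] * 6], aucs=[0.6], tsss=[0.2])
        with pytest.raises(ValueError, match="best AUC=0.600"):
            build_ensemble(committee, _calib(), auc_min=0.9, tss_min=0.9)

    def test_boundary_probability_is_absence(self):
        p = [0.1, 0.2, 0.3, 0.7, 0.8, 0.9]
        ens = build_ensemble(_stub_committee([p]), _calib())
        ens.cutoff = 0.7
        out = predict_occurrence(ens, _calib())
        assert not out["presence"].iloc[3]  # probability == cutoff -> absent
        assert out["presence"].iloc[4]

    def test_missing_covariate_named(self):
        ens = build_ensemble(_stub_committee([[0.1, 0.2, 0.3, 0.7, 0.8, 0.9]]),
                             _calib())
        with pytest.raises(ValueError, match="x"):
            predict_occurrence(ens, pd.DataFrame({"y": [1.0]}))

    def test_extrapolation_warns(self):
        ens = build_ensemble(_stub_committee([[0.1, 0.2, 0.3, 0.7, 0.8, 0.9]]),
                             _calib())
        with pytest.warns(UserWarning, match="extrapolation"):
            predict_occurrence(ens, pd.DataFrame({"x": [5.0, 0.1, 0.2, 0.3, 0.4, 0.5]}))


def test_fitted_probability_monotone_in_substrate(first_quadrats):
    """Substrate-driven truth: ensemble response rises with substrate cover."""
    from oysterhsm import PREDICTORS, response_curve
    from oysterhsm.influence import occurrence_predictor

    committee = fit_committee(first_quadrats, PREDICTORS, n_splits=10, seed=4)
    ens = build_ensemble(committee, first_quadrats)
    curve = response_curve(occurrence_predictor(ens), first_quadrats,
                           "substrate_cover", PREDICTORS, n_points=25)
    smoothed = curve["response"].rolling(5, center=True, min_periods=1).mean()
    assert smoothed.iloc[-1] > smoothed.iloc[0] + 0.2
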