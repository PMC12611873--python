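"""Fit the gated presence-absence ensemble and inspect its quality.

Four learner families x repeated 80/20 splits; members with holdout
AUC >= 0.70 and TSS >= 0.50 enter the ensemble, which classifies with the
sensitivity+specificity-maximizing cutoff.
"""

import warnings

from oysterhsm import (GeneratorConfig, PREDICTORS, build_ensemble,
                       fit_committee, generate_survey, predict_occurrence)
from oysterhsm.field_summary import first_quadrat_table

cfg = GeneratorConfig(seed=1)
sites, quadrats = generate_survey(cfg)
fq = first_quadrat_table(sites, quadrats)

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    committee = fit_committee(fq, PREDICTORS, n_splits=30, seed=2)
    ensemble = build_ensemble(committee, fq)

print(f"candidate members: {committee.n_attempted} "
      f"(skipped {committee.n_skipped} degenerate splits)")
print(f"included after AUC>=0.70 / TSS>=0.50 gates: {len(ensemble.members)} "
      f"({100 * ensemble.inclusion_fraction:.0f}%)")
print(f"calibration AUC: {ensemble.calibration_auc:.3f}")
print(f"probability cutoff: {ensemble.cutoff:.2f}")

pred = predict_occurrence(ensemble, fq)
obs = fq["observed_presence"].to_numpy()
sens = (pred["presence"] & obs).sum() / obs.sum()
spec = (~pred["presence"] & ~obs).sum() / (~obs).sum()
print(f"sensitivity {sens:.2f}, specificity {spec:.2f} at the cutoff")
print("\nA high calibration AUC with balanced sensitivity/specificity means"
      "\nthe committee separates occupied from empty sites almost perfectly"
      "\non this strongly substrate-driven synthetic truth.")
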