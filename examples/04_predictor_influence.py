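"""Which predictor drives occurrence, and which drives abundance?

Permutation importance (1 - Pearson r between original and permuted-column
predictions), evaluation-strip response curves, and a 2-D partial
dependence check for interactions.
"""

import warnings

from oysterhsm import (GeneratorConfig, PREDICTORS, build_ensemble,
                       fit_abundance, fit_committee, generate_survey,
                       partial_dependence_2d, permutation_importance,
                       response_curve)
from oysterhsm.field_summary import first_quadrat_table, site_abundance_table
from oysterhsm.influence import abundance_log_predictor, occurrence_predictor

cfg = GeneratorConfig(seed=1)
sites, quadrats = generate_survey(cfg)
fq = first_quadrat_table(sites, quadrats)
table = site_abundance_table(sites, quadrats, cfg.quadrat_area)
pres = table[table["observed_presence"]].copy()
pres["substrate_cover"] = pres["mean_substrate"]

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    ens = build_ensemble(fit_committee(fq, PREDICTORS, n_splits=20, seed=4), fq)
    model = fit_abundance(pres, PREDICTORS, folds=6, repeats=2, seed=5)

    occ_f, abn_f = occurrence_predictor(ens), abundance_log_predictor(model)
    print("occurrence importance (1 - r):")
    print(permutation_importance(occ_f, fq, PREDICTORS, seed=6)
          .round(3).to_string(index=False))
    print("\nabundance importance (1 - r):")
    print(permutation_importance(abn_f, pres, PREDICTORS, seed=7)
          .round(3).to_string(index=False))

    sal = response_curve(abn_f, pres, "min_salinity", PREDICTORS,
                         n_points=9, value_range=(6.0, 12.0))
    print("\nabundance response to minimum salinity (log scale):")
    print(sal.round(2).to_string(index=False))

    pd2 = partial_dependence_2d(abn_f, pres, "exposure", "min_salinity",
                                PREDICTORS, grid_n=5)
print(f"\npartial-dependence surface spans "
      f"{pd2['effect'].min():.2f} .. {pd2['effect'].max():.2f} log units")
print("\nSubstrate dominates occurrence while wave exposure dominates"
      "\nabundance - the occurrence/abundance dichotomy the hurdle design"
      "\nexists to capture; the salinity strip falls below ~8 psu.")
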