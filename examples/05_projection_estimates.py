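"""Project both models onto marinas and natural shoreline sites and turn
them into possible population sizes, biomass and per-unit-area risk.

Nh = x̄h * Ph * Ah per habitat stratum, with percentile-bootstrap CIs from
resampling projection sites.
"""

import warnings

from oysterhsm import PipelineConfig, per_unit_area, run_pipeline
from oysterhsm.projection import estimates_table

cfg = PipelineConfig(seed=1, n_splits=30, cv_repeats=2, n_boot=500)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    result = run_pipeline(cfg)

print(estimates_table(result.estimates).round(2).to_string(index=False))

by_name = {e.habitat: e for e in result.estimates}
ratios = per_unit_area(by_name["marina"], by_name["natural_overall"])
print(f"\nmarina : natural abundance per unit of total habitat = "
      f"{ratios['abundance_ratio']:.1f}x")
print(f"marina : natural biomass per unit of total habitat   = "
      f"{ratios['biomass_ratio']:.1f}x")
print("\nMarinas hold little area, so their total possible population is"
      "\nsmall - but per square metre of available habitat they are by far"
      "\nthe riskiest habitat, which is what targeted monitoring should use.")
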