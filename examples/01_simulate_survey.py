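"""Generate a synthetic invasion-front survey and summarize what was observed.

45 sites in three habitat types (15 each) along a north-south salinity
gradient, five 0.25 m^2 quadrats per site with a targeted first quadrat.
"""

from oysterhsm import GeneratorConfig, generate_survey, habitat_comparison
from oysterhsm.field_summary import site_abundance_table

cfg = GeneratorConfig(seed=1)
sites, quadrats = generate_survey(cfg)
table = site_abundance_table(sites, quadrats, cfg.quadrat_area)
present = table[table["observed_presence"]]

print(f"{len(sites)} sites, {len(quadrats)} quadrats, "
      f"{len(present)} sites with the species present")
print("\nObserved mean abundance over presence sites (ind/m^2):")
print(present.groupby("habitat")["abundance"].mean().round(1).to_string())

comp = habitat_comparison(present)
print(f"\nANOVA on log abundance: F({comp.df_between},{comp.df_within}) "
      f"= {comp.f_statistic:.1f}, p = {comp.p_value:.3f}")
print("Tukey HSD pairwise p-values:")
print(comp.tukey.round(3).to_string(index=False))
print("\nMarinas combine full hard-substrate cover with strong wave shelter,"
      "\nso they support several-fold higher densities than piers or rock.")
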