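"""Calibration of the synthetic generator's default truth coefficients.

Runs the generator over many seeds and reports, per habitat, the mean
observed abundance over presence sites (the statistic a field survey would
report), the presence counts, and how often site minimum salinity falls
below the 8-psu breakpoint.  The anchor values are roughly 10.4 / 3.3 /
2.8 ind m^-2 for marinas / piers / natural rock.  Defaults in
``oysterhsm.synth`` were frozen from this script's output; rerun after
changing any truth coefficient.

Usage: python scripts/calibrate_generator.py [n_seeds]
"""

import sys

import numpy as np

from oysterhsm import GeneratorConfig, generate_survey
from oysterhsm.field_summary import site_abundance_table


def summarize(n_seeds: int = 30) -> dict:
    means = {h: [] for h in ("marina", "pier", "natural_rocky")}
    presences, below_bp, presence_below_bp = [], [], []
    for seed in range(n_seeds):
        cfg = GeneratorConfig(seed=seed)
        sites, quadrats = generate_survey(cfg)
        table = site_abundance_table(sites, quadrats, cfg.quadrat_area)
        present = table[table["observed_presence"]]
        for h in means:
            vals = present.loc[present["habitat"] == h, "abundance"]
            if len(vals):
                means[h].append(vals.mean())
        presences.append(len(present))
        below_bp.append(int((sites["min_salinity"] < cfg.salinity_breakpoint).sum()))
        presence_below_bp.append(int(
            (present["min_salinity"] < cfg.salinity_breakpoint).sum()))
    return {
        "habitat_means": {h: float(np.mean(v)) for h, v in means.items()},
        "habitat_mean_sd": {h: float(np.std(v)) for h, v in means.items()},
        "mean_presences": float(np.mean(presences)),
        "mean_sites_below_breakpoint": float(np.mean(below_bp)),
        "mean_presences_below_breakpoint": float(np.mean(presence_below_bp)),
    }


if __name__ == "__main__":
    n = int(sys.argv[1]) if len(sys.argv) > 1 else 30
    out = summarize(n)
    print(f"over {n} seeds (anchors: marina 10.4, pier 3.3, natural 2.8 ind/m^2):")
    for k, v in out.items():
        print(f"  {k}: {v}")
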