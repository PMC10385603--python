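"""Synthetic ex vivo biodistribution: generate, summarize, compare groups.

Generates seeded healthy and tumour-bearing cohorts from the default
parameter table, converts counter cpm back to decay-corrected %ID/g, prints
the summary for a few organs, and runs a Welch t-test on 24 h liver uptake
between the two groups.
"""

import numpy as np

from theradose import (cu64, default_config, gen_biodistribution,
                       percent_id_per_gram, summarize, welch_t_test)

nuclide = cu64()
config = default_config(seed=0)

healthy = gen_biodistribution(config, seed=0, group="healthy", nuclide=nuclide)
tumour = gen_biodistribution(config, seed=0, group="tumour_bearing", nuclide=nuclide)

summary = summarize(healthy + tumour, nuclide)
show = summary[(summary["organ"].isin(["blood", "liver", "tumour"]))
               & (summary["timepoint_h"].isin([0.0833, 24.0]))]
print("group means (%ID/g, decay-corrected):")
print(show.to_string(index=False))

def organ_values(records, organ, t):
    return [percent_id_per_gram(r, nuclide) for r in records
            if r.organ == organ and abs(r.timepoint_h - t) < 1e-6]

liver_h = organ_values(healthy, "liver", 24.0)
liver_t = organ_values(tumour, "liver", 24.0)
t, df, p = welch_t_test(liver_h, liver_t)
print(f"\nliver @24 h, healthy {np.mean(liver_h):.1f} vs tumour-bearing "
      f"{np.mean(liver_t):.1f} %ID/g: Welch t = {t:.2f}, df = {df:.1f}, p = {p:.3g}")
print("(healthy-mouse liver uptake is higher: less antigen sink elsewhere)")
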