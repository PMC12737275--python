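"""Generate survey-like data and verify its statistical structure.

Draws per-congener log-normal concentrations moment-matched to the bundled
survey statistics, with species multipliers reproducing the observed
accumulation ordering.
"""

import numpy as np
import pandas as pd

from pahrisk import registry, synthetic

conc = synthetic.generate_from_survey(5000, seed=3)
target = registry.survey_mean_vector()
rel_err = np.abs(conc.values.mean(axis=0) - target) / target
print(f"Max per-congener mean error vs survey targets: {rel_err.max():.1%}")

totals = pd.Series(conc.values.sum(axis=1)).groupby(pd.Series(conc.species)).mean()
print("\nMean total PAH burden by species (ug/kg ww):")
print(totals.sort_values(ascending=False).to_string())

rings = registry.ring_counts()
high = conc.values[:, rings >= 5].sum(axis=1) / conc.values.sum(axis=1)
frac = pd.Series(high).groupby(pd.Series(conc.species)).mean()
print("\nMean 5-6-ring fraction by species:")
print(frac.sort_values(ascending=False).to_string())

# Crayfish accumulates the largest total burden, but yellow catfish carries
# the largest high-ring (carcinogen-rich) fraction.
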