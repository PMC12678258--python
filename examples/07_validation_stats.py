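"""Expert-panel statistics: reliability, retention, consensus, variance flags.

A simulated five-expert Likert panel rates candidate indicators; the
printed numbers are the mean pairwise Cohen's kappa (inter-rater
reliability), the indicators retained under the 4-approvals-and-mean>=4
rule, and the between-stratum variance flags.
"""

import numpy as np

from resilmine.stats import cohen_kappa, likert_retention, npi_variance_flag, panel_kappa
from resilmine.synth import generate_raters

table = generate_raters(n_items=20, n_raters=5, agreement=0.8, seed=3)
print(f"panel: {table.shape[0]} items x {table.shape[1]} raters")
print(f"mean pairwise Cohen's kappa: {panel_kappa(table):.3f}")
print(f"kappa of first two raters:   {cohen_kappa(table.rater0, table.rater1):.3f}")

retained = likert_retention(table)
print(f"retained {len(retained)}/{len(table)} items under >=4 approvals and mean >= 4.0")

# stratify raters into two intervention-stringency groups and flag items
# whose group means differ by more than 20% of the overall mean
strict = table[["rater0", "rater1", "rater2"]].mean(axis=1)
lenient = table[["rater3", "rater4"]].mean(axis=1)
flags = npi_variance_flag({i: [strict[i], lenient[i]] for i in table.index})
print(f"variance-flagged items: {sum(flags.values())} (flagged items stay retained)")
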