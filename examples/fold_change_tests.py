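"""The fold-change statistical workflow on a small made-up assay table.

Normalises raw values by the control mean, screens normality, tests each
group against 1 and applies Bonferroni over the planned comparisons.
"""

import numpy as np

import nquant as nq

rng = np.random.default_rng(5)
conditions = ["MOCK"] * 6 + ["ANKK1"] * 6 + ["FARP1"] * 6
values = np.concatenate([rng.normal(1.0, 0.12, 6),
                         rng.normal(1.8, 0.20, 6),
                         rng.normal(1.1, 0.15, 6)])

table = nq.one_vs_control_analysis(conditions, values, control="MOCK")
print(table.round(4))
# mean_fold is each group's mean after dividing by the MOCK mean; p_adj is
# the Bonferroni-corrected one-sample t (vs 1) p-value. Here the ANKK1
# group was generated ~1.8x the control and should be the significant row.
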