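"""Relative qPCR quantification with the ddCt method.

Cycle thresholds are normalized to a reference gene (Gapdh) within each
condition, referenced to the sham-operated baseline, and converted to a
fold change as 2**-ddCt.
"""

import pandas as pd

from uuoseq import qpcr_folds
from uuoseq.reporting import ddct_fold

# one cycle earlier for the target (reference unchanged) doubles expression
print("ddCt -1 ->", ddct_fold(19.0, 15.0, 20.0, 15.0), "fold")
print("ddCt +2 ->", ddct_fold(22.0, 15.0, 20.0, 15.0), "fold")

ct = pd.DataFrame({
    "target":    ["Acta2"] * 6 + ["Gapdh"] * 6,
    "condition": ["SO", "SO", "2D", "2D", "8D", "8D"] * 2,
    "ct":        [25.1, 25.3, 23.0, 23.2, 22.1, 22.3,
                  18.0, 18.2, 18.1, 17.9, 18.0, 18.2],
})
folds = qpcr_folds(ct, reference_gene="Gapdh", baseline_condition="SO")
print("\nfold change vs sham (replicate Cts averaged first):")
print(folds.to_string(index=False))
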