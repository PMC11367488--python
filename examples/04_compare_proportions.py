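"""Test whether cell-type composition differs between two conditions.

Proportions are compositional (one type growing shrinks the rest), so the
comparison uses a cell-level permutation test on the log2 fold-difference
of each type's proportion, BH-FDR corrected, with a bootstrap confidence
interval.  A type is called significant at FDR < 0.05 and |log2FD| > 0.58
(about 1.5-fold).
"""

import numpy as np
import pandas as pd

from cytotype.events import EventTable
from cytotype.stats import permutation_test_two

rng = np.random.default_rng(5)

# condition "mutant": neurons doubled from 15% to 30% at the expense of glia
compositions = {
    "control": {"neurons": 300, "NPC": 700, "glia": 1000},
    "mutant": {"neurons": 600, "NPC": 700, "glia": 700},
}
labels, sids = [], []
for group, counts in compositions.items():
    for cell_type, n in counts.items():
        labels += [cell_type] * n
        sids += [f"sample_{group}"] * n
events = EventTable(
    rng.uniform(0, 10, (len(labels), 2)),
    ["A", "B"],
    np.asarray(sids),
    sample_meta=pd.DataFrame(
        {"condition": list(compositions)},
        index=pd.Index([f"sample_{g}" for g in compositions], name="sample_id"),
    ),
    obs=pd.DataFrame({"final_label": labels}),
)

result = permutation_test_two(
    events, "condition", ("mutant", "control"), n_perm=1000, n_boot=1000, seed=0
)
print(result.round(4).to_string(index=False))
print("\nlog2fd near +1 for neurons = the planted two-fold enrichment in the")
print("mutant; the permutation p and FDR confirm it; the CI excludes zero.")
print("NPC, identical in both groups, is correctly left non-significant.")
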