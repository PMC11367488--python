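"""Remove a planted batch effect by landmark alignment.

Two simulated samples share the same cell populations, but one was
"acquired on a different day": every intensity on marker M1 is offset by
+0.5 on the asinh scale.  Harmonization transforms to asinh space,
detects the density peaks of each sample, and warps each sample so its
peaks land on the cross-sample consensus positions.
"""

import numpy as np

from cytotype import (
    LandmarkSpec,
    SimSpec,
    biexp_transform,
    detect_landmarks,
    dominant_marker_reference,
    harmonize,
    simulate,
)

reference = dominant_marker_reference(4)
spec = SimSpec(
    reference=reference,
    proportions={"day1": [0.25] * 4, "day2": [0.25] * 4},
    n_cells={"day1": 3000, "day2": 3000},
    batch_shift={"day2": np.array([0.5, 0.0, 0.0, 0.0])},  # the batch effect
    seed=0,
)
events = simulate(spec)

landmark_spec = LandmarkSpec({"M1": 2})  # M1 is bimodal: negative + positive


def peak_gap(table):
    """Largest between-sample discrepancy of matched density peaks."""
    t = table.copy()
    t.space_tag = "transformed"
    report = detect_landmarks(t, landmark_spec)
    piv = report.records.pivot_table(index="peak", columns="sample", values="position")
    return float(np.abs(piv["day1"] - piv["day2"]).max())


before = peak_gap(biexp_transform(events))
aligned, report = harmonize(events, landmark_spec, do_retro=False)
after = peak_gap(aligned)

print(f"peak discrepancy before alignment: {before:.3f} (planted offset 0.5)")
print(f"peak discrepancy after alignment:  {after:.3f}")
print(f"reduction: {100 * (1 - after / before):.1f}%")
print("\nA reduction above 90% means the two acquisition days are now")
print("comparable: downstream clustering will not split cells by batch.")
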