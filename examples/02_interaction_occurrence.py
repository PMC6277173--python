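"""H-bond and parallel-stacking occurrence on labelled fixtures.

The generator places a donor-H-acceptor triad and a pair of aromatic rings
at interacting geometry in a known fraction of frames (40 % H-bonded, 20 %
stacked) and random non-interacting geometry otherwise, with a random
rigid-body motion per frame.  The occurrence statistics must recover those
fractions exactly, because the criteria are internal-geometry-only.
"""

from cdrloop import (
    HBondCriterion,
    StackingCriterion,
    hbond_occurrence,
    make_interaction_ensemble,
    stacking_occurrence,
)

ensemble, triplet, ring_pair, truth = make_interaction_ensemble(
    hbond_fraction=0.40, stacking_fraction=0.20, n_frames=200, seed=1
)

hb = hbond_occurrence([ensemble], [triplet], HBondCriterion())
st = stacking_occurrence([ensemble], [ring_pair], StackingCriterion())

print("H-bond criterion: d(H..A) < 0.25 nm and angle(D-H-A) > 135 deg")
print(hb[["ensemble", "interaction_id", "n_hits", "percent", "status"]].to_string(index=False))
print()
print("Stacking criterion: centroid distance <= 0.5 nm and plane angle <= 30 deg")
print(st[["ensemble", "n_hits", "percent", "status"]].to_string(index=False))
print()
print("'percent' is the share of monitored frames satisfying the criterion;")
print("the values match the generator's 40 % / 20 % labels exactly despite")
print("every frame being randomly rotated and translated.")
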