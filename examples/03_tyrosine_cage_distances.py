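"""Ring-centroid distance monitoring, as used for a tyrosine cage.

Monitors the distance between the centre of geometry of an aromatic ring
and a probe atom of a neighbouring residue, summarises the distribution,
and reports the fraction of frames below the 0.4 nm contact threshold.
Distances here are drawn from a bimodal mixture (70 % in contact at
~0.32 nm, 30 % detached at ~0.55 nm) to mimic a partially formed contact.
"""

import numpy as np

from cdrloop import (
    Atom,
    AtomId,
    Ensemble,
    Frame,
    below_threshold_fraction,
    distance_series,
    histogram,
    make_ring_pair_fixture,
)

rng = np.random.default_rng(3)
ring_top, ring_frame, _, _ = make_ring_pair_fixture(0.5, 0.0)
topology = ring_top[:6] + [Atom("H", 94, "", "ARG", "CZ", "C")]

n_frames = 1000
contact = rng.random(n_frames) < 0.70
gaps = np.where(contact, rng.normal(0.32, 0.015, n_frames),
                rng.normal(0.55, 0.02, n_frames))
frames = [
    Frame(np.concatenate([ring_frame.coordinates[:6], [[0.0, 0.0, g]]]),
          model_index=i)
    for i, g in enumerate(gaps)
]
ensemble = Ensemble(label="demo", topology=topology, frames=frames)

series = distance_series(ensemble, "resi 27", [AtomId("H", 94, "", "CZ")])[0]
hist = histogram(series, bin_width=0.01)
contact_fraction = below_threshold_fraction(series, threshold=0.4)

mode = int(np.argmax(hist.densities))
print(f"frames: {len(series.values)}")
print(f"mean ring-probe distance: {series.values.mean():.3f} nm")
print(f"histogram mode bin: [{hist.bin_edges[mode]:.2f}, "
      f"{hist.bin_edges[mode + 1]:.2f}) nm")
print(f"fraction of frames closer than 0.4 nm: {contact_fraction:.3f}")
print()
print("A contact fraction near the generator's 70 % occupancy and a mode")
print("near 0.32 nm indicate a predominantly formed (cage-like) contact;")
print("distances persistently above 0.4 nm would signal its loss.")
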