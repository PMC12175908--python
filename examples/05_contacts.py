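"""Weighted contact maps, interface profiles, and state-specific contacts.

Contact frequencies are weighted fractions of frames in which two 4-residue
segments approach within the cutoff; restricting the weights to one state and
renormalizing gives per-state maps, from which contacts highly represented in
exactly one state are extracted.
"""

import numpy as np

from idpre import ChainSpec, GroundTruth
from idpre.contacts import (
    contact_frequency_map,
    interaction_profile,
    state_specific_contacts,
)
from idpre.synthetic import default_states, sample_complex_ensemble

truth = GroundTruth(state_weights={"I": 0.4, "II": 0.3, "III": 0.2, "IV": 0.1},
                    seed=5)
ens = sample_complex_ensemble(ChainSpec(), default_states(), truth,
                              n_frames_per_state=100)
w = ens.true_weights

per_state = contact_frequency_map(ens, w, chain_a="A", per_state=True)
for s, cmap in per_state.items():
    n_frequent = int((cmap.frequencies > 0.5).sum() / 2)  # symmetric matrix
    print(f"state {s}: {n_frequent} intra-chain segment pairs in contact "
          f">50% of the time")

specific = state_specific_contacts(per_state, high_thresh=0.6, low_thresh=0.2)
print(f"{len(specific)} state-specific contacts "
      f"(>=60% in one state, <=20% in the others)")

profiles = interaction_profile(ens, w, "A", "B")
pa = profiles["A"].segment_probability
windows = profiles["A"].windows
top = np.argsort(pa)[-4:][::-1]
print("chain segments most often at the receptor interface:")
for i in top:
    s, e = windows[i]
    print(f"  residues {s+1:3d}-{e:3d}: in contact {pa[i]:.0%} of the time")
# The anchored LD motifs dominate the interface; linker segments show the
# transient receptor contacts characteristic of a fuzzy complex.
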